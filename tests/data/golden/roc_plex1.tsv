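cutoff	tpr	fpr
2.87545	0.02	0
2.66658	0.04	0
2.57983	0.06	0
2.48081	0.08	0
2.29924	0.1	0
2.04903	0.12	0
1.95786	0.14	0
1.95433	0.16	0
1.93218	0.18	0
1.8691	0.2	0
1.83437	0.22	0
1.76868	0.24	0
1.75578	0.26	0
1.71004	0.28	0
1.68918	0.3	0
1.64222	0.32	0
1.62899	0.34	0
1.60412	0.36	0
1.58157	0.38	0
1.51899	0.4	0
1.51887	0.42	0
1.46268	0.44	0
1.45169	0.46	0
1.39622	0.48	0
1.39178	0.5	0
1.30984	0.52	0
1.20526	0.54	0
1.19357	0.56	0
1.09849	0.58	0
1.09126	0.6	0
1.04908	0.62	0
0.983784	0.64	0
0.935078	0.66	0
0.93233	0.68	0
0.927083	0.7	0
0.844719	0.72	0
0.843361	0.74	0
0.797758	0.76	0
0.77269	0.78	0
0.739579	0.8	0
0.677096	0.82	0
0.569214	0.84	0
0.531922	0.86	0
0.234029	0.88	0
0.224393	0.9	0
-0.0455102	0.92	0
-0.128843	0.94	0
-0.298188	0.96	0
-0.339731	0.98	0
-0.380826	1	0
-1.61278	1	0.02
-1.6986	1	0.04
-1.70828	1	0.06
-1.7244	1	0.08
-1.72925	1	0.1
-1.73096	1	0.12
-1.73614	1	0.14
-1.77406	1	0.16
-1.78129	1	0.18
-1.78278	1	0.2
-1.78418	1	0.22
-1.7892	1	0.24
-1.79505	1	0.26
-1.79701	1	0.28
-1.81225	1	0.3
-1.81341	1	0.32
-1.814	1	0.34
-1.81699	1	0.36
-1.81777	1	0.38
-1.83192	1	0.4
-1.83193	1	0.42
-1.84142	1	0.44
-1.84481	1	0.46
-1.84598	1	0.48
-1.84762	1	0.5
-1.86443	1	0.52
-1.87771	1	0.54
-1.87819	1	0.56
-1.88246	1	0.58
-1.88586	1	0.6
-1.88886	1	0.62
-1.91006	1	0.64
-1.91357	1	0.66
-1.91493	1	0.68
-1.92001	1	0.7
-1.93012	1	0.72
-1.94618	1	0.74
-1.95959	1	0.76
-1.96825	1	0.78
-2.00456	1	0.8
-2.00497	1	0.82
-2.01261	1	0.84
-2.01272	1	0.86
-2.01846	1	0.88
-2.02559	1	0.9
-2.04443	1	0.92
-2.06831	1	0.94
-2.0868	1	0.96
-2.17428	1	0.98
-2.21413	1	1
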