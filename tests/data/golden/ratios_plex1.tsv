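protein	log2_ratio
P00001	1.83437
P00002	1.51899
P00003	2.48081
P00004	1.68918
P00005	1.71004
P00006	1.62899
P00007	1.76868
P00008	0.843361
P00009	0.983784
P00010	0.739579
P00011	1.45169
P00012	1.39622
P00013	1.64222
P00014	1.75578
P00015	0.797758
P00016	1.95433
P00017	1.60412
P00018	-0.339731
P00019	-0.298188
P00020	0.677096
P00021	-0.380826
P00022	1.09126
P00023	2.29924
P00024	2.87545
P00025	1.30984
P00026	2.04903
P00027	1.8691
P00028	1.46268
P00029	0.234029
P00030	2.57983
P00031	1.04908
P00032	0.844719
P00033	1.19357
P00034	1.51887
P00035	0.927083
P00036	1.20526
P00037	0.224393
P00038	-0.128843
P00039	1.95786
P00040	-0.0455102
P00041	0.569214
P00042	0.935078
P00043	0.93233
P00044	0.77269
P00045	1.93218
P00046	1.09849
P00047	0.531922
P00048	1.58157
P00049	1.39178
P00050	2.66658
P00051	-1.81225
P00052	-1.96825
P00053	-1.7244
P00054	-1.78418
P00055	-1.88586
P00056	-1.79701
P00057	-1.83193
P00058	-1.78129
P00059	-1.61278
P00060	-1.88246
P00061	-2.00456
P00062	-1.88886
P00063	-1.91006
P00064	-1.7892
P00065	-1.77406
P00066	-1.84142
P00067	-1.95959
P00068	-2.01846
P00069	-1.94618
P00070	-1.73096
P00071	-1.81699
P00072	-1.84762
P00073	-1.91493
P00074	-2.04443
P00075	-2.06831
P00076	-2.0868
P00077	-2.00497
P00078	-1.87771
P00079	-1.91357
P00080	-1.70828
P00081	-2.21413
P00082	-1.92001
P00083	-2.02559
P00084	-1.81341
P00085	-2.17428
P00086	-1.83192
P00087	-1.79505
P00088	-2.01272
P00089	-1.6986
P00090	-1.84481
P00091	-1.81777
P00092	-1.72925
P00093	-1.73614
P00094	-1.814
P00095	-1.84598
P00096	-1.86443
P00097	-2.01261
P00098	-1.87819
P00099	-1.93012
P00100	-1.78278
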