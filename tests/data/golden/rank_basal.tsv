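protein	mean_intensity	rank	concentration_pmol_ml
P00001	178022	46	
P00002	1.7222e+06	17	
P00003	203232	43	
P00004	906586	25	
P00005	1.0502e+06	23	
P00006	1.21178e+06	20	
P00007	295962	37	
P00008	10492.8	77	
P00009	1.85217e+06	16	
P00010	4477.79	85	
P00011	263525	41	
P00012	1.0405e+06	24	
P00013	1.29266e+07	5	
P00014	9.53084e+08	1	
P00015	290791	38	
P00016	394278	35	
P00017	289699	39	
P00018	4.59975e+07	2	
P00019	10484.9	78	
P00020	713307	28	
P00021	302750	36	
P00022	413251	33	
P00023	1.54255e+06	19	
P00024	1.60207e+06	18	
P00025	1.334e+07	4	
P00026	1.49109e+07	3	
P00027	2.72741e+06	12	
P00028	122754	50	
P00029	101817	55	
P00030	2.92412e+06	11	
P00031	44907.5	64	
P00032	4.5431e+06	10	
P00033	4.63228e+06	9	
P00034	5.57452e+06	7	
P00035	72858.7	60	
P00036	1.93081e+06	15	
P00037	396013	34	
P00038	88392.7	56	
P00039	424571	32	
P00040	455581	30	
P00041	85394.6	57	
P00042	5.09018e+06	8	
P00043	154819	47	
P00044	266151	40	
P00045	449602	31	
P00046	9.75446e+06	6	
P00047	1894.48	88	
P00048	243328	42	
P00049	2.39806e+06	13	
P00050	508831	29	
P00051	26747.9	69	
P00052	48152.3	63	
P00053	105943	52	
P00054	1142.07	92	
P00055	7306.15	81	
P00056	8366.44	79	
P00057	6685.24	83	
P00058	16511.8	72	
P00059	136820	49	
P00060	725932	27	
P00061	1243.94	91	
P00062	36904.7	66	
P00063	13497.4	74	
P00064	801850	26	
P00065	7203.75	82	
P00066	61637.8	62	
P00067	121921	51	
P00068	20541.8	70	
P00069	103195	54	
P00070	26796.5	68	
P00071	182483	45	
P00072	1.07404e+06	22	
P00073	1.16579e+06	21	
P00074	15347.5	73	
P00075	139841	48	
P00076	343.821	97	
P00077	103378	53	
P00078	7387.57	80	
P00079	1387.14	90	
P00080	19543.7	71	
P00081	32.7676	100	
P00082	1.94084e+06	14	
P00083	10870.9	76	
P00084	1001.07	94	
P00085	1861.3	89	
P00086	1006.16	93	
P00087	577.736	96	
P00088	193519	44	
P00089	81503.2	59	
P00090	4065.37	87	
P00091	6447.14	84	
P00092	82153.1	58	
P00093	59.7922	99	
P00094	64338	61	
P00095	35078	67	
P00096	37751.8	65	
P00097	4259.02	86	
P00098	271.485	98	
P00099	971.203	95	
P00100	12885.4	75	
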