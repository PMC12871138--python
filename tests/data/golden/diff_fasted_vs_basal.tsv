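protein	contrast	log2fc	p	q	significant	n_a	n_b
P00001	fasted_vs_basal	-0.203897	0.50754	0.9437268093584662	False	3	3
P00002	fasted_vs_basal	-0.127182	0.707769	0.9437268093584662	False	3	3
P00003	fasted_vs_basal	0.154311	0.507033	0.9437268093584662	False	3	3
P00004	fasted_vs_basal	-0.407723	0.251669	0.8221195749206673	False	3	3
P00005	fasted_vs_basal	0.0517522	0.876855	0.9437268093584662	False	3	3
P00006	fasted_vs_basal	0.175447	0.639571	0.9437268093584662	False	3	3
P00007	fasted_vs_basal	0.15946	0.733135	0.9437268093584662	False	3	2
P00008	fasted_vs_basal	-0.554665	0.0977834	0.43558059054744	False	3	3
P00009	fasted_vs_basal	0.207328	0.598615	0.9437268093584662	False	3	2
P00010	fasted_vs_basal	-1.42153			False	3	1
P00011	fasted_vs_basal	0.145579	0.466664	0.9437268093584662	False	3	3
P00012	fasted_vs_basal	0.0194631	0.962619	0.9626194443342277	False	3	2
P00013	fasted_vs_basal	0.0603357	0.872858	0.9437268093584662	False	3	3
P00014	fasted_vs_basal	0.102855	0.752417	0.9437268093584662	False	2	3
P00015	fasted_vs_basal	0.53285	0.0712867	0.34930492995315765	False	2	3
P00016	fasted_vs_basal	0.220937	0.310701	0.9437268093584662	False	3	3
P00017	fasted_vs_basal	-1.10688	0.0440818	0.34930492995315765	True	3	3
P00018	fasted_vs_basal	0.122406	0.633594	0.9437268093584662	False	3	3
P00019	fasted_vs_basal	-0.0895176	0.821318	0.9437268093584662	False	3	3
P00020	fasted_vs_basal	-0.0242198	0.920955	0.9601445100160173	False	3	2
P00021	fasted_vs_basal	-0.720506	0.123987	0.5062816479717509	False	3	2
P00022	fasted_vs_basal	0.0634657	0.817208	0.9437268093584662	False	3	3
P00023	fasted_vs_basal	-0.11444	0.796607	0.9437268093584662	False	3	3
P00024	fasted_vs_basal	-0.259344	0.0259908	0.2840267645072287	False	3	3
P00025	fasted_vs_basal	-0.106489	0.674979	0.9437268093584662	False	3	3
P00026	fasted_vs_basal	-0.249282	0.385956	0.9437268093584662	False	3	3
P00027	fasted_vs_basal	0.227698	0.634361	0.9437268093584662	False	3	3
P00028	fasted_vs_basal	0.432383	0.0289823	0.2840267645072287	False	3	3
P00029	fasted_vs_basal	-0.0854011	0.773168	0.9437268093584662	False	3	3
P00030	fasted_vs_basal	1.30878	0.00860619	0.18230395641467229	True	3	3
P00031	fasted_vs_basal	0.160227	0.606195	0.9437268093584662	False	3	3
P00032	fasted_vs_basal	-2.26589	0.00587899	0.18230395641467229	True	2	3
P00033	fasted_vs_basal	0.197194	0.559274	0.9437268093584662	False	3	2
P00034	fasted_vs_basal	0.117811	0.731428	0.9437268093584662	False	3	3
P00035	fasted_vs_basal	0.539506	0.0617458	0.34930492995315765	False	2	3
P00036	fasted_vs_basal	-0.712569	0.21106	0.7873562753188066	False	3	2
P00037	fasted_vs_basal	-0.101745	0.736685	0.9437268093584662	False	3	3
P00038	fasted_vs_basal	-0.396024	0.530156	0.9437268093584662	False	2	2
P00039	fasted_vs_basal	-0.0576626	0.885948	0.9437268093584662	False	3	2
P00040	fasted_vs_basal	0.046739	0.835245	0.9437268093584662	False	3	3
P00041	fasted_vs_basal	-0.099537	0.642669	0.9437268093584662	False	3	3
P00042	fasted_vs_basal	0.0810321	0.810236	0.9437268093584662	False	3	3
P00043	fasted_vs_basal	-2.19303	0.0685946	0.34930492995315765	False	2	3
P00044	fasted_vs_basal	-0.919705	0.0527805	0.34930492995315765	False	3	2
P00045	fasted_vs_basal	1.92659	0.0111615	0.18230395641467229	True	3	3
P00046	fasted_vs_basal	-0.510391	0.224959	0.7873562753188066	False	3	3
P00047	fasted_vs_basal	-0.198853	0.59425	0.9437268093584662	False	2	3
P00048	fasted_vs_basal	-0.025242	0.951258	0.9626194443342277	False	3	3
P00049	fasted_vs_basal	0.206036	0.614638	0.9437268093584662	False	3	3
P00050	fasted_vs_basal	-0.0487864	0.844438	0.9437268093584662	False	3	3
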