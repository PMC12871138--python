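protein	contrast	log2fc	p	q	significant	n_a	n_b
P00001	LPS_vs_basal	-0.0281882	0.92748	0.9543683515903082	False	3	3
P00002	LPS_vs_basal	0.234587	0.508156	0.8331783751262412	False	3	3
P00003	LPS_vs_basal	0.312255	0.336245	0.7501486468732737	False	3	3
P00004	LPS_vs_basal	0.812172	0.0328668	0.15776062735958934	True	3	3
P00005	LPS_vs_basal	0.356778	0.327304	0.7501486468732737	False	3	3
P00006	LPS_vs_basal	0.0916292	0.742784	0.9543683515903082	False	3	3
P00007	LPS_vs_basal	-1.08238	0.0147223	0.07879913674734905	True	3	2
P00008	LPS_vs_basal	-0.0196141	0.894758	0.9543683515903082	False	3	3
P00009	LPS_vs_basal	0.638427	0.223598	0.670795041871111	False	2	2
P00010	LPS_vs_basal	0.506384			False	3	1
P00011	LPS_vs_basal	0.421025	0.22068	0.670795041871111	False	3	3
P00012	LPS_vs_basal	-1.5684	0.0665772	0.2663089589435085	False	3	2
P00013	LPS_vs_basal	0.159451	0.520736	0.8331783751262412	False	3	3
P00014	LPS_vs_basal	-1.83728	9.32843e-05	0.003666435624392643	True	3	3
P00015	LPS_vs_basal	-0.832713	0.00410286	0.03329919546115363	True	3	3
P00016	LPS_vs_basal	0.0978368	0.713109	0.9543683515903082	False	3	3
P00017	LPS_vs_basal	0.340122	0.414718	0.8263049793425243	False	3	3
P00018	LPS_vs_basal	0.50703	0.191958	0.658141531938589	False	2	3
P00019	LPS_vs_basal	1.29005	0.0147748	0.07879913674734905	True	3	3
P00020	LPS_vs_basal	-0.0207541			False	1	2
P00021	LPS_vs_basal	0.49333	0.277836	0.7442782599910001	False	3	2
P00022	LPS_vs_basal	0.308571	0.107348	0.39636125584352483	False	3	3
P00023	LPS_vs_basal	0.034649	0.934486	0.9543683515903082	False	3	3
P00024	LPS_vs_basal	-2.2192	0.000152768	0.003666435624392643	True	3	3
P00025	LPS_vs_basal	0.242457	0.343818	0.7501486468732737	False	3	3
P00026	LPS_vs_basal	0.262927	0.471803	0.8263049793425243	False	3	3
P00027	LPS_vs_basal	0.212469	0.587551	0.8570707470624138	False	3	3
P00028	LPS_vs_basal	-1.26655	0.00064239	0.010278237263866006	True	3	3
P00029	LPS_vs_basal	0.048273	0.888743	0.9543683515903082	False	3	3
P00030	LPS_vs_basal	-0.129281	0.589236	0.8570707470624138	False	3	3
P00031	LPS_vs_basal	0.0286585	0.924609	0.9543683515903082	False	3	3
P00032	LPS_vs_basal	0.224855	0.482011	0.8263049793425243	False	3	3
P00033	LPS_vs_basal	0.383332	0.29461	0.7442782599910001	False	3	2
P00034	LPS_vs_basal	-0.37401	0.461009	0.8263049793425243	False	3	3
P00035	LPS_vs_basal	-1.541	0.0041624	0.03329919546115363	True	3	3
P00036	LPS_vs_basal	0.197984	0.46629	0.8263049793425243	False	3	2
P00037	LPS_vs_basal	0.0833023	0.869131	0.9543683515903082	False	2	3
P00038	LPS_vs_basal	-0.10726	0.84968	0.9543683515903082	False	3	2
P00039	LPS_vs_basal	-0.0418631	0.928027	0.9543683515903082	False	3	2
P00040	LPS_vs_basal	-1.53619	0.00267672	0.03212063529896636	True	3	3
P00041	LPS_vs_basal	0.0781028	0.779724	0.9543683515903082	False	3	3
P00042	LPS_vs_basal	-1.26289	0.0141909	0.07879913674734905	True	3	3
P00043	LPS_vs_basal	-0.152623	0.547601	0.8478978716425287	False	3	3
P00044	LPS_vs_basal	0.430892	0.0431442	0.18826564226996054	False	3	2
P00045	LPS_vs_basal	0.149963	0.660771	0.9328536743921139	False	3	3
P00046	LPS_vs_basal	0.0528485	0.862522	0.9543683515903082	False	2	3
P00047	LPS_vs_basal	-0.340349	0.398192	0.8263049793425243	False	3	3
P00048	LPS_vs_basal	0.521367	0.280442	0.7442782599910001	False	3	3
P00049	LPS_vs_basal	0.0848106	0.844111	0.9543683515903082	False	3	3
P00050	LPS_vs_basal	-0.000147694	0.999563	0.9995626530258176	False	2	3
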