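protein	class	true_base_abundance	true_log2_enrichment	true_log2_effect_LPS	true_log2_effect_fasted
P00001	secretory	22785.1	3.74943	0	0
P00002	secretory	308042	3.14317	0	0
P00003	secretory	17569.7	4.39212	0	0
P00004	secretory	195120	3.22966	0	-0.476372
P00005	secretory	165943	3.60831	0	0
P00006	secretory	190022	3.21571	0	0
P00007	secretory	37723.5	4.01493	-1.29056	0
P00008	secretory	2350.66	2.89223	0	0
P00009	secretory	546055	2.7667	0	0
P00010	secretory	1576.26	2.56694	0	-1.63342
P00011	secretory	58253.8	3.24294	0	0
P00012	secretory	187619	3.25681	-1.5965	0
P00013	secretory	2.20744e+06	3.41955	0	0
P00014	secretory	1.41128e+08	3.65499	-2.00254	0
P00015	secretory	94350.8	2.87931	-1.52293	0
P00016	secretory	48927.2	3.73493	0	0
P00017	secretory	48771	3.47713	0	-1.29639
P00018	secretory	3.09231e+07	1.59473	0	0
P00019	secretory	6317.79	1.57981	1.124	0
P00020	secretory	208888	2.49929	0	0
P00021	secretory	229940	1.60608	0	-1.23151
P00022	secretory	98464.1	2.87294	0	0
P00023	secretory	161033	4.06304	0	0
P00024	secretory	91569.9	4.79254	-2.20866	0
P00025	secretory	2.52231e+06	3.27181	0	0
P00026	secretory	1.81688e+06	3.93858	0	0
P00027	secretory	446935	3.75501	0	0
P00028	secretory	28964.7	3.25591	-1.47832	0
P00029	secretory	43635.8	2.05954	0	0
P00030	secretory	196588	4.48693	0	1.41209
P00031	secretory	10394.2	3.02233	0	0
P00032	secretory	1.26567e+06	2.67125	0	-1.79927
P00033	secretory	1.19972e+06	2.93394	0	0
P00034	secretory	870753	3.36433	0	0
P00035	secretory	24256.8	2.80134	-2.10745	0
P00036	secretory	439670	3.09596	0	-0.749954
P00037	secretory	160050	2.0603	0	0
P00038	secretory	39862	1.87806	0	0
P00039	secretory	48985.4	3.7173	0	0
P00040	secretory	207790	1.90676	-1.69052	0
P00041	secretory	28148.5	2.39098	0	0
P00042	secretory	1.44004e+06	2.65171	-1.70095	0
P00043	secretory	40968.4	2.69641	0	-2.15177
P00044	secretory	90039	2.63907	0	-1.07703
P00045	secretory	59222.4	3.94059	0	1.55726
P00046	secretory	1.86468e+06	2.97207	0	0
P00047	secretory	628.348	2.13587	0	0
P00048	secretory	40923.8	3.30715	0	0
P00049	secretory	428612	3.50156	0	0
P00050	secretory	35747.1	4.65774	0	0
P00051	background	48859.2	0	0	0
P00052	background	71259	0	0	0
P00053	background	190700	0	0	0
P00054	background	1653.13	0	0	0
P00055	background	13926.5	0	0	0
P00056	background	16353.5	0	0	0
P00057	background	9693.71	0	0	0
P00058	background	25144.5	0	0	0
P00059	background	207218	0	0	0
P00060	background	1.39178e+06	0	0	0
P00061	background	2036.24	0	0	0
P00062	background	72096.8	0	0	0
P00063	background	23925	0	0	0
P00064	background	1.37418e+06	0	0	0
P00065	background	14988	0	0	0
P00066	background	102695	0	0	0
P00067	background	202124	0	0	0
P00068	background	38568.6	0	0	0
P00069	background	214340	0	0	0
P00070	background	52452.6	0	0	0
P00071	background	344901	0	0	0
P00072	background	1.87735e+06	0	0	0
P00073	background	1.72155e+06	0	0	0
P00074	background	29987.5	0	0	0
P00075	background	288560	0	0	0
P00076	background	612.644	0	0	0
P00077	background	223947	0	0	0
P00078	background	11023.7	0	0	0
P00079	background	2827.46	0	0	0
P00080	background	29507.9	0	0	0
P00081	nonspecific	59.9156	0	0	0
P00082	nonspecific	4.56046e+06	0	0	0
P00083	nonspecific	21444.1	0	0	0
P00084	nonspecific	1899.62	0	0	0
P00085	nonspecific	3354.54	0	0	0
P00086	nonspecific	1974.71	0	0	0
P00087	nonspecific	1143.73	0	0	0
P00088	nonspecific	345432	0	0	0
P00089	nonspecific	134396	0	0	0
P00090	nonspecific	8074.29	0	0	0
P00091	nonspecific	10775.5	0	0	0
P00092	nonspecific	143538	0	0	0
P00093	nonspecific	103.461	0	0	0
P00094	nonspecific	102806	0	0	0
P00095	nonspecific	65596.6	0	0	0
P00096	nonspecific	72362.8	0	0	0
P00097	nonspecific	8221.11	0	0	0
P00098	nonspecific	461.581	0	0	0
P00099	nonspecific	1733.03	0	0	0
P00100	nonspecific	20688.6	0	0	0
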