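CC:Golgi_apparatus	Golgi apparatus	P00008	P00009	P00011	P00018	P00022	P00037	P00039	P00040	P00046	P00049
CC:cytosol	cytosol	P00083	P00086	P00091	P00092	P00094	P00095	P00096	P00098
CC:endoplasmic_reticulum	endoplasmic reticulum	P00001	P00010	P00014	P00025	P00028	P00033	P00034	P00038	P00048
CC:extracellular_region	extracellular region	P00004	P00007	P00017	P00020	P00029	P00030	P00031	P00036	P00041	P00047
CC:lysosome	lysosome	P00003	P00006	P00012	P00015	P00016	P00021	P00024	P00026	P00027
CC:mitochondrion	mitochondrion	P00051	P00052	P00053	P00054	P00055	P00056	P00057	P00058	P00059	P00060	P00061	P00062	P00063	P00064	P00065	P00066	P00067	P00068	P00069	P00070	P00071	P00072	P00073	P00074	P00075	P00076	P00077	P00078	P00079	P00080
CC:nucleus	nucleus	P00081	P00082	P00084	P00085	P00087	P00088	P00089	P00090	P00093	P00097	P00099	P00100
CC:plasma_membrane	plasma membrane	P00002	P00005	P00013	P00019	P00023	P00032	P00035	P00042	P00043	P00044	P00045	P00050
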