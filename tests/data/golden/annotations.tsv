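protein	cc_terms	signal_peptide	ups_predicted	transmembrane	tissue_enriched	concentration	concentration_unit
P00001	endoplasmic reticulum	False	False	False			
P00002	plasma membrane	True	False	False			
P00003	lysosome	True	False	False			
P00004	extracellular region	True	False	False			
P00005	plasma membrane	True	False	True			
P00006	lysosome	True	False	False			
P00007	extracellular region	True	False	False			
P00008	Golgi apparatus	False	True	False			
P00009	Golgi apparatus	True	False	False			
P00010	endoplasmic reticulum	True	False	False			
P00011	Golgi apparatus	True	False	False			
P00012	lysosome	True	False	True			
P00013	plasma membrane	True	False	False			
P00014	endoplasmic reticulum	True	False	False			
P00015	lysosome	True	False	False			
P00016	lysosome	True	False	True			
P00017	extracellular region	False	False	False			
P00018	Golgi apparatus	True	False	False			
P00019	plasma membrane	True	False	False			
P00020	extracellular region	False	True	False			
P00021	lysosome	True	False	False			
P00022	Golgi apparatus	False	False	False			
P00023	plasma membrane	True	False	False			
P00024	lysosome	True	False	True			
P00025	endoplasmic reticulum	True	False	False			
P00026	lysosome	True	False	True			
P00027	lysosome	True	False	False			
P00028	endoplasmic reticulum	True	False	False			
P00029	extracellular region	True	False	True			
P00030	extracellular region	True	False	False			
P00031	extracellular region	False	False	False			
P00032	plasma membrane	True	False	False			
P00033	endoplasmic reticulum	True	False	False			
P00034	endoplasmic reticulum	True	False	False			
P00035	plasma membrane	True	False	False			
P00036	extracellular region	True	False	True			
P00037	Golgi apparatus	True	False	True			
P00038	endoplasmic reticulum	False	False	False			
P00039	Golgi apparatus	False	False	False			
P00040	Golgi apparatus	True	False	False			
P00041	extracellular region	True	False	False			
P00042	plasma membrane	True	False	False			
P00043	plasma membrane	True	False	False			
P00044	plasma membrane	True	False	False			
P00045	plasma membrane	True	False	False			
P00046	Golgi apparatus	False	True	True			
P00047	extracellular region	True	False	False			
P00048	endoplasmic reticulum	True	False	True			
P00049	Golgi apparatus	True	False	False			
P00050	plasma membrane	True	False	False			
P00051	mitochondrion	False	False	False			
P00052	mitochondrion	False	False	False			
P00053	mitochondrion	False	False	False			
P00054	mitochondrion	False	False	False			
P00055	mitochondrion	False	False	False			
P00056	mitochondrion	False	False	False			
P00057	mitochondrion	False	False	False			
P00058	mitochondrion	False	False	False			
P00059	mitochondrion	False	False	False			
P00060	mitochondrion	False	False	False			
P00061	mitochondrion	False	False	False			
P00062	mitochondrion	False	False	False			
P00063	mitochondrion	False	False	False			
P00064	mitochondrion	False	False	False			
P00065	mitochondrion	False	False	False			
P00066	mitochondrion	False	False	False			
P00067	mitochondrion	False	False	False			
P00068	mitochondrion	False	False	False			
P00069	mitochondrion	False	False	False			
P00070	mitochondrion	False	False	False			
P00071	mitochondrion	False	False	False			
P00072	mitochondrion	False	False	False			
P00073	mitochondrion	False	False	False			
P00074	mitochondrion	False	False	False			
P00075	mitochondrion	False	False	False			
P00076	mitochondrion	False	False	False			
P00077	mitochondrion	False	False	False			
P00078	mitochondrion	False	False	False			
P00079	mitochondrion	False	False	False			
P00080	mitochondrion	False	False	False			
P00081	nucleus	False	False	False			
P00082	nucleus	False	False	False			
P00083	cytosol	False	False	False			
P00084	nucleus	False	False	False			
P00085	nucleus	False	False	False			
P00086	cytosol	False	False	False			
P00087	nucleus	False	False	False			
P00088	nucleus	False	False	False			
P00089	nucleus	False	False	False			
P00090	nucleus	False	False	False			
P00091	cytosol	False	False	False			
P00092	cytosol	False	False	False			
P00093	nucleus	False	False	False			
P00094	cytosol	False	False	False			
P00095	cytosol	False	False	False			
P00096	cytosol	False	False	False			
P00097	nucleus	False	False	False			
P00098	cytosol	False	False	False			
P00099	nucleus	False	False	False			
P00100	nucleus	False	False	False			
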