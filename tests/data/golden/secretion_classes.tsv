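protein	secretion_class	signal_peptide	ups_predicted	transmembrane
P00001	intracellular_other	False	False	False
P00002	signal_peptide	True	False	False
P00003	signal_peptide	True	False	False
P00004	signal_peptide	True	False	False
P00005	signal_peptide	True	False	True
P00006	signal_peptide	True	False	False
P00007	signal_peptide	True	False	False
P00008	ups_predicted	False	True	False
P00009	signal_peptide	True	False	False
P00010	signal_peptide	True	False	False
P00011	signal_peptide	True	False	False
P00012	signal_peptide	True	False	True
P00013	signal_peptide	True	False	False
P00014	signal_peptide	True	False	False
P00015	signal_peptide	True	False	False
P00016	signal_peptide	True	False	True
P00017	intracellular_other	False	False	False
P00018	signal_peptide	True	False	False
P00019	signal_peptide	True	False	False
P00020	ups_predicted	False	True	False
P00021	signal_peptide	True	False	False
P00022	intracellular_other	False	False	False
P00023	signal_peptide	True	False	False
P00024	signal_peptide	True	False	True
P00025	signal_peptide	True	False	False
P00026	signal_peptide	True	False	True
P00027	signal_peptide	True	False	False
P00028	signal_peptide	True	False	False
P00029	signal_peptide	True	False	True
P00030	signal_peptide	True	False	False
P00031	intracellular_other	False	False	False
P00032	signal_peptide	True	False	False
P00033	signal_peptide	True	False	False
P00034	signal_peptide	True	False	False
P00035	signal_peptide	True	False	False
P00036	signal_peptide	True	False	True
P00037	signal_peptide	True	False	True
P00038	intracellular_other	False	False	False
P00039	intracellular_other	False	False	False
P00040	signal_peptide	True	False	False
P00041	signal_peptide	True	False	False
P00042	signal_peptide	True	False	False
P00043	signal_peptide	True	False	False
P00044	signal_peptide	True	False	False
P00045	signal_peptide	True	False	False
P00046	ups_predicted	False	True	True
P00047	signal_peptide	True	False	False
P00048	signal_peptide	True	False	True
P00049	signal_peptide	True	False	False
P00050	signal_peptide	True	False	False
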