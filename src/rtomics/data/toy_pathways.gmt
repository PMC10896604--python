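TOY_PATHWAY_0	synthetic toy pathway 0 (fictional)	PROT0000	PROT0001	PROT0002	PROT0003	PROT0004	PROT0005	PROT0006	PROT0007	PROT0008	PROT0009	MET0000	MET0001	MET0002	MET0003	MET0004
TOY_PATHWAY_1	synthetic toy pathway 1 (fictional)	PROT0010	PROT0011	PROT0012	PROT0013	PROT0014	PROT0015	PROT0016	PROT0017	PROT0018	PROT0019	MET0005	MET0006	MET0007	MET0008	MET0009
TOY_PATHWAY_2	synthetic toy pathway 2 (fictional)	PROT0020	PROT0021	PROT0022	PROT0023	PROT0024	PROT0025	PROT0026	PROT0027	PROT0028	PROT0029	MET0010	MET0011	MET0012	MET0013	MET0014
TOY_PATHWAY_3	synthetic toy pathway 3 (fictional)	PROT0030	PROT0031	PROT0032	PROT0033	PROT0034	PROT0035	PROT0036	PROT0037	PROT0038	PROT0039	MET0015	MET0016	MET0017	MET0018	MET0019
TOY_PATHWAY_4	synthetic toy pathway 4 (fictional)	PROT0040	PROT0041	PROT0042	PROT0043	PROT0044	PROT0045	PROT0046	PROT0047	PROT0048	PROT0049	MET0020	MET0021	MET0022	MET0023	MET0024
TOY_PATHWAY_5	synthetic toy pathway 5 (fictional)	PROT0050	PROT0051	PROT0052	PROT0053	PROT0054	PROT0055	PROT0056	PROT0057	PROT0058	PROT0059	MET0025	MET0026	MET0027	MET0028	MET0029
TOY_PATHWAY_6	synthetic toy pathway 6 (fictional)	PROT0060	PROT0061	PROT0062	PROT0063	PROT0064	PROT0065	PROT0066	PROT0067	PROT0068	PROT0069	MET0030	MET0031	MET0032	MET0033	MET0034
TOY_PATHWAY_7	synthetic toy pathway 7 (fictional)	PROT0070	PROT0071	PROT0072	PROT0073	PROT0074	PROT0075	PROT0076	PROT0077	PROT0078	PROT0079	MET0035	MET0036	MET0037	MET0038	MET0039
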