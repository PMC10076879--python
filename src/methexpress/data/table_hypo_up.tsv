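Probe_ID	Gene	beta_case_avg	beta_control_avg	beta_change	RELATION_TO_CPG_ISLAND	log2FoldChange	padj
cg24587601	CASS4	0.137575599	0.72258402	0.58500842		1.77916735	0.01566374
cg01329005	BST2	0.108425528	0.63957445	0.531148922		2.95333954	1.53E-05
cg13214190	PIK3CG	0.329104785	0.81439809	0.485293304	N_Shelf	1.75014039	0.01724619
cg13718960	RNASE1	0.327354776	0.79572139	0.468366613		2.68147978	1.05E-05
cg20986996	TCF21	0.211925743	0.67962279	0.467697044	N_Shore	6.09318374	5.74E-12
cg00123072	THBS4	0.453287548	0.88810567	0.434818118	N_Shore	2.15240829	0.00020269
cg26928972	CSTA	0.348577804	0.7816603	0.433082493		5.87099798	8.69E-13
cg15338159	FHL2	0.412303334	0.82354861	0.411245276		3.14284341	0.00012948
cg19876649	MYOM1	0.399121642	0.75975417	0.360632532		2.51276745	3.61E-05
cg13661129	NR5A1	0.469142795	0.82427195	0.355129158	S_Shelf	8.7981021	5.00E-19
cg24315815	PLSCR4	0.311694902	0.66008554	0.348390633	S_Shore	1.857896	0.01098051
cg04413226	FMO1	0.436500059	0.78104022	0.344540159		3.61678571	4.07E-09
cg01089639	JAK3	0.348527172	0.66969015	0.32116298	S_Shore	2.04877678	0.01319003
cg18525352	NUAK1	0.055519124	0.37199013	0.316471009	S_Shore	1.83605399	0.00401288
cg26683398	LTC4S	0.302200139	0.61640078	0.314200641	N_Shelf	3.06959132	4.57E-05
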