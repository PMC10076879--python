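Probe_ID	Gene	beta_case_avg	beta_control_avg	beta_change	RELATION_TO_CPG_ISLAND	log2FoldChange	padj
cg06738242	TWIST2	0.554053551	0.15610387	0.397949684	Island	-2.6571473	0.00015233
cg23210268	GREM2	0.699915101	0.30227628	0.397638816		-3.3286895	0.00018973
cg15188268	ADAMTS19	0.817201563	0.43219189	0.385009671	N_Shore	-3.6976664	6.26E-05
cg09386458	QPCT	0.886765946	0.51097633	0.375789613	N_Shore	-2.1138241	0.00406449
cg23037932	KIR3DX1	0.815017046	0.45292026	0.362096786		-4.7201206	0.00906221
cg22920700	OSR2	0.579597099	0.22700124	0.352595857	N_Shore	-1.7278745	0.02790383
cg01352551	SLC24A3	0.793752782	0.46820021	0.325552568	N_Shore	-1.5072888	0.03022538
cg23719157	STRA6	0.78738477	0.46561667	0.321768098		-2.4999297	0.01348782
cg13213527	ZNF516	0.775537145	0.45945426	0.316082885		-1.9614117	0.00040565
cg16549596	SFN	0.649653471	0.33389726	0.315756214	N_Shore	-2.9059607	0.00244178
cg04555941	HPGD	0.417078247	0.11941307	0.297665176	S_Shore	-2.5526777	0.00058597
cg00335591	TMEM184A	0.857047129	0.56488322	0.292163912		-1.8289676	0.04205992
cg25338972	ESR1	0.515218373	0.22405393	0.291164441		-2.5746547	0.00330811
cg13468624	PSORS1C3	0.694573016	0.41112169	0.283451322	N_Shore	-2.0015838	0.03245501
cg02992645	OVGP1	0.796760034	0.53732872	0.259431316		-2.9074884	0.00245663
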