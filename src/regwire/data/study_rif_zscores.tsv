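probe_set	gene	rif1_z	rif2_z
Ssc.10025.3.S1_at	CEBPD	-3.152	-0.017
Ssc.1012.1.S1_at	ZNF277	-1.251	2.751
Ssc.10128.1.A1_at	SIX4	-2.986	3.127
Ssc.13567.1.A1_at	ZHX2	-0.921	3.454
Ssc.14573.1.S1_at	EYA2	-2.907	3.048
Ssc.16976.1.S1_at	SREBF2	-0.970	2.533
Ssc.19163.1.S1_at	MXI1	-1.860	3.443
Ssc.19313.1.A1_at	MAX	-3.270	-1.671
Ssc.19537.1.S1_at	IRF2	-2.701	-0.615
Ssc.2001.1.A1_at	LHX6	-1.383	-2.847
Ssc.21096.1.S1_at	PAX2	-0.895	2.378
Ssc.22470.1.S1_at	PER3	-2.258	0.824
Ssc.23498.1.S1_s_at	MSTN	-1.930	2.582
Ssc.24606.1.A1_a_at	PPARGC1B	-2.896	0.167
Ssc.26039.1.S1_at	RORA	-3.597	1.736
Ssc.2719.1.A1_at	MTA3	-1.805	-2.555
Ssc.27410.1.S1_at	MYCN	-2.823	-0.783
Ssc.27576.1.S1_at	MN1	-2.263	-0.086
Ssc.27622.1.S1_at	KLF11	-3.789	2.701
Ssc.27964.2.S1_at	GATA3	0.063	-2.061
Ssc.29855.1.A1_at	CDCA7	-2.346	0.220
Ssc.30288.1.A1_at	GRHL3	0.489	-2.038
Ssc.30799.1.A1_at	DACH1	0.772	-2.329
Ssc.3355.1.S1_at	HDAC1	0.747	-1.971
Ssc.4212.1.A1_at	ELK3	-2.349	-1.032
Ssc.6697.1.S1_at	SOX4	-3.143	-0.718
Ssc.8529.1.A1_at	ZFP36L1	-3.282	1.299
Ssc.9136.1.S1_at	CCRN4L	-1.056	-2.354
Ssc.9298.1.A1_at	IRX3	-2.538	-0.692
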