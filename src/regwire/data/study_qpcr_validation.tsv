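gene	ratio_microarray	pp_microarray	ratio_qpcr	p_qpcr	r	p_r
IGF2	4.88	0.00001	2.95	0.0001	0.796	0.0001
KERA	3.41	0.00001	2.41	0.0009	0.889	0.0001
FMOD	3.35	0.00006	2.78	0.0048	0.764	0.0001
COL1A1	2.18	0.00082	2.15	0.0060	0.540	0.0030
FBN2	1.88	0.00009	1.76	0.012	0.744	0.0001
AEBP1	1.81	0.00111	2.00	0.019	0.832	0.0001
LOX	1.72	0.00071	1.58	0.019	0.506	0.0084
FKBP14	1.72	0.00005	1.60	0.025	0.794	0.0001
PSMD11	0.73	0.00541	0.65	0.046	0.444	0.0229
ALOX5AP	0.70	0.00139	0.78	0.128	0.189	0.3331
CASP4	0.64	0.00216	0.54	0.084	0.869	0.0001
ELOVL6	0.64	0.00114	1.11	0.561	0.086	0.6616
NFKBIZ	0.59	0.00369	0.82	0.358	0.502	0.0065
ME1	0.50	0.00028	0.57	0.024	0.802	0.0001
PLA1A	0.42	0.00017	0.42	0.074	0.769	0.0001
PON3	0.31	0.00001	0.37	0.001	0.787	0.0001
SCD	0.65	0.15186	0.50	0.030	0.866	0.0001
ELOVL5	1.07	0.28406	1.13	0.433	0.255	0.2089
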