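metric	level	lower	upper
rif1	0.95	-2.155	1.898
rif1	0.99	-3.288	2.754
rif2	0.95	-1.966	2.030
rif2	0.99	-2.594	3.007
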