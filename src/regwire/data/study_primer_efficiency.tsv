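gene	efficiency_pct	amplicon_bp
IGF2	86	151
KERA	89	198
FMOD	93	194
COL1A1	88	164
FBN2	96	201
AEBP1	90	233
LOX	88	223
FKBP14	91	250
PSMD11	91	219
ALOX5AP	94	213
CASP4	97	190
ELOVL6	96	182
NFKBIZ	91	196
ME1	90	213
PLA1A	91	215
PON3	92	142
SCD	90	205
ELOVL5	82	223
DLK1	83	208
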