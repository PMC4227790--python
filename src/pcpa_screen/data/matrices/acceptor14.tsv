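# name: acceptor_3ss_14mer
# 14-position 3' splice-site window: 13 intronic positions (-13..-1) ending in the
# invariant AG, plus the first exonic base (+1). Per-position base frequencies in the
# Shapiro-Senapathy style, compiled from human acceptor-site consensus compositions.
# required: 11=A 12=G
A	C	G	T
0.10	0.31	0.15	0.44
0.09	0.31	0.12	0.48
0.07	0.33	0.10	0.50
0.08	0.35	0.09	0.48
0.09	0.37	0.09	0.45
0.07	0.38	0.09	0.46
0.08	0.40	0.08	0.44
0.09	0.32	0.08	0.51
0.06	0.33	0.06	0.55
0.24	0.28	0.10	0.38
0.04	0.74	0.01	0.21
1.00	0.00	0.00	0.00
0.00	0.00	1.00	0.00
0.28	0.14	0.47	0.11
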