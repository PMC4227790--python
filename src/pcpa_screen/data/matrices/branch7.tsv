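# name: branch_site_7mer
# 7-position branch-site window (yUnAy-style human consensus, branch adenosine at
# position 6). Per-position base frequencies compiled from human branch-point
# consensus compositions; the branch A is strongly preferred but not invariant.
A	C	G	T
0.15	0.31	0.16	0.38
0.12	0.34	0.12	0.42
0.14	0.30	0.15	0.41
0.06	0.12	0.05	0.77
0.22	0.30	0.21	0.27
0.97	0.01	0.01	0.01
0.07	0.40	0.08	0.45
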