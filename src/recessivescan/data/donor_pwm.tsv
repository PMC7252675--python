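# Vertebrate 5' splice-donor base frequencies for positions -3..+6 relative
# to the exon/intron boundary (position +1 = the G of the invariant GT).
# Values are rounded literature consensus frequencies of the kind tabulated
# by Shapiro & Senapathy (1987) for vertebrate donor sites; the +1/+2
# positions use 0.991 rather than 1.0 so log-odds stay finite.
pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.14	0.13
-1	0.08	0.04	0.81	0.07
1	0.003	0.003	0.991	0.003
2	0.003	0.003	0.003	0.991
3	0.60	0.03	0.34	0.03
4	0.71	0.08	0.12	0.09
5	0.06	0.06	0.82	0.06
6	0.16	0.17	0.20	0.47
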