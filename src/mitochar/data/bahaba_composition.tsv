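# Published per-region base composition (%) of the Bahaba taipingensis
# mitogenome (H strand). Columns: region, T, C, A, G, number of bases.
Region	T	C	A	G	N
ND1	25.9	35.3	24.5	14.3	975
ND2	24.6	38.1	25.6	11.7	1046
ND3	26.4	38.1	20.9	14.6	349
ND4	24.6	35	26.1	14.3	1381
ND4L	25.6	38.7	21.9	13.8	297
ND5	26.2	33.4	28.3	12.1	1839
ND6	12.3	35.4	38.3	14	522
COI	29.2	28.7	23	19.1	1557
COII	27.1	28.9	28.5	15.5	691
COIII	28.3	31.2	23.6	16.9	785
ATP6	25.2	38.4	23.4	13	683
ATP8	23.2	33.3	32.8	10.7	168
Cytb	26.8	35	24	14.2	1141
PCG_1st	29.1	30.6	24	16.3	3630
PCG_2nd	21.7	35.1	26.9	16.3	3630
PCG_3rd	28.3	36.2	24.7	10.8	3630
PCG_total	26.4	34	25.2	14.4	10890
tRNA	27.1	22.6	27.4	23.9	1553
rRNA	20.8	26.7	32.2	20.3	2651
D-loop	30.4	22.8	31.6	15.2	826
Overall	25.1	31.4	27.6	15.9	16500
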