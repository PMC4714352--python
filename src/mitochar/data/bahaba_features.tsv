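# Canonical gene arrangement of the Bahaba taipingensis mitogenome (16,500 bp,
# GenBank JX232404). Coordinates are 1-based, both ends inclusive, H-strand sense.
# Three rows are reconciled against the published text where the printed table
# is internally inconsistent: tRNA-Trp is on the H strand (canonical vertebrate
# arrangement; gives the described 8 L-strand tRNAs), ND6 is placed at
# 13802-14323 (printed size 522 and the +4 spacer after ND5 of the published
# intergenic census, rather than the printed start 13794 which would overlap
# ND5 by 4 bp), and the ND2/ND3 stop classes are the ones consistent with
# their coordinate lengths (1045 -> T, 350 -> TA).
Gene	Class	From	To	Strand	StartCodon	StopCodon
tRNA-Phe	tRNA	1	68	H
12S_rRNA	rRNA	69	1017	H
tRNA-Val	tRNA	1018	1090	H
16S_rRNA	rRNA	1091	2792	H
tRNA-Leu_UUR	tRNA	2793	2866	H
ND1	protein_coding	2867	3841	H	ATG	TAG
tRNA-Ile	tRNA	3846	3915	H
tRNA-Gln	tRNA	3915	3985	L
tRNA-Met	tRNA	3985	4054	H
ND2	protein_coding	4055	5099	H	ATG	T
tRNA-Trp	tRNA	5100	5170	H
tRNA-Ala	tRNA	5172	5240	L
tRNA-Asn	tRNA	5243	5315	L
tRNA-Cys	tRNA	5353	5418	L
tRNA-Tyr	tRNA	5419	5488	L
COI	protein_coding	5490	7046	H	ATG	AGA
tRNA-Ser_UCN	tRNA	7042	7112	L
tRNA-Asp	tRNA	7116	7184	H
COII	protein_coding	7193	7883	H	ATG	T
tRNA-Lys	tRNA	7884	7957	H
ATP8	protein_coding	7959	8126	H	ATG	TAA
ATP6	protein_coding	8117	8799	H	ATG	TA
COIII	protein_coding	8800	9584	H	ATG	TA
tRNA-Gly	tRNA	9585	9655	H
ND3	protein_coding	9656	10005	H	ATG	TA
tRNA-Arg	tRNA	10005	10073	H
ND4L	protein_coding	10074	10370	H	ATG	TAA
ND4	protein_coding	10364	11744	H	ATG	T
tRNA-His	tRNA	11745	11813	H
tRNA-Ser_AGY	tRNA	11814	11880	H
tRNA-Leu_CUN	tRNA	11886	11958	H
ND5	protein_coding	11959	13797	H	ATG	TAG
ND6	protein_coding	13802	14323	L	ATG	TAA
tRNA-Glu	tRNA	14316	14384	L
Cytb	protein_coding	14389	15529	H	ATG	T
tRNA-Thr	tRNA	15530	15601	H
tRNA-Pro	tRNA	15605	15674	L
D-loop	control_region	15675	16500	H
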