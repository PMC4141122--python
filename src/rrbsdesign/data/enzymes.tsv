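# rrbsdesign enzyme catalog v1
# Methylation-insensitive (and two reference methylation-sensitive) restriction
# enzymes suitable for RRBS library construction. cut_offset counts the bases
# before the top-strand cut within the recognition site (AG|CT -> 2).
# heat_inactivation_temp_c is empty when the supplier lists none.
name	site	cut_offset	incubation_temp_c	buffer	heat_inactivation_temp_c	methylation_sensitive	catalog_number
AluI	AGCT	2	37	CutSmart	80	No	R0137S
BfaI	CTAG	1	37	CutSmart	80	No	R0568S
HaeIII	GGCC	2	37	CutSmart	80	No	R0108S
HpyCH4V	TGCA	2	37	CutSmart	65	No	R0620S
MluCI	AATT	0	37	CutSmart		No	R0538S
MseI	TTAA	1	37	CutSmart	65	No	R0525S
MspI	CCGG	1	37	CutSmart		No	R0106S
TaqI	TCGA	1	65	CutSmart	80	dam	R0149S
CviQI	GTAC	1	25	NEB 3.1		No	R0639S
CviAII	CATG	1	25	CutSmart	65	No	R0640S
ApeKI	GCWGC	1	75	NEB 3.1		Yes	R0643S
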