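# Tip karyotype states (haploid count n, haploid biarmed count b) for the
# genus-level reconstruction. Focal species carry published values
# (mercatorius 2n=42 with 6 biarmed pairs; mabouia 2n=42 with 7). The two
# Cyrtodactylus tips bracket the genus range 2n=34 (many biarmed) to
# 2n=48 (all acrocentric). Where only 2n is published (turcicus 2n=44,
# the 2n=40 frenatus group), b is fixture metadata: the value implied by
# a fusion-dominated path from the 2n=48 all-acrocentric condition.
label	n	b
Cyrtodactylus_sp_2n48	24	0
Cyrtodactylus_sp_2n34	17	7
Hemidactylus_bowringii	23	1
Hemidactylus_platyurus	23	1
Hemidactylus_turcicus	22	2
Hemidactylus_flavoviridis	20	4
Hemidactylus_brookii	20	4
Hemidactylus_fasciatus	20	4
Hemidactylus_frenatus	20	4
Hemidactylus_mabouia	21	7
Hemidactylus_mercatorius	21	6
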