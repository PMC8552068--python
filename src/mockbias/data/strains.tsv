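name	kctc	accession	n_contigs	genome_gc	sixteen_s_copies	genome_size_mb
L. acidophilus	KCTC 3164	GCA_003047065.1	1	34.7	4	2.00997
L. fermentum	KCTC 3112	GCA_000010145.1	1	51.5	5	2.09868
L. gasseri	KCTC 3163	GCA_000014425.1	1	35.3	6	1.89436
L. paracasei subsp. paracasei	KCTC 3510	GCA_000829035.1	3	46.6	5	3.01780
L. reuteri	KCTC 3594	GCA_000010005.1	1	38.9	6	2.03941
B. animalis subsp. lactis	KCTC 5854	GCA_000022965.1	1	60.5	4	1.93269
B. breve	KCTC 3220	GCA_900637145.1	1	58.9	3	2.26941
L. lactis	KCTC 3769	ATCC_19435	3	35.4	6	2.62782
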