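# Published per-strain sequence-read ratios (percent), as printed in the
# source study's results text. Only the strains called out there are
# available; mocks B and F are complete two-member profiles.
platform	region	mock	strain	percent
MiSeq	V1-V2	A	L. acidophilus	8.83
MiSeq	V3	A	L. acidophilus	8.64
MiSeq	V4	A	L. acidophilus	7.76
MiSeq	V1-V3	A	L. acidophilus	6.59
MiSeq	V1-V2	A	L. gasseri	26.43
MiSeq	V3	A	L. gasseri	22.87
MiSeq	V4	A	L. gasseri	29.29
MiSeq	V1-V3	A	L. gasseri	27.71
MiSeq	V1-V2	B	B. animalis subsp. lactis	53.55
MiSeq	V3	B	B. animalis subsp. lactis	55.15
MiSeq	V4	B	B. animalis subsp. lactis	74.1
MiSeq	V1-V3	B	B. animalis subsp. lactis	84.21
MiSeq	V1-V2	B	B. breve	46.45
MiSeq	V3	B	B. breve	44.85
MiSeq	V4	B	B. breve	25.9
MiSeq	V1-V3	B	B. breve	15.79
MiSeq	V1-V2	C	L. acidophilus	5.54
MiSeq	V3	C	L. acidophilus	5.29
MiSeq	V4	C	L. acidophilus	4.8
MiSeq	V1-V3	C	L. acidophilus	2.26
MiSeq	V1-V2	C	L. lactis	27.46
MiSeq	V3	C	L. lactis	27.5
MiSeq	V4	C	L. lactis	31.61
MiSeq	V1-V3	C	L. lactis	40.88
MiSeq	V1-V2	D	B. breve	29.35
MiSeq	V3	D	B. breve	20.88
MiSeq	V4	D	B. breve	15.57
MiSeq	V1-V3	D	B. breve	9.16
MiSeq	V1-V2	D	L. lactis	35.61
MiSeq	V3	D	L. lactis	49.88
MiSeq	V4	D	L. lactis	53.05
MiSeq	V1-V3	D	L. lactis	52.74
MiSeq	V1-V2	E	L. acidophilus	15.66
MiSeq	V3	E	L. acidophilus	15.46
MiSeq	V4	E	L. acidophilus	14.85
MiSeq	V1-V3	E	L. acidophilus	7.32
MiSeq	V1-V2	E	L. reuteri	9.14
MiSeq	V3	E	L. reuteri	10.11
MiSeq	V4	E	L. reuteri	9.93
MiSeq	V1-V3	E	L. reuteri	7.11
MiSeq	V1-V2	F	B. animalis subsp. lactis	61.74
MiSeq	V3	F	B. animalis subsp. lactis	63.12
MiSeq	V4	F	B. animalis subsp. lactis	75.91
MiSeq	V1-V3	F	B. animalis subsp. lactis	85.23
MiSeq	V1-V2	F	B. breve	38.26
MiSeq	V3	F	B. breve	36.88
MiSeq	V4	F	B. breve	24.09
MiSeq	V1-V3	F	B. breve	14.77
MiSeq	V1-V2	G	L. acidophilus	1.89
MiSeq	V3	G	L. acidophilus	2.74
MiSeq	V4	G	L. acidophilus	2.87
MiSeq	V1-V3	G	L. acidophilus	1.14
MiSeq	V1-V2	G	L. lactis	23.59
MiSeq	V3	G	L. lactis	32.13
MiSeq	V4	G	L. lactis	34.56
MiSeq	V1-V3	G	L. lactis	35.35
MiSeq	V1-V2	H	L. acidophilus	3.08
MiSeq	V3	H	L. acidophilus	3.96
MiSeq	V4	H	L. acidophilus	4.06
MiSeq	V1-V3	H	L. acidophilus	1.33
MiSeq	V1-V2	H	L. lactis	15.12
MiSeq	V3	H	L. lactis	21.96
MiSeq	V4	H	L. lactis	23.81
MiSeq	V1-V3	H	L. lactis	27.46
IonTorrent	V1-V2	A	L. acidophilus	7.12
IonTorrent	V3	A	L. acidophilus	7.38
IonTorrent	V4	A	L. acidophilus	6.82
IonTorrent	V1-V3	A	L. acidophilus	12.78
IonTorrent	V1-V2	A	L. gasseri	21.18
IonTorrent	V3	A	L. gasseri	20.21
IonTorrent	V4	A	L. gasseri	28.5
IonTorrent	V1-V3	A	L. gasseri	40.74
IonTorrent	V4	B	B. animalis subsp. lactis	57.06
IonTorrent	V4	B	B. breve	42.94
IonTorrent	V1-V2	C	L. acidophilus	4.57
IonTorrent	V3	C	L. acidophilus	4.42
IonTorrent	V4	C	L. acidophilus	4.1
IonTorrent	V1-V3	C	L. acidophilus	6.72
IonTorrent	V1-V2	C	L. lactis	26.32
IonTorrent	V3	C	L. lactis	30.64
IonTorrent	V4	C	L. lactis	35.2
IonTorrent	V1-V3	C	L. lactis	45.57
IonTorrent	V1-V2	D	B. animalis subsp. lactis	12.25
IonTorrent	V3	D	B. animalis subsp. lactis	18.8
IonTorrent	V4	D	B. animalis subsp. lactis	20.46
IonTorrent	V1-V3	D	B. animalis subsp. lactis	11.23
IonTorrent	V1-V2	D	L. lactis	73.26
IonTorrent	V3	D	L. lactis	60.74
IonTorrent	V4	D	L. lactis	65.64
IonTorrent	V1-V3	D	L. lactis	75.93
IonTorrent	V1-V2	E	L. acidophilus	15.88
IonTorrent	V3	E	L. acidophilus	13.63
IonTorrent	V4	E	L. acidophilus	13.13
IonTorrent	V1-V3	E	L. acidophilus	25.43
IonTorrent	V1-V2	E	L. gasseri	25.51
IonTorrent	V3	E	L. gasseri	23.28
IonTorrent	V4	E	L. gasseri	33.03
IonTorrent	V1-V3	E	L. gasseri	43.12
IonTorrent	V1-V2	F	B. animalis subsp. lactis	55.27
IonTorrent	V3	F	B. animalis subsp. lactis	57.32
IonTorrent	V4	F	B. animalis subsp. lactis	66.81
IonTorrent	V1-V3	F	B. animalis subsp. lactis	56.51
IonTorrent	V1-V2	F	B. breve	44.73
IonTorrent	V3	F	B. breve	42.68
IonTorrent	V4	F	B. breve	33.19
IonTorrent	V1-V3	F	B. breve	43.49
IonTorrent	V1-V2	G	L. acidophilus	2.36
IonTorrent	V3	G	L. acidophilus	2.31
IonTorrent	V4	G	L. acidophilus	2.2
IonTorrent	V1-V3	G	L. acidophilus	3.14
IonTorrent	V1-V2	G	L. lactis	34.66
IonTorrent	V3	G	L. lactis	39.92
IonTorrent	V4	G	L. lactis	44.59
IonTorrent	V1-V3	G	L. lactis	53.23
IonTorrent	V1-V2	H	L. acidophilus	3.96
IonTorrent	V3	H	L. acidophilus	3.45
IonTorrent	V4	H	L. acidophilus	3.55
IonTorrent	V1-V3	H	L. acidophilus	5.32
IonTorrent	V1-V2	H	L. lactis	19.13
IonTorrent	V3	H	L. lactis	25.31
IonTorrent	V4	H	L. lactis	27.43
IonTorrent	V1-V3	H	L. lactis	36.62
MGIseq-2000	V3	A	L. acidophilus	8.35
MGIseq-2000	V3	C	L. acidophilus	10.25
MGIseq-2000	V3	E	L. acidophilus	6.83
MGIseq-2000	V3	G	L. acidophilus	2.57
MGIseq-2000	V3	H	L. acidophilus	3.98
MGIseq-2000	V3	A	L. reuteri	27.27
MGIseq-2000	V3	E	L. reuteri	28.37
MGIseq-2000	V3	G	L. reuteri	10.6
MGIseq-2000	V3	H	L. reuteri	15.36
SequelII	V1-V9	A	L. fermentum	3.96
SequelII	V1-V9	C	L. fermentum	1.41
SequelII	V1-V9	E	L. fermentum	5.06
SequelII	V1-V9	G	L. fermentum	0.62
SequelII	V1-V9	H	L. fermentum	1.4
SequelII	V1-V9	C	L. lactis	50.57
SequelII	V1-V9	D	L. lactis	55.03
SequelII	V1-V9	G	L. lactis	59.05
SequelII	V1-V9	H	L. lactis	43.0
MinION	V1-V9	A	L. fermentum	3.27
MinION	V1-V9	C	L. fermentum	1.51
MinION	V1-V9	E	L. fermentum	4.71
MinION	V1-V9	G	L. fermentum	0.37
MinION	V1-V9	H	L. fermentum	0.9
MinION	V1-V9	C	L. lactis	55.8
MinION	V1-V9	D	L. lactis	66.35
MinION	V1-V9	G	L. lactis	58.75
MinION	V1-V9	H	L. lactis	42.97
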