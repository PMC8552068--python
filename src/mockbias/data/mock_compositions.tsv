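mock	strain	percent
A	L. acidophilus	18.6
A	L. fermentum	18.45
A	L. gasseri	17.48
A	L. paracasei subsp. paracasei	20.18
A	L. reuteri	25.3
B	B. animalis subsp. lactis	46.55
B	B. breve	53.45
C	L. acidophilus	16.62
C	L. fermentum	16.79
C	L. gasseri	15.98
C	L. paracasei subsp. paracasei	18.16
C	L. reuteri	15.32
C	L. lactis	17.13
D	B. animalis subsp. lactis	30.73
D	B. breve	35.14
D	L. lactis	34.13
E	L. acidophilus	33.41
E	L. fermentum	26.73
E	L. gasseri	19.12
E	L. paracasei subsp. paracasei	14.57
E	L. reuteri	6.16
F	B. animalis subsp. lactis	56.64
F	B. breve	43.36
G	L. acidophilus	8.11
G	L. fermentum	8.08
G	L. gasseri	7.78
G	L. paracasei subsp. paracasei	8.88
G	L. reuteri	7.53
G	B. animalis subsp. lactis	16.99
G	B. breve	19.43
G	L. lactis	23.21
H	L. acidophilus	12.56
H	L. fermentum	12.51
H	L. gasseri	11.96
H	L. paracasei subsp. paracasei	13.63
H	L. reuteri	11.58
H	B. animalis subsp. lactis	11.55
H	B. breve	13.3
H	L. lactis	12.91
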