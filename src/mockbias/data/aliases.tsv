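# Known classifier misassignments: reported label -> canonical strain.
# region column records where the confusion was observed (informational).
reported	canonical	region
L. zeae	L. paracasei subsp. paracasei	V3/V4
B. pseudolongum	B. animalis subsp. lactis	V3
GQ156395s	L. fermentum	V4
CP006809s	L. gasseri	V4
L. panis	L. reuteri	V4
B. longum	B. breve	V4
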