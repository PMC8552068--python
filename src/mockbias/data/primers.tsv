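platform	name	sequence	purpose
QX200	337F	GACTCCTACGGGAGGCWGCAG	ddPCR quantification
QX200	518R	CGTATTACCGCGGCTGCTGG	ddPCR quantification
MiSeq	MiSeq_27F	TCGTCGGCAGCGTC-AGATGTGTATAAGAGACAG-AGAGTTTGATCMTGGCTCAG	amplicon
MiSeq	MiSeq_bif27F	TCGTCGGCAGCGTC-AGATGTGTATAAGAGACAG-GGGTTCGATTCTGGCTCAG	amplicon
MiSeq	MiSeq_337R	GTCTCGTGGGCTCGG-AGATGTGTATAAGAGACAG-CTGCWGCCTCCCGTAGGAGTC	amplicon
MiSeq	MiSeq_337F	TCGTCGGCAGCGTC-AGATGTGTATAAGAGACAG-GACTCCTACGGGAGGCWGCAG	amplicon
MiSeq	MiSeq_518R	GTCTCGTGGGCTCGG-AGATGTGTATAAGAGACAG-CGTATTACCGCGGCTGCTGG	amplicon
MiSeq	MiSeq_518F	TCGTCGGCAGCGTC-AGATGTGTATAAGAGACAG-CCAGCAGCCGCGGTAATACG	amplicon
MiSeq	MiSeq_800R	GTCTCGTGGGCTCGG-AGATGTGTATAAGAGACAG-TACCAGGGTATCTAATCC	amplicon
IonTorrent	27F	AGAGTTTGATCMTGGCTCAG	amplicon
IonTorrent	bif27F	GGGTTCGATTCTGGCTCAG	amplicon
IonTorrent	337R	CTGCWGCCTCCCGTAGGAGTC	amplicon
IonTorrent	337F	GACTCCTACGGGAGGCWGCAG	amplicon
IonTorrent	518R	CGTATTACCGCGGCTGCTGG	amplicon
IonTorrent	518F	CCAGCAGCCGCGGTAATACG	amplicon
IonTorrent	800R	TACCAGGGTATCTAATCC	amplicon
MGIseq-2000	337F	GACTCCTACGGGAGGCWGCAG	amplicon
MGIseq-2000	518R	CGTATTACCGCGGCTGCTGG	amplicon
SequelII/MinION	27F	AGAGTTTGATCMTGGCTCAG	amplicon
SequelII/MinION	bif27F	GGGTTCGATTCTGGCTCAG	amplicon
SequelII/MinION	1492R	TACGGYTACCTTGTTACGACTT	amplicon
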