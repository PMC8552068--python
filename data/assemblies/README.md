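# Local assembly store

The genome-level checks (genome GC%, annotated 16S rRNA feature counts,
in-silico V3 amplicon lengths) read plain-text assembly files from this
directory, named `<accession>.fna` and `<accession>.gff`.

Populate it once, with network access, from the repository root:

    python scripts/fetch_assemblies.py

which downloads GCA_003047065.1, GCA_000010005.1, GCA_000022965.1 and
GCA_900637145.1 from the NCBI Datasets API. Without these files the
genome-level acceptance tests fail with a pointer here, and
`scripts/acceptance.py` omits the corresponding targets.
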