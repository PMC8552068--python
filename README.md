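# mockbias

Bias assessment of 16S rRNA amplicon community profiling against mock
communities designed from droplet-digital-PCR (ddPCR) quantified genomic
DNA.

The package covers the full desk-side workflow:

- **`mockbias.ddpcr_quant`** — Poisson-corrected absolute quantification
  from droplet counts (`lambda = -ln(1 - p)`), dilution correction and
  replicate summaries.
- **`mockbias.mock_design`** — expected ("original") mock composition from
  copy concentrations, mixing volumes and per-genome 16S copy numbers;
  ships the eight reference mock designs (A–H) as packaged fixtures.
- **`mockbias.insilico_amplicon`** — degenerate-primer in-silico PCR over
  16S gene sequences (IUPAC-aware, ≤ *k* mismatches), primer-excluded
  amplicon lengths and GC, genome GC, 16S feature counting from GFF3 /
  GenBank annotations.
- **`mockbias.profile_io`** — ingestion of classified-read count tables
  (mothur `shared` dialect or plain TSV), rarefaction to fixed depth
  (hypergeometric, seeded), misclassification-alias folding, conversion to
  community profiles.
- **`mockbias.bias_metrics`** — per-strain relative difference
  `d_i = (observed_i − original_i) / original_i`, the strict ±0.5
  representation rule, and the Bias Index
  `BI = sqrt(Σ d_i² / (N − 1))`, plus BI matrices over mock × platform/region
  and the published sequence-read-ratio fixture tables.
- **`mockbias.profile_compare`** — covariance PCA (reproducible sign
  convention) and agglomerative Euclidean clustering with an exact-subtree
  query and Newick export.
- **`mockbias.synthetic_community`** — simulator: multiplicative per-strain
  amplification bias, multinomial sampling at fixed depth, optional
  row-stochastic taxonomic confusion, and bias-factor recovery.
- **`mockbias.pipeline` / `mockbias.cli`** — end-to-end runs from one YAML
  config with provenance-stamped TSV/Newick outputs.

## CLI

`mockbias` exposes one subcommand per stage:

```sh
mockbias ddpcr droplets.tsv --dilution 1e4        # copies/uL from droplet counts
mockbias design --fixture B                       # packaged mock design
mockbias design --mix-sheet mix.tsv               # design from a mix sheet
mockbias amplicon genes.fasta --region V3         # in-silico PCR
mockbias profile counts.tsv --depth 10000 --seed 1 --aliases
mockbias bias --original B --observed counts.tsv  # d_i, labels, BI
mockbias compare profiles.tsv --linkage average   # PCA + dendrogram
mockbias simulate scenario.yaml                   # synthetic count tables
mockbias run --config run.yaml --seed 1           # full pipeline
```

A run config names the originals (fixture ids A–H or files), the observed
sources (count tables or simulation scenarios), and options (depth, seed,
threshold, linkage, aliases); see `tests/test_pipeline.py` for examples.

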