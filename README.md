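# twinase

Allele-specific expression (ASE) analysis for twin-pair RNA-seq.

Monozygotic co-twins share a germline genome, so any within-pair disparity in
which allele of a heterozygous site is expressed points at post-zygotic or
epigenetic processes: random monoallelic expression, genomic imprinting,
X-chromosome inactivation (XCI), A-to-I(G) RNA editing, or a discordant
karyotype such as trisomy 21 in one co-twin. `twinase` takes per-site allele
read-count tables (the GATK ASEReadCounter TSV dialect, one file per
sequencing run) and quantifies, classifies and cross-references that
disparity end to end. It is aimed at researchers analysing twin (or any
paired-sample) RNA-seq allele counts who want a transparent, fully tested
implementation of the downstream statistics.

## The statistics at its core

For a heterozygous site with reference and alternative read counts
*n*<sub>ref</sub>, *n*<sub>alt</sub>:

- **ASE statistic** — `ASE = |0.5 − n_ref / (n_ref + n_alt)|` ∈ [0, 0.5]:
  0 at perfect 1:1 expression, 0.5 at strict monoallelism. Replicate runs are
  amalgamated per site with a first-quartile (Q1, type-7) summary of per-run
  ASE values; sites need ≥ 12 reads to be called informative.
- **Pattern classification** — strictly monoallelic (minor allele absent),
  biallelic imbalance (exact two-sided binomial test against p = 0.5,
  α = 0.05), or biallelic.
- **Within-pair comparison** — a shared site is *discordant* when exactly one
  co-twin is monoallelic; magnitude shifts are measured by
  `LogASE = log2(ASE_A / ASE_B)` with ±0.8 flagged as altered.
- **Gene heterogeneity** — per gene with k eSNVs, the chi-square homogeneity
  Q of per-site reference-allele proportions (binomial weights) gives
  `I² = max(0, 100·(Q − df)/Q)`, ranked homogeneous (< 30), moderate
  (30–50), substantial (50–75) or considerable (≥ 75).
- **e-karyotyping** — per chromosome, the summed binomial log-likelihood
  ratio of minor-allele fraction 1/3 versus 1/2 over biallelic sites calls
  trisomy-like chromosomes (an extra copy shifts heterozygous sites toward
  1/3 : 2/3).
- **RNA-editing discordance** — sites matching a canonical A-to-I(G) catalog
  (A>G on +, T>C on −, repeat-masked) get editing levels `G/(A+G)` per twin;
  within-pair level gaps > 25 percentage points are discordant, and twin
  levels are related by an OLS linear model on the percent scale.
- **Cross-referencing** — gene-wide monoallelic genes with ≥ 8 eSNVs against
  an imprinting catalog (candidates when uncatalogued), XCI reports for
  non-escapee genes with ≥ 2 discordant eSNVs, pathogenic-allele expression
  modes, and mitochondrial microheteroplasmy.

A truth-labelled synthetic twin-pair generator (`twinase.simulate`) emits
count tables, a gene model GTF and all catalogs with known ground truth, so
every stage is testable without any download.

## Worked example

Simulate a heterokaryotypic pair (trisomy 21 in twin A, 5,000 sites, 2.7%
injected discordance) and run the full pipeline:

```sh
twinase simulate --seed 42 --n-sites 5000 --trisomy-chrom chr21 --outdir demo
twinase run-all --manifest demo/manifest.yaml
```

Key excerpts from the printed report:

```json
"pair_summary": { "n_shared_sites": 5000, "n_discordant": 132, "pct_discordant": 2.64 },
"aneuploidy_calls": { "twinA": ["chr21"], "twinB": [] },
"editing": { "n_matched": 96,
             "discordance_counts": { "concordant": 88, "level_discordant": 6,
                                     "pattern_discordant": 2 } },
"crossref": { "known_imprinted": { "twinA": ["IMP_1", "IMP_2", "IMP_3"] } }
```

Reading: 2.64% of the 5,000 shared sites switched expression pattern between
the co-twins (the injected rate was 2.7%); the extra chromosome 21 was called
in twin A only; 96 shared sites matched the editing catalog, 8 of them
discordant; and the three planted imprinted genes were recovered from twin
A's all-monoallelic ≥ 8-eSNV genes. Stage tables (per-site TSVs, gene I²
table, e-karyotype profile, editing table, XCI/pathogenic/mitochondrial
reports) are written under `demo/results/`.

The same stages are available as library functions
(`twinase.call_ase_sites`, `twinase.pair_sites`, `twinase.gene_summary`,
`twinase.detect_aneuploidy`, `twinase.match_editing_sites`, …) and as
stagewise subcommands (`call-ase`, `compare`, `heterogeneity`,
`ekaryotype`, `editing`, `crossref`).

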