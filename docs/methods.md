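# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `twinase`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute themselves.

## Per-site ASE model

Each observed site carries reference/alternative read counts from one
sequencing run. A site is *informative* at total depth ≥ `min_depth`
(default 12 reads) — below that, the binomial test has essentially no power
and monoallelism cannot be distinguished from sampling dropout.

Replicate runs of one individual are amalgamated per site. The default
(`q1_of_ase`) computes per-run ASE values and reports their first quartile
under the type-7 (linear-interpolation) definition; the reported counts are
those of the run whose ASE lies closest to that quartile (ties broken by run
order), so downstream tests always operate on a realisable count pair. The
Q1 summary is deliberately conservative: it leans toward the more balanced
replicates, damping single-run artifacts. A `sum_counts` mode (pooling reads
across runs) is offered as an alternative; outputs record the method used.
With a single informative run, both modes pass that run through unchanged.
The significance test runs on the aggregated counts, and `n_support` records
how many runs contributed.

The statistic `ASE = |0.5 − n_ref/(n_ref+n_alt)|` measures departure from
1:1 allelic expression: 0 iff the counts are equal, 0.5 iff one allele is
absent. Significance of imbalance is an exact two-sided binomial test at
p = 0.5. Because the null is symmetric, the pmf of outcome *i* is
proportional to the integer C(n, i); the implementation sums all outcomes
whose coefficient does not exceed the observed one, in exact integer
arithmetic. This removes floating-point tie ambiguity entirely — the test
suite checks agreement with full enumeration to 1e−12 for every count pair
up to depth 40, and with `scipy.stats.binomtest` as an independent route.

Patterns: MONOALLELIC when the minor allele has ≤ `mono_minor_max` reads
(default 0 — the strictest reading of "strictly monoallelic"; raise it to
tolerate sequencing noise); else BIALLELIC_IMBALANCE when the binomial p
falls below `alpha` (default 0.05, uncorrected); else BIALLELIC. Raw
per-site p-values are the default because the headline discordance
definition is pattern-based, not significance-count-based; users needing
family-wise control can apply Benjamini–Hochberg to the emitted `p_value`
column.

Region annotation uses a GTF gene model; introns are derived as gene span
minus exon union, and a position's class follows the precedence
five_prime_utr > three_prime_utr > exon > intron (UTRs are subsets of
exons, so a deterministic tiebreak is required); positions in no gene are
intergenic. All coordinates are 1-based inclusive internally; BED inputs
are converted on read; chromosome names are normalised to the chr-prefixed
style with the mitochondrial contig as `chrM`.

## Twin comparison

Sites are joined across the pair on (chrom, pos, ref, alt); a position
observed with different allele pairs is excluded and counted. Discordance is
the mono-versus-biallelic dichotomy: exactly one twin MONOALLELIC. A
BIALLELIC versus BIALLELIC_IMBALANCE pair is concordant — the magnitude
channel for such shifts is `LogASE = log2(ASE_A/ASE_B)`, with |LogASE| ≥ 0.8
flagged as altered. LogASE is undefined (NaN, excluded from tail counts)
when either ASE is exactly 0, avoiding arbitrary pseudocounts in a headline
statistic. Percentages use shared (paired) sites as the denominator, and
every summary reports that denominator. Note that LogASE tails are a pure
threshold rule: near-balanced sites have small, noisy ASE values whose
ratios often exceed the threshold, so tail counts on unfiltered site sets
are large by construction; interpret them jointly with the imbalance
patterns. Cross-pair recurrence tables count, per site, the pairs in which
it is shared and those in which it is discordant.

## Gene heterogeneity (I²)

For a gene with k ≥ 2 eSNVs, Q is the chi-square homogeneity statistic of
per-site reference-allele proportions with binomial inverse-variance
weights — algebraically the Pearson chi-square of the 2×k count table,
which the tests verify against `scipy.stats.chi2_contingency`. Proportions
(rather than folded ASE values) are used because Q is invariant to a
consistent ref/alt relabelling, making the two choices equivalent up to
folding. When the pooled proportion is 0 or 1 there is no variance to test
and Q is defined as 0. I² = 100·(Q − df)/Q is floored at 0, and categories
are assigned half-open upward: < 30 homogeneous, [30, 50) moderate,
[50, 75) substantial, ≥ 75 considerable. Single-eSNV genes are reported as
`single_site`, and the eSNVs-per-gene histogram uses bins
{1, 2–10, 11–200, 201–500, > 500}. No random-effects τ² is estimated; I² is
used descriptively only.

## e-karyotyping

Monoallelic sites are excluded (homozygosity and imprinting carry no dosage
signal); each remaining site contributes its minor-allele fraction
min(ref, alt)/depth — folding removes ref/alt orientation effects, since
dosage is unsigned. The decision statistic is the summed per-site binomial
log-likelihood ratio of minor fraction 1/3 versus 1/2. A chromosome with at
least `min_sites` (default 20) biallelic sites is trisomy-like when the sum
is positive (`llr_threshold` = 0); fewer sites give `insufficient`. The LLR
is a deliberately simple likelihood formalisation of allelic-bias shading;
both knobs are configurable. Biallelic-imbalance sites contribute positive
terms (their minor fractions sit below 1/2), but at realistic class mixtures
they are far outnumbered by balanced sites, keeping disomic sums strongly
negative; the false-positive rate is checked empirically in the acceptance
suite. The mitochondrial contig is excluded from karyotype calls by
default: its allele fractions reflect heteroplasmy, not chromosomal dosage,
so it has no disomic null. Track exports label each shared site
concordant/discordant for ideogram-style plotting, with per-Mb densities
available.

## RNA editing

A paired site matches the canonical A-to-I(G) catalog when its position is
catalogued, its allele change is A>G for catalog strand + or T>C for strand
− (the reference-forward appearance of an edited adenosine on the minus
strand), and it lies in no repeat/segmental-duplication interval. Repeat
screening is interval-based against a supplied BED — same intent as
sequence-context screens, without a genome-sequence dependency. Editing
level is G/(A+G) on the strand-oriented counts. Discordance: one twin
monoallelic and the other not dominates (`pattern_discordant`); otherwise a
level gap > `level_threshold` (default 0.25, measured on editing levels) is
`level_discordant`. The within-pair association is an ordinary
least-squares fit of twin-1 on twin-2 levels on the percent scale (so
intercepts are comparable across datasets), refused below 3 points. Note
that levels estimated from counts attenuate the fitted slope relative to
the true latent-level slope (errors-in-variables); the parameter-recovery
test therefore fits on simulated levels with additive noise, matching the
generative model of the regression.

## Cross-referencing

One monoallelism definition (`mono_minor_max`) serves the whole pipeline.
Imprinting: genes whose every eSNV is monoallelic with ≥ 8 sites are
reported — as *known* when present in the imprinting catalog, otherwise as
*candidates* only, since extended homozygosity cannot be excluded without
genotypes, and parent-of-origin is never claimed. XCI: restricted to
catalogued non-escapee genes (escapees are expected biallelic in pooled
cells); a gene is reported at ≥ 2 pattern-discordant shared eSNVs.
Pathogenic sites report whether the risk allele is expressed alone, with
the wild type, or not at all. Mitochondrial microheteroplasmy requires both
alleles at ≥ 1 read each on `chrM` at the standard depth filter — minimal
detectable biallelism, configurable.

## Synthetic data generator

The generator emulates the downstream form of twin ASE studies: two
individuals, `replicates_per_twin` runs each (default 2), per-run
ASEReadCounter-style tables plus a matching GTF and catalogs, and a truth
table sharing keys with the counts. Defaults, chosen once as the study
conditions: 5,000 sites; total depth Poisson with mean 60 (gamma-Poisson
overdispersion optional, off by default — the simplest noise model
consistent with the binomial test applied downstream); class fractions
biallelic 0.80, imbalance 0.08 (ref fraction uniform on 0.6–0.9, random
direction), monoallelic 0.06, imprinted 0.02, XCI 0.01, edited 0.02,
mitochondrial-heteroplasmic 0.01; within-pair pattern-discordance injection
0.027. Larger problem sizes used by specific checks (e.g. 20,000 sites for
discordance recovery, depth 200 for dosage calibration) are set explicitly
by those checks.

Structure: single-exon genes tile the autosomes every 500 kb; three
dedicated imprinted genes sit in inter-tile gaps (gene-wide monoallelic, one
shared silenced direction per gene — the concordant-monoallelic signature of
imprinting); chrX carries three non-escapee genes (monoallelic in both
twins, i.e. a shared inactive X) and two escapee genes (biallelic). Edited
sites are A/G (+) or T/C (−); twin B's level is uniform on 10–90% and twin
A's follows `intercept + slope·level_B + noise` on the percent scale
(defaults 6, 0.8, σ = 5). Mitochondrial sites share a heteroplasmy fraction
uniform on 0.10–0.45 across twins. An optional trisomic chromosome moves
heterozygous fractions in twin A to 1/3 or 2/3. Discordance injection flips
twin B's pattern at the stated fraction of shared sites (monoallelic sites
become balanced; heterozygous sites become monoallelic for their major
allele). Unrelated-pair mode shares a configurable fraction (default 0.5)
of positions and draws each individual's class independently — a
simplification (real imprinting would stay concordant across unrelated
individuals) that is adequate for its purpose, the directional MZ-versus-
unrelated discordance contrast. Catalog emission plants exactly the edited
positions plus configurable decoys, a configurable fraction of decoys
covered by the repeat BED, the planted imprinted/XCI gene lists, and a
small pathogenic table over generic sites.

What the generator does not emulate: mapping and reference bias, strand-
specific error profiles, eQTL-driven imbalance structure, linkage between
neighbouring sites, cell-type mixtures, or sub-chromosomal mosaicism.
Passing tests therefore demonstrate correctness of the statistics and
recovery under idealised binomial sampling, not robustness to alignment
artifacts — those are upstream concerns of the count-table producer.

## Numerical and policy choices

- Binomial p-values are exact (integer enumeration), cached per (k, n).
- Q1 quartiles: NumPy's default linear interpolation (type 7), stated
  explicitly because quartile conventions differ across software.
- Aggregation tie-break (run closest to Q1): stable order by run sort.
- Degenerate inputs: zero-depth ASE and editing levels raise; empty site
  tables flow through every stage as empty outputs; LogASE at zero ASE is
  NaN by design.
- Determinism: one `numpy` Generator seeded from the config drives the
  whole simulation; identical configs produce byte-identical files.
- I² boundary values 30/50/75 land in the higher category (half-open
  upward), stated and tested explicitly.

## Limitations

Within-pair denominators depend on the shared-site universe, so percentages
are comparable only across runs with the same filters. The pipeline tests
imbalance after replicate aggregation (recording `n_support`) rather than
per run. No mapping-bias correction, genotype phasing, CNV segmentation or
mosaic-fraction estimation is attempted; catalogs are taken as supplied, in
target coordinates, and conflicting strand annotations in the editing
catalog are dropped and logged rather than resolved.
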