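"""Truth-labelled synthetic twin-pair allele-count generator.

The generator emulates the downstream form of twin RNA-seq ASE studies:
per-run ASEReadCounter-style count tables for two co-twins with replicate
runs, a matching gene model (GTF) and annotation catalogs, plus a truth
table keyed like the counts.  Site classes cover strictly biallelic
(p = 0.5), biallelic imbalance (p drawn from a stated range), strictly
monoallelic (p = 1), imprinted genes (gene-wide monoallelic, shared
silenced haplotype), X-linked genes under XCI (non-escapees monoallelic
with a shared inactive X; escapees biallelic), canonical A-to-I(G) edited
sites whose per-twin levels are linked by a linear model, and
mitochondrial heteroplasmy.  An optional trisomic chromosome shifts
heterozygous allele fractions to 1/3 : 2/3 in one twin.  Read counts are
binomial at the true fraction with Poisson (optionally gamma-Poisson)
total depth.  Identical configs produce identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COUNT_COLUMNS

BASES = np.array(list("ACGT"))

DEFAULT_CHROMOSOMES = (
    ("chr1", 60_000_000),
    ("chr2", 50_000_000),
    ("chr3", 40_000_000),
    ("chr21", 35_000_000),
    ("chrX", 50_000_000),
    ("chrM", 16_569),
)

DEFAULT_CLASS_FRACTIONS = {
    "biallelic": 0.80,
    "imbalance": 0.08,
    "monoallelic": 0.06,
    "imprinted_gene": 0.02,
    "xci_gene": 0.01,
    "edited_site": 0.02,
    "mito_heteroplasmic": 0.01,
}

_GENE_SPACING = 500_000
_GENE_LENGTH = 20_000


@dataclass
class SimulationConfig:
    """All knobs of the twin-pair simulator; the seed fully determines output."""

    seed: int = 0
    n_sites: int = 5000
    chromosomes: tuple = DEFAULT_CHROMOSOMES
    depth_mean: float = 60.0
    depth_dispersion: float = 0.0  # 0 = Poisson; >0 = gamma-Poisson heterogeneity
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    imbalance_range: tuple = (0.6, 0.9)
    pair_mode: str = "mz_twins"  # or "unrelated"
    discordance_injection: float = 0.027
    unrelated_overlap: float = 0.5
    trisomy_chrom: str | None = None
    replicates_per_twin: int = 2
    editing_slope: float = 0.8
    editing_intercept: float = 6.0  # percent scale
    editing_noise_sd: float = 5.0  # percent scale
    editing_level_range: tuple = (0.10, 0.90)
    mito_heteroplasmy_range: tuple = (0.10, 0.45)
    n_imprinted_genes: int = 3
    n_xci_genes: int = 3
    n_escapee_genes: int = 2
    n_decoy_editing: int = 20
    decoy_repeat_fraction: float = 0.5
    n_pathogenic: int = 5

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        if any(not 0 <= f <= 1 for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.pair_mode not in ("mz_twins", "unrelated"):
            raise ValueError("pair_mode must be 'mz_twins' or 'unrelated'")
        if not 0 <= self.discordance_injection <= 1:
            raise ValueError("discordance_injection must lie in [0, 1]")


def build_gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic synthetic gene layout implied by a config.

    Generic single-exon genes tile the autosomes every 500 kb; dedicated
    imprinted genes sit in the inter-tile gaps of the first autosome, and
    XCI (non-escapee) plus escapee genes tile chrX.  Columns: gene_id,
    chrom, start, end, kind.
    """
    rows = []
    autosomes = [(c, l) for c, l in config.chromosomes
                 if c not in ("chrX", "chrY", "chrM")]
    for chrom, length in autosomes:
        n = max(1, int(length // _GENE_SPACING))
        for i in range(n):
            start = i * _GENE_SPACING + 50_001
            rows.append((f"GEN_{chrom[3:]}_{i:04d}", chrom, start,
                         start + _GENE_LENGTH - 1, "generic"))
    first = autosomes[0][0]
    for i in range(config.n_imprinted_genes):
        start = i * _GENE_SPACING + 250_001  # inter-tile gap
        rows.append((f"IMP_{i+1}", first, start, start + _GENE_LENGTH - 1, "imprinted"))
    x = [c for c, _ in config.chromosomes if c == "chrX"]
    if x:
        for i in range(config.n_xci_genes):
            start = i * _GENE_SPACING + 50_001
            rows.append((f"XCI_{i+1}", "chrX", start, start + _GENE_LENGTH - 1,
                         "xci_non_escapee"))
        for i in range(config.n_escapee_genes):
            start = (config.n_xci_genes + i) * _GENE_SPACING + 50_001
            rows.append((f"ESC_{i+1}", "chrX", start, start + _GENE_LENGTH - 1,
                         "xci_escapee"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "kind"])


def _assign_positions(rng: np.random.Generator, genes: pd.DataFrame,
                      gene_idx: np.ndarray) -> np.ndarray:
    """Distinct 1-based positions inside each site's assigned gene."""
    pos = np.zeros(len(gene_idx), dtype=int)
    for gi in np.unique(gene_idx):
        mask = gene_idx == gi
        g = genes.iloc[gi]
        span = int(g["end"] - g["start"] + 1)
        offs = rng.choice(span, size=int(mask.sum()), replace=False)
        pos[mask] = int(g["start"]) + offs
    return pos


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return BASES[ref], BASES[alt]


def _site_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out site positions, alleles, classes and per-site base parameters."""
    genes = build_gene_table(config)
    classes = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    cls = rng.choice(classes, size=config.n_sites, p=probs)

    generic_idx = genes.index[genes["kind"] == "generic"].to_numpy()
    imp_idx = genes.index[genes["kind"] == "imprinted"].to_numpy()
    xci_idx = genes.index[genes["kind"] == "xci_non_escapee"].to_numpy()
    esc_idx = genes.index[genes["kind"] == "xci_escapee"].to_numpy()

    gene_of = np.full(config.n_sites, -1, dtype=int)
    for name, pool in (("biallelic", generic_idx), ("imbalance", generic_idx),
                       ("monoallelic", generic_idx), ("edited_site", generic_idx)):
        m = cls == name
        if m.any():
            gene_of[m] = rng.choice(pool, size=int(m.sum()))
    m = cls == "imprinted_gene"
    if m.any():
        gene_of[m] = imp_idx[np.arange(int(m.sum())) % len(imp_idx)]
    m = cls == "xci_gene"
    if m.any():
        k = int(m.sum())
        n_esc = int(round(0.25 * k)) if len(esc_idx) else 0
        pool = np.concatenate([
            xci_idx[np.arange(k - n_esc) % len(xci_idx)],
            esc_idx[np.arange(n_esc) % len(esc_idx)] if n_esc else esc_idx[:0],
        ])
        gene_of[m] = pool

    sites = pd.DataFrame({"cls": cls, "gene_idx": gene_of})
    mito = cls == "mito_heteroplasmic"
    chrom = np.empty(config.n_sites, dtype=object)
    pos = np.zeros(config.n_sites, dtype=int)
    nonmito = ~mito
    chrom[nonmito] = genes["chrom"].to_numpy()[gene_of[nonmito]]
    pos[nonmito] = _assign_positions(rng, genes, gene_of[nonmito]) if nonmito.any() else 0
    if mito.any():
        mchrom = [c for c, _ in config.chromosomes if c == "chrM"]
        mlen = dict(config.chromosomes).get("chrM", 16_569)
        chrom[mito] = mchrom[0] if mchrom else "chrM"
        pos[mito] = 1 + rng.choice(int(mlen), size=int(mito.sum()), replace=False)
    sites["chrom"] = chrom
    sites["pos"] = pos

    ref, alt = _draw_alleles(rng, config.n_sites)
    strand = np.where(rng.random(config.n_sites) < 0.5, "+", "-")
    edited = cls == "edited_site"
    ref[edited] = np.where(strand[edited] == "+", "A", "T")
    alt[edited] = np.where(strand[edited] == "+", "G", "C")
    sites["ref"], sites["alt"], sites["strand"] = ref, alt, strand
    sites["gene_id"] = np.where(gene_of >= 0, genes["gene_id"].reindex(gene_of).to_numpy(), "")

    # per-gene silenced-haplotype direction for imprinted / XCI genes
    special = genes.loc[genes["kind"].isin(["imprinted", "xci_non_escapee"])]
    gene_dir = {int(i): (1.0 if rng.random() < 0.5 else 0.0) for i in special.index}
    sites["_gene_dir"] = [gene_dir.get(int(g), np.nan) for g in gene_of]
    return sites


def _base_fraction(config: SimulationConfig, rng: np.random.Generator,
                   sites: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-site true reference-allele fraction and editing level (NaN if unedited)."""
    n = len(sites)
    p = np.full(n, 0.5)
    level = np.full(n, np.nan)
    cls = sites["cls"].to_numpy()

    m = cls == "imbalance"
    if m.any():
        lo, hi = config.imbalance_range
        mag = rng.uniform(lo, hi, size=int(m.sum()))
        flip = rng.random(int(m.sum())) < 0.5
        p[m] = np.where(flip, 1.0 - mag, mag)
    m = cls == "monoallelic"
    if m.any():
        p[m] = np.where(rng.random(int(m.sum())) < 0.5, 1.0, 0.0)
    for name in ("imprinted_gene", "xci_gene"):
        m = cls == name
        if m.any():
            d = sites.loc[m, "_gene_dir"].to_numpy()
            p[m] = np.where(np.isnan(d), 0.5, d)  # escapee genes stay at 0.5
    m = cls == "edited_site"
    if m.any():
        lo, hi = config.editing_level_range
        level[m] = rng.uniform(lo, hi, size=int(m.sum()))
        p[m] = 1.0 - level[m]  # ref base A/T, alt base carries the edit
    m = cls == "mito_heteroplasmic"
    if m.any():
        lo, hi = config.mito_heteroplasmy_range
        h = rng.uniform(lo, hi, size=int(m.sum()))
        major_ref = rng.random(int(m.sum())) < 0.5
        p[m] = np.where(major_ref, 1.0 - h, h)
    return p, level


def _linked_editing_level(config: SimulationConfig, rng: np.random.Generator,
                          level_b: np.ndarray) -> np.ndarray:
    """Twin-A editing level from twin-B level via the linear percent-scale model."""
    pct = config.editing_intercept + config.editing_slope * (100.0 * level_b)
    pct = pct + rng.normal(0.0, config.editing_noise_sd, size=level_b.shape)
    return np.clip(pct, 0.0, 100.0) / 100.0


def _apply_trisomy(config: SimulationConfig, rng: np.random.Generator,
                   sites: pd.DataFrame, p: np.ndarray) -> np.ndarray:
    """Shift heterozygous fractions to 1/3 or 2/3 on the trisomic chromosome."""
    if config.trisomy_chrom is None:
        return p
    out = p.copy()
    on = (sites["chrom"] == config.trisomy_chrom).to_numpy() & (p > 0) & (p < 1)
    dup_ref = rng.random(int(on.sum())) < 0.5
    out[on] = np.where(dup_ref, 2.0 / 3.0, 1.0 / 3.0)
    return out


def _flip_pattern(p: np.ndarray, flip: np.ndarray) -> np.ndarray:
    """Mono sites become balanced; het sites become monoallelic (major allele kept)."""
    out = p.copy()
    mono = (p <= 0.0) | (p >= 1.0)
    out[flip & mono] = 0.5
    het = flip & ~mono
    out[het] = np.where(p[het] >= 0.5, 1.0, 0.0)
    return out


def _emit_counts(config: SimulationConfig, rng: np.random.Generator,
                 sites: pd.DataFrame, p: np.ndarray, present: np.ndarray,
                 sample_id: str) -> pd.DataFrame:
    """Binomial read counts for one individual across its replicate runs."""
    frames = []
    idx = np.flatnonzero(present)
    for r in range(config.replicates_per_twin):
        if config.depth_dispersion > 0:
            shape = 1.0 / config.depth_dispersion
            lam = rng.gamma(shape, config.depth_mean / shape, size=len(idx))
        else:
            lam = np.full(len(idx), config.depth_mean)
        depth = rng.poisson(lam)
        refc = rng.binomial(depth, p[idx])
        frames.append(pd.DataFrame({
            "chrom": sites["chrom"].to_numpy()[idx],
            "pos": sites["pos"].to_numpy()[idx],
            "ref": sites["ref"].to_numpy()[idx],
            "alt": sites["alt"].to_numpy()[idx],
            "ref_count": refc,
            "alt_count": depth - refc,
            "sample_id": sample_id,
            "run_id": f"{sample_id}_run{r + 1}",
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "run_id"], kind="stable",
                           ignore_index=True)[COUNT_COLUMNS]


def simulate_pair(config: SimulationConfig,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one twin (or unrelated) pair: per-run counts and the truth table.

    Returns
    -------
    counts_a, counts_b
        Canonical count tables (all replicate runs concatenated; the
        ``run_id`` column separates runs).
    truth
        One row per simulated site: class per individual, true reference
        fraction per individual, editing levels, sharing, injected flips
        and the true pair-level discordance status.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_frame(config, rng)
    p_a, level_a = _base_fraction(config, rng, sites)

    if config.pair_mode == "mz_twins":
        cls_b = sites["cls"].to_numpy().copy()
        p_b = p_a.copy()
        level_b = level_a.copy()
        edited = cls_b == "edited_site"
        if edited.any():
            level_b[edited] = level_a[edited]
            level_a2 = _linked_editing_level(config, rng, level_b[edited])
            level_a[edited] = level_a2
            p_a[edited] = 1.0 - level_a2
        p_a = _apply_trisomy(config, rng, sites, p_a)  # twin A carries the extra copy
        shared = np.ones(len(sites), dtype=bool)
        flip = rng.random(len(sites)) < config.discordance_injection
        p_b = _flip_pattern(p_b, flip)
        level_b[edited] = 1.0 - p_b[edited]  # keep levels consistent after flips
        present_a = shared.copy()
        present_b = shared.copy()
    else:
        cls_b = rng.choice(list(config.class_fractions), size=len(sites),
                           p=np.array(list(config.class_fractions.values())))
        sites_b = sites.copy()
        sites_b["cls"] = cls_b
        p_b, level_b = _base_fraction(config, rng, sites_b)
        shared = rng.random(len(sites)) < config.unrelated_overlap
        flip = np.zeros(len(sites), dtype=bool)
        to_a = rng.random(len(sites)) < 0.5
        present_a = shared | to_a
        present_b = shared | ~to_a

    mono_a = (p_a <= 0) | (p_a >= 1)
    mono_b = (p_b <= 0) | (p_b >= 1)
    truth = sites[["chrom", "pos", "ref", "alt", "strand", "gene_id"]].copy()
    truth["class_a"] = sites["cls"].to_numpy()
    truth["class_b"] = cls_b
    truth["p_ref_a"] = p_a
    truth["p_ref_b"] = p_b
    truth["level_a"] = level_a
    truth["level_b"] = level_b
    truth["shared"] = shared
    truth["flipped"] = flip
    truth["trisomy"] = (sites["chrom"] == config.trisomy_chrom).to_numpy() \
        if config.trisomy_chrom else False
    truth["true_discordant"] = shared & (mono_a ^ mono_b)

    counts_a = _emit_counts(config, rng, sites, p_a, present_a, "twinA")
    counts_b = _emit_counts(config, rng, sites, p_b, present_b, "twinB")
    truth = truth.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)
    return counts_a, counts_b, truth


def write_gene_model_gtf(config: SimulationConfig, path: str | os.PathLike) -> None:
    """Write the simulated gene layout as a minimal Ensembl-style GTF."""
    genes = build_gene_table(config)
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            for ftype in ("gene", "exon"):
                fh.write(f"{g.chrom}\tsim\t{ftype}\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}\n")


def emit_catalogs(config: SimulationConfig, truth: pd.DataFrame, outdir: str,
                  ) -> dict[str, str]:
    """Write annotation files matched to a simulated pair.

    Produces the editing catalog (planted edited positions plus decoys, a
    configurable fraction of decoys covered by the repeat BED), the
    imprinted-gene list, the XCI status table, the repeat BED, a small
    pathogenic-variant table (risk allele = alt at a few generic sites)
    and the gene-model GTF.  Returns a name -> path mapping.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 987_654_321 % (2**31))
    paths = {}
    genes = build_gene_table(config)

    planted = truth.loc[truth["class_a"].eq("edited_site")
                        | truth["class_b"].eq("edited_site"),
                        ["chrom", "pos", "strand"]].drop_duplicates(["chrom", "pos"])
    autosomes = [(c, l) for c, l in config.chromosomes if c not in ("chrX", "chrM")]
    used = set(map(tuple, truth[["chrom", "pos"]].itertuples(index=False)))
    decoys, repeat_rows = [], []
    for i in range(config.n_decoy_editing):
        chrom, length = autosomes[i % len(autosomes)]
        pos = int(rng.integers(1, length))
        while (chrom, pos) in used:
            pos = int(rng.integers(1, length))
        used.add((chrom, pos))
        decoys.append((chrom, pos, "+" if rng.random() < 0.5 else "-"))
        if rng.random() < config.decoy_repeat_fraction:
            repeat_rows.append((chrom, pos - 1, pos + 49))  # BED half-open, covers pos
    catalog = pd.concat([planted,
                         pd.DataFrame(decoys, columns=["chrom", "pos", "strand"])],
                        ignore_index=True).sort_values(["chrom", "pos"])
    paths["editing_catalog"] = os.path.join(outdir, "editing_catalog.tsv")
    catalog.to_csv(paths["editing_catalog"], sep="\t", index=False)

    paths["repeats"] = os.path.join(outdir, "repeats.bed")
    pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]).to_csv(
        paths["repeats"], sep="\t", index=False, header=False)

    paths["imprinted"] = os.path.join(outdir, "imprinted_genes.tsv")
    imp = genes.loc[genes["kind"] == "imprinted", "gene_id"]
    imp.to_csv(paths["imprinted"], sep="\t", index=False, header=False)

    paths["xci"] = os.path.join(outdir, "xci_status.tsv")
    xci = pd.concat([
        genes.loc[genes["kind"] == "xci_non_escapee", ["gene_id"]].assign(status="non_escapee"),
        genes.loc[genes["kind"] == "xci_escapee", ["gene_id"]].assign(status="escapee"),
    ])
    xci.to_csv(paths["xci"], sep="\t", index=False, header=False)

    generic = truth.loc[truth["class_a"].isin(["biallelic", "imbalance", "monoallelic"])]
    k = min(config.n_pathogenic, len(generic))
    picks = generic.iloc[rng.choice(len(generic), size=k, replace=False)] if k else generic
    path_tab = pd.DataFrame({
        "chrom": picks["chrom"].to_numpy(),
        "pos": picks["pos"].to_numpy(),
        "risk_allele": picks["alt"].to_numpy(),
        "condition_label": [f"synthetic_condition_{i+1}" for i in range(k)],
    })
    paths["pathogenic"] = os.path.join(outdir, "pathogenic_variants.tsv")
    path_tab.to_csv(paths["pathogenic"], sep="\t", index=False)

    paths["gtf"] = os.path.join(outdir, "genes.gtf")
    write_gene_model_gtf(config, paths["gtf"])
    return paths


def write_pair(config: SimulationConfig, outdir: str) -> dict:
    """Simulate a pair and write everything (counts, truth, catalogs, manifest inputs).

    Count files are written one per run in the ASEReadCounter dialect.
    Returns a dict with per-twin run file lists, catalog paths and the
    truth-table path.
    """
    from .io import write_allele_counts

    os.makedirs(outdir, exist_ok=True)
    counts_a, counts_b, truth = simulate_pair(config)
    out = {"runs": {"twinA": [], "twinB": []}}
    for sample, counts in (("twinA", counts_a), ("twinB", counts_b)):
        for run_id, sub in counts.groupby("run_id", sort=True):
            p = os.path.join(outdir, f"{run_id}.counts.tsv")
            write_allele_counts(sub, p)
            out["runs"][sample].append({"run_id": str(run_id), "path": p})
    out["truth"] = os.path.join(outdir, "truth.tsv")
    truth.to_csv(out["truth"], sep="\t", index=False)
    out.update(emit_catalogs(config, truth, outdir))
    return out
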