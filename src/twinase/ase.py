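"""Per-site allele-specific expression: filtering, aggregation, the ASE
statistic, exact binomial testing and expression-pattern classification.

The ASE statistic is ``|0.5 - ref/(ref+alt)|``: 0 at perfect 1:1 allelic
balance, 0.5 at strict monoallelism.  Significance of allelic imbalance is
an exact two-sided binomial test against p=0.5, computed in integer
arithmetic so tie handling is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .io import COUNT_COLUMNS, SITE_COLUMNS

PATTERNS = ("MONOALLELIC", "BIALLELIC_IMBALANCE", "BIALLELIC")


@dataclass
class AseParams:
    """Tunable thresholds for ASE site calling.

    min_depth
        Minimum aggregated read depth for an informative site (reads).
    alpha
        Significance level of the per-site binomial test.
    mono_minor_max
        Maximum minor-allele read count still called strictly monoallelic;
        0 means the minor allele must be entirely absent.
    """

    min_depth: int = 12
    alpha: float = 0.05
    mono_minor_max: int = 0

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mono_minor_max < 0:
            raise ValueError("mono_minor_max must be >= 0")


def compute_ase(ref_count: int, alt_count: int) -> float:
    """Allelic imbalance |0.5 - ref/(ref+alt)|, in [0, 0.5].

    Raises
    ------
    ValueError
        If total depth is zero.
    """
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("ASE undefined at zero total depth")
    return abs(0.5 - ref_count / total)


@lru_cache(maxsize=1 << 20)
def _binom_pvalue_cached(k: int, n: int) -> float:
    # Exact two-sided test at p = 1/2.  pmf(i) is proportional to C(n, i),
    # so "sum all outcomes at most as probable as k" is an exact integer
    # comparison of binomial coefficients — no floating-point tie ambiguity.
    ck = comb(n, k)
    num = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= ck)
    return min(1.0, num / 2.0 ** n) if n < 1024 else min(1.0, float(num / (1 << n)))


def binomial_pvalue(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial p-value for ref successes out of ref+alt at p=0.5."""
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("binomial test undefined at zero depth")
    return _binom_pvalue_cached(int(ref_count), int(n))


def classify_pattern(ref_count: int, alt_count: int, params: AseParams | None = None) -> str:
    """MONOALLELIC / BIALLELIC_IMBALANCE / BIALLELIC for one aggregated site."""
    params = params or AseParams()
    if min(ref_count, alt_count) <= params.mono_minor_max:
        return "MONOALLELIC"
    if binomial_pvalue(ref_count, alt_count) < params.alpha:
        return "BIALLELIC_IMBALANCE"
    return "BIALLELIC"


def filter_informative(counts: pd.DataFrame, params: AseParams | None = None) -> pd.DataFrame:
    """Keep count rows whose total depth reaches ``params.min_depth``."""
    params = params or AseParams()
    if counts.empty:
        return counts.copy()
    keep = (counts["ref_count"] + counts["alt_count"]) >= params.min_depth
    return counts.loc[keep].reset_index(drop=True)


def aggregate_replicates(per_run: pd.DataFrame, method: str = "q1_of_ase",
                         ) -> tuple[int, int, float, int]:
    """Amalgamate informative runs at one site into a single record.

    Parameters
    ----------
    per_run
        Count rows sharing (chrom, pos, ref, alt), one per informative run.
    method
        ``q1_of_ase``: the site ASE is the first quartile (linear
        interpolation between order statistics) of per-run ASE values and
        the reported counts come from the run whose ASE is closest to that
        quartile (ties broken by run order).  ``sum_counts``: counts are
        summed across runs and ASE recomputed from the sums.  A single run
        passes through unchanged either way.

    Returns
    -------
    (ref_count, alt_count, ase_value, n_support)
    """
    if per_run.empty:
        raise ValueError("aggregate_replicates needs at least one run")
    key = per_run[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    if len(key) != 1:
        raise ValueError("mixed alleles or positions supplied to aggregate_replicates")
    refs = per_run["ref_count"].to_numpy()
    alts = per_run["alt_count"].to_numpy()
    n_support = len(per_run)
    if method == "sum_counts":
        r, a = int(refs.sum()), int(alts.sum())
        return r, a, compute_ase(r, a), n_support
    if method != "q1_of_ase":
        raise ValueError(f"unknown aggregation method {method!r}")
    ases = np.abs(0.5 - refs / (refs + alts))
    q1 = float(np.percentile(ases, 25))  # linear interpolation (type 7)
    idx = int(np.argmin(np.abs(ases - q1)))
    return int(refs[idx]), int(alts[idx]), q1, n_support


def _aggregate_table(counts: pd.DataFrame, method: str) -> pd.DataFrame:
    """Vectorised per-site aggregation over all (chrom, pos, ref, alt) groups."""
    gcols = ["chrom", "pos", "ref", "alt"]
    # reject positions observed with different allele pairs in different runs
    npairs = counts.groupby(["chrom", "pos"])["ref"].transform("nunique") * \
        counts.groupby(["chrom", "pos"])["alt"].transform("nunique")
    if (npairs > 1).any():
        raise ValueError("position observed with different allele pairs across runs")
    g = counts.groupby(gcols, sort=True)
    if method == "sum_counts":
        agg = g[["ref_count", "alt_count"]].sum()
        agg["n_support"] = g.size()
        agg = agg.reset_index()
        total = agg["ref_count"] + agg["alt_count"]
        agg["ase"] = np.abs(0.5 - agg["ref_count"] / total)
        return agg
    depth = counts["ref_count"] + counts["alt_count"]
    work = counts.assign(_ase=np.abs(0.5 - counts["ref_count"] / depth))
    g = work.groupby(gcols, sort=True)
    q1 = g["_ase"].quantile(0.25)
    n = g.size()
    work = work.merge(q1.rename("_q1"), left_on=gcols, right_index=True)
    work["_dist"] = np.abs(work["_ase"] - work["_q1"])
    rep = work.sort_values(gcols + ["_dist"], kind="stable").groupby(gcols, sort=True).first()
    agg = rep[["ref_count", "alt_count"]].copy()
    agg["n_support"] = n
    agg["ase"] = q1
    return agg.reset_index()


def call_ase_sites(counts: pd.DataFrame, params: AseParams | None = None,
                   gene_model=None, method: str = "q1_of_ase") -> pd.DataFrame:
    """Full per-individual site calling: filter, aggregate, test, classify, annotate.

    Parameters
    ----------
    counts
        Per-run count rows (:data:`twinase.io.COUNT_COLUMNS`) for one
        individual, possibly spanning several sequencing runs.
    params
        Thresholds; defaults to :class:`AseParams`.
    gene_model
        Optional :class:`twinase.io.GeneModel` for gene/region annotation.
    method
        Replicate aggregation mode (see :func:`aggregate_replicates`).

    Returns
    -------
    One row per informative site with :data:`twinase.io.SITE_COLUMNS`.
    The binomial test runs on the aggregated counts.
    """
    params = params or AseParams()
    counts = filter_informative(counts, params)
    if counts.empty:
        return pd.DataFrame(columns=SITE_COLUMNS)
    agg = _aggregate_table(counts, method)
    refs = agg["ref_count"].to_numpy()
    alts = agg["alt_count"].to_numpy()
    agg["p_value"] = [binomial_pvalue(int(r), int(a)) for r, a in zip(refs, alts)]
    minor = np.minimum(refs, alts)
    pattern = np.where(minor <= params.mono_minor_max, "MONOALLELIC",
                       np.where(agg["p_value"] < params.alpha,
                                "BIALLELIC_IMBALANCE", "BIALLELIC"))
    agg["pattern"] = pattern
    if gene_model is not None:
        region, gids = gene_model.classify_table(agg["chrom"], agg["pos"])
        agg["region_class"] = region
        agg["gene_ids"] = gids
    else:
        agg["region_class"] = "intergenic"
        agg["gene_ids"] = ""
    return agg.reindex(columns=SITE_COLUMNS)


def annotate_region(sites: pd.DataFrame, gene_model) -> pd.DataFrame:
    """Attach region_class and comma-joined gene_ids to a site table."""
    out = sites.copy()
    region, gids = gene_model.classify_table(out["chrom"], out["pos"])
    out["region_class"] = region
    out["gene_ids"] = gids
    return out
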