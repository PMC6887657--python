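"""A-to-I(G) RNA-editing analysis on paired ASE sites.

Inosine is read as guanosine by sequencers, so editing at a catalogued
adenosine appears as an A>G change on the + strand or, in reference-
forward counts, a T>C change when the catalogued site lies on the -
strand.  The editing level is G/(A+G) over the strand-oriented reads.
Within a twin pair, a matched site is discordant when the two levels
differ by more than 25 percentage points, or pattern-discordant when one
twin is strictly monoallelic and the other is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_LEVEL_THRESHOLD = 0.25

DISCORDANCE_LABELS = ("concordant", "level_discordant", "pattern_discordant")

EDITING_COLUMNS = ["chrom", "pos", "strand", "a1", "g1", "a2", "g2",
                   "level1", "level2", "discordance"]


def editing_level(a_count: int, g_count: int) -> float:
    """Editing level g/(a+g) in [0, 1]; raises at zero total reads."""
    total = a_count + g_count
    if total <= 0:
        raise ValueError("editing level undefined at zero depth")
    return g_count / total


def classify_editing_discordance(level_1: float, level_2: float,
                                 pattern_1: str | None = None,
                                 pattern_2: str | None = None,
                                 level_threshold: float = DEFAULT_LEVEL_THRESHOLD) -> str:
    """Discordance label for one matched editing site.

    ``pattern_discordant`` (one twin monoallelic, the other not) dominates;
    otherwise ``level_discordant`` iff |level_1 - level_2| > threshold.
    Symmetric in the two twins.
    """
    mono_1 = pattern_1 == "MONOALLELIC"
    mono_2 = pattern_2 == "MONOALLELIC"
    if mono_1 ^ mono_2:
        return "pattern_discordant"
    if abs(level_1 - level_2) > level_threshold:
        return "level_discordant"
    return "concordant"


def match_editing_sites(pairs: pd.DataFrame, catalog: pd.DataFrame,
                        repeat_trees: dict | None = None,
                        level_threshold: float = DEFAULT_LEVEL_THRESHOLD) -> pd.DataFrame:
    """Intersect paired sites with a canonical editing catalog.

    A paired site matches iff its (chrom, pos) is catalogued, the allele
    change is the canonical one for the catalog strand (ref A / alt G on
    +; ref T / alt C on -), and the position falls in no repeat interval.
    A-supporting reads are the ref counts and G-supporting reads the alt
    counts in this orientation, per twin.

    Parameters
    ----------
    pairs
        Output of :func:`twinase.compare.pair_sites`.
    catalog
        DataFrame with chrom, pos, strand (see
        :func:`twinase.io.read_editing_catalog`).
    repeat_trees
        chrom -> IntervalTree of repeat/segmental-duplication intervals
        (as built by :func:`twinase.io.read_annotation_sets`).

    Returns
    -------
    One row per matched site with :data:`EDITING_COLUMNS`.
    """
    if pairs.empty or catalog.empty:
        return pd.DataFrame(columns=EDITING_COLUMNS)
    cat = catalog.rename(columns={"strand": "_strand"})
    m = pairs.merge(cat, on=["chrom", "pos"], how="inner")
    if m.empty:
        return pd.DataFrame(columns=EDITING_COLUMNS)
    canonical = ((m["_strand"] == "+") & (m["ref"] == "A") & (m["alt"] == "G")) | \
                ((m["_strand"] == "-") & (m["ref"] == "T") & (m["alt"] == "C"))
    m = m.loc[canonical]
    if repeat_trees:
        keep = [not (repeat_trees.get(c) and repeat_trees[c][int(p)])
                for c, p in zip(m["chrom"], m["pos"])]
        m = m.loc[keep]
    if m.empty:
        return pd.DataFrame(columns=EDITING_COLUMNS)
    out = pd.DataFrame({
        "chrom": m["chrom"].to_numpy(),
        "pos": m["pos"].to_numpy(),
        "strand": m["_strand"].to_numpy(),
        "a1": m["ref_count_a"].to_numpy(int),
        "g1": m["alt_count_a"].to_numpy(int),
        "a2": m["ref_count_b"].to_numpy(int),
        "g2": m["alt_count_b"].to_numpy(int),
    })
    out["level1"] = out["g1"] / (out["a1"] + out["g1"])
    out["level2"] = out["g2"] / (out["a2"] + out["g2"])
    out["discordance"] = [
        classify_editing_discordance(l1, l2, p1, p2, level_threshold)
        for l1, l2, p1, p2 in zip(out["level1"], out["level2"],
                                  m["pattern_a"], m["pattern_b"])
    ]
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class EditingModelFit:
    """OLS fit of twin-1 editing level (%) on twin-2 editing level (%)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_twin_editing_model(levels_1, levels_2) -> EditingModelFit:
    """Ordinary least squares of twin-1 on twin-2 editing levels.

    Levels may be fractions in [0, 1] or percents; they are placed on the
    percent scale (0-100) before fitting so intercepts are comparable
    across datasets.  Refuses to fit fewer than 3 points.
    """
    y = np.asarray(levels_1, dtype=float)
    x = np.asarray(levels_2, dtype=float)
    if y.size != x.size:
        raise ValueError("level vectors must have equal length")
    if y.size < 3:
        raise ValueError("twin editing model needs at least 3 points")
    if np.nanmax(np.concatenate([y, x])) <= 1.0:
        y, x = 100.0 * y, 100.0 * x
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return EditingModelFit(slope=float(model.params[1]),
                           intercept=float(model.params[0]),
                           r_squared=float(model.rsquared),
                           n_points=int(y.size))
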