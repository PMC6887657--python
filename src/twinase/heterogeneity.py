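"""Gene-level I² heterogeneity of per-site allele proportions.

For a gene covered by k eSNVs, Q is the chi-square homogeneity statistic
of the per-site reference-allele proportions p_i = ref_i / n_i with
binomial inverse-variance weights:

    Q = sum_i n_i (p_i - pbar)^2 / (pbar (1 - pbar)),   df = k - 1,

where pbar is the depth-weighted mean proportion.  This is algebraically
the Pearson chi-square of the 2 x k ref/alt count table.  The descriptive
heterogeneity percentage is I² = 100 (Q - df) / Q, floored at 0, and genes
rank as homogeneous (<30), moderate ([30, 50)), substantial ([50, 75)) or
considerable (>=75).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("homogeneous", "moderate", "substantial", "considerable", "single_site")

#: eSNVs-per-gene histogram bins (right-inclusive labels)
HIST_BINS = ("1", "2-10", "11-200", "201-500", ">500")


def gene_q_statistic(ref_counts, alt_counts) -> tuple[float, int]:
    """Cochran-style Q and df over one gene's site-level allele counts.

    Requires at least two sites.  When the pooled proportion is 0 or 1
    (every site fully monoallelic for the same allele) there is no
    variance to test and Q is defined as 0.
    """
    refs = np.asarray(ref_counts, dtype=float)
    alts = np.asarray(alt_counts, dtype=float)
    if refs.size < 2:
        raise ValueError("Q statistic needs at least two sites")
    n = refs + alts
    if (n <= 0).any():
        raise ValueError("site with zero depth")
    pbar = refs.sum() / n.sum()
    df = int(refs.size - 1)
    if pbar <= 0.0 or pbar >= 1.0:
        return 0.0, df
    p = refs / n
    q = float(np.sum(n * (p - pbar) ** 2) / (pbar * (1.0 - pbar)))
    return q, df


def i_squared(q_stat: float, df: int) -> float:
    """I² percent: 100 (Q - df)/Q floored at 0; 0 when Q = 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if q_stat <= 0:
        return 0.0
    return max(0.0, 100.0 * (q_stat - df) / q_stat)


def rank_heterogeneity(i_sq: float) -> str:
    """Four-way heterogeneity category; boundaries half-open upward."""
    if not 0 <= i_sq <= 100:
        raise ValueError("I² must be within [0, 100]")
    if i_sq < 30:
        return "homogeneous"
    if i_sq < 50:
        return "moderate"
    if i_sq < 75:
        return "substantial"
    return "considerable"


def _bin_label(n_sites: int) -> str:
    if n_sites == 1:
        return "1"
    if n_sites <= 10:
        return "2-10"
    if n_sites <= 200:
        return "11-200"
    if n_sites <= 500:
        return "201-500"
    return ">500"


def gene_summary(sites: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene heterogeneity table plus the eSNVs-per-gene histogram.

    Parameters
    ----------
    sites
        Region-annotated site table; ``gene_ids`` holds comma-joined gene
        identifiers.  A site annotated to several genes contributes to
        each of them; intergenic sites are skipped.

    Returns
    -------
    table
        Columns gene_id, n_sites, q_stat, df, i_squared, category; genes
        with one site get category ``single_site`` and Q/df/I² of 0.
    histogram
        Site-count histogram over the bins 1, 2-10, 11-200, 201-500, >500.
    """
    work = sites.loc[sites["gene_ids"].astype(str).str.len() > 0,
                     ["gene_ids", "ref_count", "alt_count"]].copy()
    if work.empty:
        table = pd.DataFrame(columns=["gene_id", "n_sites", "q_stat", "df",
                                      "i_squared", "category"])
        return table, pd.Series(0, index=list(HIST_BINS), name="n_genes")
    work = work.assign(gene_id=work["gene_ids"].str.split(",")).explode("gene_id")
    rows = []
    for gid, grp in work.groupby("gene_id", sort=True):
        k = len(grp)
        if k == 1:
            rows.append((gid, 1, 0.0, 0, 0.0, "single_site"))
            continue
        q, df = gene_q_statistic(grp["ref_count"], grp["alt_count"])
        isq = i_squared(q, df)
        rows.append((gid, k, q, df, isq, rank_heterogeneity(isq)))
    table = pd.DataFrame(rows, columns=["gene_id", "n_sites", "q_stat", "df",
                                        "i_squared", "category"])
    hist = (table["n_sites"].map(_bin_label).value_counts()
            .reindex(list(HIST_BINS), fill_value=0).rename("n_genes"))
    return table, hist
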