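"""Expression karyotyping: per-chromosome allelic-bias profiles and
trisomy-like calls.

In a disomic cell the two alleles of a heterozygous site are present in
one copy each, so the minor-allele read fraction centres on 1/2; an extra
chromosomal copy shifts heterozygous sites toward 1/3 : 2/3.  Each
chromosome is scored by the summed per-site binomial log-likelihood ratio
of minor fraction 1/3 versus 1/2 over its biallelic sites; a positive sum
over enough sites is trisomy-like.  Monoallelic sites carry no
heterozygous ratio signal and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

DEFAULT_MIN_SITES = 20
DEFAULT_LLR_THRESHOLD = 0.0


@dataclass
class ChromosomeBiasProfile:
    """Allelic-bias summary of one chromosome in one individual."""

    chrom: str
    n_sites: int
    site_fractions: np.ndarray = field(repr=False)
    median_maf: float = float("nan")
    llr_trisomy: float = float("nan")
    call: str = "insufficient"


def chromosome_profile(sites: pd.DataFrame, chrom: str,
                       min_sites: int = DEFAULT_MIN_SITES,
                       llr_threshold: float = DEFAULT_LLR_THRESHOLD,
                       ) -> ChromosomeBiasProfile:
    """Build the allelic-bias profile for one chromosome.

    Parameters
    ----------
    sites
        One individual's aggregated site table (``pattern`` column present).
    chrom
        Chromosome to profile; monoallelic sites are dropped first.
    min_sites
        Below this many biallelic sites the call is ``insufficient``.
    llr_threshold
        Summed LLR above which (with enough sites) the call is
        ``trisomic_like``.
    """
    sub = sites[(sites["chrom"] == chrom) & (sites["pattern"] != "MONOALLELIC")]
    refs = sub["ref_count"].to_numpy(float)
    alts = sub["alt_count"].to_numpy(float)
    n = refs + alts
    minor = np.minimum(refs, alts)
    frac = np.sort(minor / n) if len(sub) else np.array([])
    if len(sub) == 0:
        return ChromosomeBiasProfile(chrom, 0, frac)
    llr = float(np.sum(binom.logpmf(minor, n, 1.0 / 3.0)
                       - binom.logpmf(minor, n, 0.5)))
    call = "insufficient"
    if len(sub) >= min_sites:
        call = "trisomic_like" if llr > llr_threshold else "disomic"
    return ChromosomeBiasProfile(chrom, len(sub), frac,
                                 float(np.median(frac)), llr, call)


def detect_aneuploidy(sites: pd.DataFrame,
                      min_sites: int = DEFAULT_MIN_SITES,
                      llr_threshold: float = DEFAULT_LLR_THRESHOLD,
                      exclude: tuple = ("chrM",),
                      ) -> tuple[list[str], pd.DataFrame]:
    """Profile every chromosome of one individual and list trisomy-like calls.

    The mitochondrial contig is excluded by default: its allele fractions
    reflect heteroplasmy, not chromosomal dosage, so it has no disomic
    null to test against.

    Returns
    -------
    called
        Chromosomes called ``trisomic_like``, strongest LLR first.
    table
        One row per chromosome (chrom, n_sites, median_maf, llr_trisomy,
        call) sorted by llr_trisomy descending.
    """
    profiles = [chromosome_profile(sites, c, min_sites, llr_threshold)
                for c in sorted(sites["chrom"].unique()) if c not in exclude]
    table = pd.DataFrame(
        [(p.chrom, p.n_sites, p.median_maf, p.llr_trisomy, p.call) for p in profiles],
        columns=["chrom", "n_sites", "median_maf", "llr_trisomy", "call"],
    ).sort_values("llr_trisomy", ascending=False, na_position="last").reset_index(drop=True)
    called = table.loc[table["call"] == "trisomic_like", "chrom"].tolist()
    return called, table


def ekaryotype_tracks(pairs: pd.DataFrame) -> pd.DataFrame:
    """Ideogram-style track records for a paired-site table.

    One row per shared site with its chromosome, position and a side label:
    ``concordant`` (left-of-ideogram ticks) or ``discordant`` (right side).
    """
    if pairs.empty:
        return pd.DataFrame(columns=["chrom", "pos", "side"])
    out = pairs[["chrom", "pos"]].copy()
    out["side"] = np.where(pairs["status"] == "DISCORDANT_PATTERN",
                           "discordant", "concordant")
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def track_density_per_mb(tracks: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.Series:
    """ASE sites per megabase per chromosome, given chromosome lengths in bp."""
    counts = tracks.groupby("chrom").size()
    mb = pd.Series({c: l / 1e6 for c, l in chrom_lengths.items()})
    return (counts / mb).dropna().rename("sites_per_mb")


def plot_ekaryotype(table: pd.DataFrame, tracks: pd.DataFrame | None = None,
                    path: str | None = None):
    """Simple static e-karyotype figure: per-chromosome minor-allele-fraction
    medians with trisomy-like chromosomes highlighted; optional saving."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    colors = ["#c0392b" if c == "trisomic_like" else "#7f8c8d" for c in table["call"]]
    ax.bar(table["chrom"], table["median_maf"], color=colors)
    ax.axhline(0.5, ls="--", lw=0.8, color="k", label="disomic expectation")
    ax.axhline(1 / 3, ls=":", lw=0.8, color="#c0392b", label="trisomic expectation")
    ax.set_ylabel("median minor-allele fraction")
    ax.tick_params(axis="x", rotation=90)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
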