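"""Within-pair site comparison: joining, concordance status, LogASE.

Two co-twins' site tables are joined on (chrom, pos, ref, alt); a shared
site is pattern-discordant when exactly one twin is strictly monoallelic
(the mono-versus-biallelic dichotomy).  LogASE = log2(ASE_A / ASE_B)
measures the magnitude shift of allelic imbalance between the twins; tails
beyond +/-0.8 are counted as altered.  Percentages use shared (paired)
sites as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATUSES = ("CONCORDANT_BIALLELIC", "CONCORDANT_IMBALANCE",
            "CONCORDANT_MONOALLELIC", "DISCORDANT_PATTERN")

PAIR_KEY = ["chrom", "pos", "ref", "alt"]

LOGASE_THRESHOLD = 0.8


def pair_sites(sites_a: pd.DataFrame, sites_b: pd.DataFrame,
               ) -> tuple[pd.DataFrame, dict]:
    """Join two individuals' site tables on (chrom, pos, ref, alt).

    Returns
    -------
    pairs
        One row per shared site with ``_a`` / ``_b`` suffixed per-twin
        columns plus ``status`` and ``log_ase``.
    report
        dict with ``n_only_a``, ``n_only_b``, ``n_allele_mismatch`` —
        sites informative in one twin only, or at the same position with a
        different allele pair (excluded).
    """
    a = sites_a.copy()
    b = sites_b.copy()
    merged = a.merge(b, on=PAIR_KEY, how="outer", suffixes=("_a", "_b"),
                     indicator=True)
    only_a = merged["_merge"] == "left_only"
    only_b = merged["_merge"] == "right_only"
    # same position, different allele pair: present on both sides as
    # unpaired rows at a shared (chrom, pos)
    pos_a = set(map(tuple, merged.loc[only_a, ["chrom", "pos"]].itertuples(index=False)))
    pos_b = set(map(tuple, merged.loc[only_b, ["chrom", "pos"]].itertuples(index=False)))
    mismatched = pos_a & pos_b
    report = {
        "n_only_a": int(only_a.sum()) - len(mismatched),
        "n_only_b": int(only_b.sum()) - len(mismatched),
        "n_allele_mismatch": len(mismatched),
    }
    pairs = merged.loc[merged["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    if pairs.empty:
        pairs["status"] = pd.Series(dtype=str)
        pairs["log_ase"] = pd.Series(dtype=float)
        return pairs, report
    pairs["status"] = _status_vector(pairs["pattern_a"], pairs["pattern_b"])
    ase_a = pairs["ase_a"].to_numpy(float)
    ase_b = pairs["ase_b"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ase = np.log2(ase_a / ase_b)
    log_ase[(ase_a == 0) | (ase_b == 0)] = np.nan
    pairs["log_ase"] = log_ase
    return pairs, report


def _status_vector(pat_a: pd.Series, pat_b: pd.Series) -> np.ndarray:
    mono_a = (pat_a == "MONOALLELIC").to_numpy()
    mono_b = (pat_b == "MONOALLELIC").to_numpy()
    both_imb = ((pat_a == "BIALLELIC_IMBALANCE") & (pat_b == "BIALLELIC_IMBALANCE")).to_numpy()
    out = np.full(len(pat_a), "CONCORDANT_BIALLELIC", dtype=object)
    out[mono_a ^ mono_b] = "DISCORDANT_PATTERN"
    out[mono_a & mono_b] = "CONCORDANT_MONOALLELIC"
    out[both_imb & ~mono_a & ~mono_b] = "CONCORDANT_IMBALANCE"
    return out


def classify_concordance(pattern_a: str, pattern_b: str) -> str:
    """Concordance status of one shared site from the two per-twin patterns.

    Discordance is the mono-versus-biallelic switch: exactly one twin
    MONOALLELIC.  Both imbalanced -> CONCORDANT_IMBALANCE; both monoallelic
    -> CONCORDANT_MONOALLELIC; any other combination (including plain
    biallelic versus imbalance) -> CONCORDANT_BIALLELIC.
    """
    mono_a = pattern_a == "MONOALLELIC"
    mono_b = pattern_b == "MONOALLELIC"
    if mono_a ^ mono_b:
        return "DISCORDANT_PATTERN"
    if mono_a and mono_b:
        return "CONCORDANT_MONOALLELIC"
    if pattern_a == pattern_b == "BIALLELIC_IMBALANCE":
        return "CONCORDANT_IMBALANCE"
    return "CONCORDANT_BIALLELIC"


def compute_logase(ase_a: float, ase_b: float) -> float:
    """log2(ase_a / ase_b); NaN when either ASE value is exactly 0."""
    if ase_a == 0 or ase_b == 0:
        return float("nan")
    return float(np.log2(ase_a / ase_b))


@dataclass
class PairSummary:
    """Per-pair concordance summary over shared sites."""

    n_shared_sites: int = 0
    n_discordant: int = 0
    pct_discordant: float = float("nan")
    n_logase_high: int = 0
    n_logase_low: int = 0
    status_counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        row = {"n_shared_sites": self.n_shared_sites,
               "n_discordant": self.n_discordant,
               "pct_discordant": self.pct_discordant,
               "n_logase_high": self.n_logase_high,
               "n_logase_low": self.n_logase_low}
        row.update({f"n_{s.lower()}": self.status_counts.get(s, 0) for s in STATUSES})
        return pd.DataFrame([row])


def summarize_pair(pairs: pd.DataFrame,
                   logase_threshold: float = LOGASE_THRESHOLD) -> PairSummary:
    """Count concordance statuses and LogASE tails over one pair's shared sites.

    ``pct_discordant`` is 100 * discordant / shared; NaN on empty input.
    LogASE tails count sites with log_ase >= +threshold (high) or
    <= -threshold (low); undefined LogASE values are excluded.
    """
    n = len(pairs)
    if n == 0:
        return PairSummary(status_counts={s: 0 for s in STATUSES})
    counts = pairs["status"].value_counts().to_dict()
    n_disc = counts.get("DISCORDANT_PATTERN", 0)
    log_ase = pairs["log_ase"].to_numpy(float)
    finite = np.isfinite(log_ase)
    return PairSummary(
        n_shared_sites=n,
        n_discordant=n_disc,
        pct_discordant=100.0 * n_disc / n,
        n_logase_high=int((log_ase[finite] >= logase_threshold).sum()),
        n_logase_low=int((log_ase[finite] <= -logase_threshold).sum()),
        status_counts={s: counts.get(s, 0) for s in STATUSES},
    )


def recurrent_discordance(pair_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-pair recurrence of discordance per site.

    Parameters
    ----------
    pair_tables
        Mapping pair_id -> paired-site table (output of :func:`pair_sites`).
        At least two pairs are required.

    Returns
    -------
    One row per site observed in any pair: n_pairs_shared, n_pairs_discordant,
    and ``mixed`` (discordant in at least one pair but concordant in another).
    """
    if len(pair_tables) < 2:
        raise ValueError("recurrent_discordance needs at least two pairs")
    rows = []
    for pid, tab in pair_tables.items():
        sub = tab[PAIR_KEY].copy()
        sub["discordant"] = (tab["status"] == "DISCORDANT_PATTERN").astype(int)
        rows.append(sub)
    allp = pd.concat(rows, ignore_index=True)
    g = allp.groupby(PAIR_KEY, sort=True)["discordant"]
    out = g.agg(n_pairs_shared="size", n_pairs_discordant="sum").reset_index()
    out["mixed"] = (out["n_pairs_discordant"] > 0) & \
        (out["n_pairs_discordant"] < out["n_pairs_shared"])
    return out
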