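"""Cross-referencing ASE results against imprinting, X-inactivation,
pathogenic-variant and mitochondrial contexts.

Every operation here is a filter over its input sites or genes: nothing is
invented, and parent-of-origin is never claimed (read counts alone cannot
establish it) — all-monoallelic multi-site genes outside the imprinting
catalog are reported only as *candidates*.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MITO_CHROM, AnnotationCatalogs

logger = logging.getLogger(__name__)

DEFAULT_IMPRINTED_MIN_SITES = 8
DEFAULT_XCI_MIN_DISCORDANT = 2


def _explode_genes(sites: pd.DataFrame) -> pd.DataFrame:
    work = sites.loc[sites["gene_ids"].astype(str).str.len() > 0].copy()
    work = work.assign(gene_id=work["gene_ids"].astype(str).str.split(","))
    return work.explode("gene_id")


def gene_ase_profiles(sites: pd.DataFrame, catalogs: AnnotationCatalogs | None = None,
                      min_sites: int = DEFAULT_IMPRINTED_MIN_SITES) -> pd.DataFrame:
    """Per-gene monoallelism profile of one individual's site table.

    Columns: gene_id, n_sites, n_monoallelic, n_biallelic_any,
    all_monoallelic, imprinted_flag, candidate_imprinted.  A gene is a
    candidate when every site is monoallelic and it carries at least
    ``min_sites`` eSNVs.
    """
    work = _explode_genes(sites)
    if work.empty:
        return pd.DataFrame(columns=["gene_id", "n_sites", "n_monoallelic",
                                     "n_biallelic_any", "all_monoallelic",
                                     "imprinted_flag", "candidate_imprinted"])
    mono = work["pattern"] == "MONOALLELIC"
    g = work.assign(_mono=mono.astype(int)).groupby("gene_id", sort=True)
    out = g.agg(n_sites=("_mono", "size"), n_monoallelic=("_mono", "sum")).reset_index()
    out["n_biallelic_any"] = out["n_sites"] - out["n_monoallelic"]
    out["all_monoallelic"] = out["n_biallelic_any"] == 0
    imprinted = catalogs.imprinted_genes if catalogs else set()
    out["imprinted_flag"] = out["gene_id"].isin(imprinted)
    out["candidate_imprinted"] = (out["all_monoallelic"]
                                  & (out["n_sites"] >= min_sites)
                                  & ~out["imprinted_flag"])
    return out


def imprinted_gene_report(profiles: pd.DataFrame, catalogs: AnnotationCatalogs,
                          min_sites: int = DEFAULT_IMPRINTED_MIN_SITES,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split all-monoallelic >=min_sites genes into known-imprinted and candidates.

    Returns (known, candidates): known genes are in the imprinting catalog;
    candidates meet the same monoallelism criterion but are uncatalogued
    (possible extended homozygosity cannot be excluded without genotypes).
    """
    eligible = profiles.loc[profiles["all_monoallelic"]
                            & (profiles["n_sites"] >= min_sites)]
    in_cat = eligible["gene_id"].isin(catalogs.imprinted_genes)
    return (eligible.loc[in_cat].reset_index(drop=True),
            eligible.loc[~in_cat].reset_index(drop=True))


def xci_discordance(pairs: pd.DataFrame, catalogs: AnnotationCatalogs,
                    min_discordant: int = DEFAULT_XCI_MIN_DISCORDANT,
                    x_chrom: str = "chrX") -> pd.DataFrame:
    """Per-gene XCI discordance report over paired X-chromosome sites.

    Restricted to catalogued non-escapee genes (escapees are expected
    biallelic from pooled cells, so a mono-versus-bi switch there is not
    an XCI signal).  A gene is reported when at least ``min_discordant``
    of its shared eSNVs are pattern-discordant between the co-twins.

    Columns: gene_id, xci_status, n_discordant_esnvs, reported.
    """
    sub = pairs.loc[pairs["chrom"] == x_chrom].copy()
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "xci_status",
                                     "n_discordant_esnvs", "reported"])
    gene_col = "gene_ids_a" if "gene_ids_a" in sub.columns else "gene_ids"
    sub = sub.assign(gene_id=sub[gene_col].astype(str).str.split(","))
    sub = sub.explode("gene_id")
    sub = sub.loc[sub["gene_id"].str.len() > 0]
    status = sub["gene_id"].map(catalogs.xci_status).fillna("unknown")
    skipped = (status != "non_escapee").sum()
    if skipped:
        logger.info("xci_discordance: excluded %d site-gene rows of escapee/unknown status",
                    int(skipped))
    sub = sub.loc[status == "non_escapee"]
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "xci_status",
                                     "n_discordant_esnvs", "reported"])
    disc = (sub["status"] == "DISCORDANT_PATTERN").astype(int)
    out = (sub.assign(_d=disc).groupby("gene_id", sort=True)["_d"].sum()
           .rename("n_discordant_esnvs").reset_index())
    out["xci_status"] = "non_escapee"
    out["reported"] = out["n_discordant_esnvs"] >= min_discordant
    return out[["gene_id", "xci_status", "n_discordant_esnvs", "reported"]]


def pathogenic_expression(sites: pd.DataFrame, catalogs: AnnotationCatalogs,
                          mono_minor_max: int = 0) -> pd.DataFrame:
    """Expression mode of catalogued pathogenic alleles observed in the data.

    For each ASE site at a catalogued pathogenic position whose risk allele
    is the site's ref or alt base, reports: ``monoallelic_risk`` (only the
    risk allele expressed), ``coexpressed`` (both alleles expressed) or
    ``monoallelic_wildtype``.  Monoallelism uses the pipeline-wide
    ``mono_minor_max`` rule.  Sites whose risk allele matches neither
    observed base are skipped (logged).
    """
    cols = ["chrom", "pos", "ref", "alt", "risk_allele", "condition_label",
            "risk_count", "wildtype_count", "expression_mode"]
    path = catalogs.pathogenic_variants
    if path.empty or sites.empty:
        return pd.DataFrame(columns=cols)
    m = sites.merge(path, on=["chrom", "pos"], how="inner")
    if m.empty:
        return pd.DataFrame(columns=cols)
    risk_is_ref = m["risk_allele"] == m["ref"]
    risk_is_alt = m["risk_allele"] == m["alt"]
    unmatched = ~(risk_is_ref | risk_is_alt)
    if unmatched.any():
        logger.info("pathogenic_expression: skipped %d site(s) whose risk allele "
                    "matches neither observed base", int(unmatched.sum()))
        m = m.loc[~unmatched]
        risk_is_ref = risk_is_ref.loc[m.index]
    risk = np.where(risk_is_ref, m["ref_count"], m["alt_count"]).astype(int)
    wild = np.where(risk_is_ref, m["alt_count"], m["ref_count"]).astype(int)
    mode = np.where(
        (risk > 0) & (wild <= mono_minor_max), "monoallelic_risk",
        np.where((risk > 0) & (wild > 0), "coexpressed", "monoallelic_wildtype"))
    out = m[["chrom", "pos", "ref", "alt", "risk_allele", "condition_label"]].copy()
    out["risk_count"] = risk
    out["wildtype_count"] = wild
    out["expression_mode"] = mode
    return out.reset_index(drop=True)


def mito_heteroplasmy(sites: pd.DataFrame, min_minor: int = 1,
                      mito_chrom: str = MITO_CHROM) -> pd.DataFrame:
    """Mitochondrial sites with both alleles observed (microheteroplasmy).

    The depth filter has already been applied upstream by site calling;
    here a site is heteroplasmic when each allele carries at least
    ``min_minor`` reads.  Non-mitochondrial sites are ignored.
    """
    sub = sites.loc[sites["chrom"] == mito_chrom]
    if sub.empty:
        return sub.copy()
    both = (sub["ref_count"] >= min_minor) & (sub["alt_count"] >= min_minor)
    return sub.loc[both].reset_index(drop=True)
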