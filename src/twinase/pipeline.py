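"""End-to-end orchestration: manifest validation and the full twin-pair run.

A run manifest (YAML or dict) names the per-run count files of the two
individuals of a pair, the gene model, the annotation catalogs and
parameter overrides.  ``run_full_pipeline`` executes filter -> aggregate ->
classify -> pair -> summarise -> heterogeneity -> e-karyotype -> editing ->
crossref and writes every stage's table as a stand-alone TSV plus a
consolidated JSON summary stamped with the parameters used.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd
import yaml

from . import __version__
from .ase import AseParams, call_ase_sites
from .compare import pair_sites, recurrent_discordance, summarize_pair
from .crossref import (gene_ase_profiles, imprinted_gene_report,
                       mito_heteroplasmy, pathogenic_expression, xci_discordance)
from .editing import fit_twin_editing_model, match_editing_sites
from .ekaryotype import detect_aneuploidy, ekaryotype_tracks
from .heterogeneity import gene_summary
from .io import (read_allele_counts, read_annotation_sets, read_editing_catalog,
                 read_gene_model, write_site_table)

logger = logging.getLogger(__name__)


def load_manifest(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_manifest(manifest: dict) -> list[str]:
    """Collect every structural problem with a manifest (never first-failure)."""
    errors = []
    individuals = manifest.get("individuals") or {}
    if len(individuals) != 2:
        errors.append(f"manifest must define exactly two individuals (got {len(individuals)})")
    for name, spec in individuals.items():
        runs = (spec or {}).get("runs") or []
        if not runs:
            errors.append(f"individual '{name}' has no runs")
        seen = set()
        for run in runs:
            rid = run.get("run_id")
            if rid in seen:
                errors.append(f"individual '{name}': duplicate run_id '{rid}'")
            seen.add(rid)
            path = run.get("path")
            if not path or not os.path.exists(path):
                errors.append(f"individual '{name}' run '{rid}': missing counts file {path!r}")
    gm = manifest.get("gene_model")
    if gm and not os.path.exists(gm):
        errors.append(f"gene_model file not found: {gm}")
    for key, path in (manifest.get("catalogs") or {}).items():
        if path and not os.path.exists(path):
            errors.append(f"catalog '{key}' file not found: {path}")
    return errors


def _load_individual(name: str, spec: dict) -> pd.DataFrame:
    frames = [read_allele_counts(run["path"], name, run["run_id"])
              for run in spec["runs"]]
    return pd.concat(frames, ignore_index=True)


def run_full_pipeline(manifest: dict, outdir: str | None = None) -> dict:
    """Execute every stage for one pair; returns the report bundle as a dict.

    When ``outdir`` is given (or set in the manifest), all stage tables are
    written there as TSVs along with ``summary.json``.
    """
    errors = validate_manifest(manifest)
    if errors:
        raise ValueError("invalid manifest:\n  " + "\n  ".join(errors))
    outdir = outdir or manifest.get("outdir")
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    p = manifest.get("params") or {}
    params = AseParams(min_depth=int(p.get("min_depth", 12)),
                       alpha=float(p.get("alpha", 0.05)),
                       mono_minor_max=int(p.get("mono_minor_max", 0)))
    logase_thr = float(p.get("logase_threshold", 0.8))
    editing_thr = float(p.get("editing_threshold", 0.25))
    agg_method = p.get("aggregation", "q1_of_ase")

    gene_model = read_gene_model(manifest["gene_model"]) if manifest.get("gene_model") else None
    cat_paths = manifest.get("catalogs") or {}
    catalogs = read_annotation_sets(imprinted=cat_paths.get("imprinted"),
                                    xci=cat_paths.get("xci"),
                                    pathogenic=cat_paths.get("pathogenic"),
                                    repeats=cat_paths.get("repeats"))
    editing_catalog = (read_editing_catalog(cat_paths["editing"])
                       if cat_paths.get("editing") else pd.DataFrame(
                           columns=["chrom", "pos", "strand"]))

    names = list(manifest["individuals"])
    sites = {}
    for name in names:
        stage = f"call_ase[{name}]"
        logger.info("stage %s", stage)
        counts = _load_individual(name, manifest["individuals"][name])
        sites[name] = call_ase_sites(counts, params, gene_model, method=agg_method)
        if outdir:
            write_site_table(sites[name], os.path.join(outdir, f"sites_{name}.tsv"))

    a, b = names
    pairs, join_report = pair_sites(sites[a], sites[b])
    summary = summarize_pair(pairs, logase_thr)
    tracks = ekaryotype_tracks(pairs)
    gene_tables = {n: gene_summary(sites[n]) for n in names}
    karyo = {n: detect_aneuploidy(sites[n]) for n in names}
    editing_table = match_editing_sites(pairs, editing_catalog,
                                        catalogs.repeat_trees, editing_thr)
    fit = None
    if len(editing_table) >= 3:
        fit = fit_twin_editing_model(editing_table["level1"], editing_table["level2"])
    profiles = {n: gene_ase_profiles(sites[n], catalogs) for n in names}
    imprint = {n: imprinted_gene_report(profiles[n], catalogs) for n in names}
    xci = xci_discordance(pairs, catalogs)
    pathog = {n: pathogenic_expression(sites[n], catalogs,
                                       params.mono_minor_max) for n in names}
    mito = {n: mito_heteroplasmy(sites[n]) for n in names}

    report = {
        "software": {"name": "twinase", "version": __version__},
        "params": {"min_depth": params.min_depth, "alpha": params.alpha,
                   "mono_minor_max": params.mono_minor_max,
                   "logase_threshold": logase_thr,
                   "editing_threshold": editing_thr,
                   "aggregation": agg_method},
        "individuals": names,
        "n_sites": {n: int(len(sites[n])) for n in names},
        "join": join_report,
        "pair_summary": summary.to_frame().iloc[0].to_dict(),
        "aneuploidy_calls": {n: karyo[n][0] for n in names},
        "gene_category_counts": {
            n: gene_tables[n][0]["category"].value_counts().to_dict() for n in names},
        "esnv_histogram": {n: gene_tables[n][1].to_dict() for n in names},
        "editing": {
            "n_matched": int(len(editing_table)),
            "discordance_counts": editing_table["discordance"].value_counts().to_dict()
            if len(editing_table) else {},
            "model": None if fit is None else
            {"slope": fit.slope, "intercept": fit.intercept,
             "r_squared": fit.r_squared, "n_points": fit.n_points},
        },
        "crossref": {
            "known_imprinted": {n: imprint[n][0]["gene_id"].tolist() for n in names},
            "candidate_imprinted": {n: imprint[n][1]["gene_id"].tolist() for n in names},
            "xci_reported": xci.loc[xci["reported"], "gene_id"].tolist(),
            "n_pathogenic_sites": {n: int(len(pathog[n])) for n in names},
            "n_mito_heteroplasmic": {n: int(len(mito[n])) for n in names},
        },
    }

    if outdir:
        pairs.to_csv(os.path.join(outdir, "paired_sites.tsv"), sep="\t", index=False)
        tracks.to_csv(os.path.join(outdir, "ekaryotype_tracks.tsv"), sep="\t", index=False)
        summary.to_frame().to_csv(os.path.join(outdir, "pair_summary.tsv"),
                                  sep="\t", index=False)
        for n in names:
            gene_tables[n][0].to_csv(os.path.join(outdir, f"gene_heterogeneity_{n}.tsv"),
                                     sep="\t", index=False)
            karyo[n][1].to_csv(os.path.join(outdir, f"ekaryotype_profile_{n}.tsv"),
                               sep="\t", index=False)
            pathog[n].to_csv(os.path.join(outdir, f"pathogenic_{n}.tsv"),
                             sep="\t", index=False)
            mito[n].to_csv(os.path.join(outdir, f"mito_heteroplasmy_{n}.tsv"),
                           sep="\t", index=False)
        editing_table.to_csv(os.path.join(outdir, "editing_sites.tsv"),
                             sep="\t", index=False)
        xci.to_csv(os.path.join(outdir, "xci_report.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def run_cohort(pair_manifests: dict[str, dict], outdir: str | None = None) -> dict:
    """Run several pairs and add the cross-pair recurrence table."""
    reports, pair_tables = {}, {}
    for pid, man in pair_manifests.items():
        sub = os.path.join(outdir, pid) if outdir else None
        reports[pid] = run_full_pipeline(man, sub)
        if sub:
            pair_tables[pid] = pd.read_csv(os.path.join(sub, "paired_sites.tsv"), sep="\t")
    out = {"pairs": reports}
    if len(pair_tables) >= 2:
        rec = recurrent_discordance(pair_tables)
        if outdir:
            rec.to_csv(os.path.join(outdir, "recurrence.tsv"), sep="\t", index=False)
        out["n_recurrent_discordant"] = int(
            (rec["n_pairs_discordant"] == rec["n_pairs_shared"]).sum())
    return out
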