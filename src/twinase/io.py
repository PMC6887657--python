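"""Readers and writers for the pipeline's tabular inputs and outputs.

All coordinates inside the pipeline are 1-based inclusive.  ASEReadCounter
TSVs and GTF are already 1-based; BED-style repeat files are 0-based
half-open and converted on read.  Chromosome names are normalised to the
"chr"-prefixed style (the mitochondrial contig becomes ``chrM``).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order for per-run allele-count tables
COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "sample_id", "run_id",
]

#: canonical column order for aggregated per-site ASE tables
SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ref_count", "alt_count",
    "ase", "p_value", "pattern", "n_support", "gene_ids", "region_class",
]

REGION_CLASSES = ("five_prime_utr", "three_prime_utr", "exon", "intron", "intergenic")

#: mitochondrial contig after normalisation
MITO_CHROM = "chrM"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the chr-prefixed style.

    ``"21" -> "chr21"``, ``"MT"/"chrMT"/"M" -> "chrM"``, ``"chrX" -> "chrX"``.
    """
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in {"MT", "M"}:
        return MITO_CHROM
    return "chr" + name


# ---------------------------------------------------------------------------
# allele counts (ASEReadCounter dialect)
# ---------------------------------------------------------------------------

_ASE_RC_REQUIRED = {
    "contig": "chrom",
    "position": "pos",
    "refAllele": "ref",
    "altAllele": "alt",
    "refCount": "ref_count",
    "altCount": "alt_count",
}


def read_allele_counts(path: str | os.PathLike, sample_id: str, run_id: str) -> pd.DataFrame:
    """Read one ASEReadCounter-style TSV into a canonical count table.

    Parameters
    ----------
    path
        Tab-separated file whose header names at least ``contig``,
        ``position``, ``refAllele``, ``altAllele``, ``refCount``,
        ``altCount``; extra columns are ignored.
    sample_id, run_id
        Labels attached to every row (one file = one sequencing run).

    Returns
    -------
    DataFrame with :data:`COUNT_COLUMNS`.  Positions stay 1-based.

    Raises
    ------
    FormatError
        If a required column is missing, a count fails to parse as a
        non-negative integer, or an allele is not a single A/C/G/T base
        (the offending line number is reported).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _ASE_RC_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    df = df[list(_ASE_RC_REQUIRED)].rename(columns=_ASE_RC_REQUIRED)
    if df.empty:
        out = pd.DataFrame(columns=COUNT_COLUMNS)
        return out.astype({"pos": int, "ref_count": int, "alt_count": int}, errors="ignore")

    for col in ("pos", "ref_count", "alt_count"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.astype("Int64").astype(float))
        if bad.any():
            line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: line {line}: non-integer value in '{col}'")
        df[col] = parsed.astype(int)
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any() or (df["pos"] < 1).any():
        bad = (df["ref_count"] < 0) | (df["alt_count"] < 0) | (df["pos"] < 1)
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}: line {line}: negative count or position < 1")

    for col in ("ref", "alt"):
        df[col] = df[col].str.upper()
        bad = ~df[col].isin(VALID_BASES)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(
                f"{path}: line {line}: allele '{df.loc[df.index[bad][0], col]}' "
                "is not a single A/C/G/T base"
            )
    same = df["ref"] == df["alt"]
    if same.any():
        line = int(df.index[same][0]) + 2
        raise FormatError(f"{path}: line {line}: ref and alt alleles are identical")

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["sample_id"] = sample_id
    df["run_id"] = run_id
    return df[COUNT_COLUMNS].reset_index(drop=True)


def write_allele_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a canonical count table back out in the ASEReadCounter dialect."""
    inverse = {v: k for k, v in _ASE_RC_REQUIRED.items()}
    out = df[list(inverse)].rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene model (GTF)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Classified gene intervals with fast positional lookup.

    ``genes`` maps gene_id -> dict with chrom, strand, span (start, end) and
    per-class interval lists (1-based inclusive).  ``_trees`` holds one
    IntervalTree per chromosome whose payloads are (gene_id, region_class);
    tree coordinates are half-open internally.
    """

    genes: dict = field(default_factory=dict)
    _trees: dict = field(default_factory=dict)

    def add_interval(self, chrom: str, start: int, end: int, gene_id: str, cls: str) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, (gene_id, cls))

    def classify(self, chrom: str, pos: int) -> tuple[str, list[str]]:
        """Region class and overlapping gene ids for a 1-based position.

        Precedence within a gene: five_prime_utr > three_prime_utr > exon >
        intron; a position in no gene is intergenic.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic", []
        hits = tree[pos]
        if not hits:
            return "intergenic", []
        genes = sorted({gid for iv in hits for gid, _ in [iv.data]})
        classes = {cls for iv in hits for _, cls in [iv.data]}
        for cls in ("five_prime_utr", "three_prime_utr", "exon", "intron"):
            if cls in classes:
                return cls, genes
        return "intergenic", genes

    def classify_table(self, chroms, positions) -> tuple[list[str], list[str]]:
        """Vector form of :meth:`classify`; gene ids comma-joined."""
        region, gids = [], []
        for c, p in zip(chroms, positions):
            cls, g = self.classify(c, int(p))
            region.append(cls)
            gids.append(",".join(g))
        return region, gids


def _subtract_intervals(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Integer-interval subtraction: span minus the union of blocks (all 1-based inclusive)."""
    out = []
    cursor = span[0]
    for s, e in sorted(blocks):
        if s > cursor:
            out.append((cursor, min(s - 1, span[1])))
        cursor = max(cursor, e + 1)
    if cursor <= span[1]:
        out.append((cursor, span[1]))
    return [(s, e) for s, e in out if s <= e]


def read_gene_model(path: str | os.PathLike) -> GeneModel:
    """Load a GTF (Ensembl dialect) into a :class:`GeneModel`.

    Introns are derived as the gene span minus the union of its exons; UTR
    intervals are retained as their own classes.  Feature types other than
    gene/exon/five_prime_utr/three_prime_utr are ignored (count logged).

    Raises
    ------
    FormatError
        If an exon lies outside its gene's span.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneModel()
    model = GeneModel()
    known = {"gene", "exon", "five_prime_utr", "three_prime_utr"}
    ignored = 0
    per_gene: dict[str, dict] = {}
    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype not in known:
            ignored += 1
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        chrom = normalize_chrom(feat.seqid)
        rec = per_gene.setdefault(
            gid, {"chrom": chrom, "strand": feat.strand, "span": None,
                  "exon": [], "five_prime_utr": [], "three_prime_utr": []},
        )
        if ftype == "gene":
            rec["span"] = (feat.start, feat.end)
            rec["strand"] = feat.strand
        elif ftype in ("exon", "five_prime_utr", "three_prime_utr"):
            rec[ftype].append((feat.start, feat.end))
    if ignored:
        logger.info("read_gene_model: ignored %d feature rows of unknown type", ignored)

    for gid, rec in per_gene.items():
        span = rec["span"]
        if span is None:
            if not rec["exon"]:
                continue
            span = (min(s for s, _ in rec["exon"]), max(e for _, e in rec["exon"]))
        for s, e in rec["exon"]:
            if s < span[0] or e > span[1]:
                raise FormatError(f"gene {gid}: exon {s}-{e} outside gene span {span}")
        introns = _subtract_intervals(span, rec["exon"]) if rec["exon"] else []
        chrom = rec["chrom"]
        model.genes[gid] = {
            "chrom": chrom, "strand": rec["strand"], "span": span,
            "exon": sorted(rec["exon"]), "intron": introns,
            "five_prime_utr": sorted(rec["five_prime_utr"]),
            "three_prime_utr": sorted(rec["three_prime_utr"]),
        }
        for cls in ("exon", "intron", "five_prime_utr", "three_prime_utr"):
            for s, e in model.genes[gid][cls]:
                model.add_interval(chrom, s, e, gid, cls)
    return model


# ---------------------------------------------------------------------------
# editing catalog
# ---------------------------------------------------------------------------

def read_editing_catalog(path: str | os.PathLike) -> pd.DataFrame:
    """Read a canonical A-to-I(G) site catalog (TSV: chrom, pos, strand).

    Duplicate (chrom, pos) rows with a consistent strand collapse to one
    record; rows whose duplicates disagree on strand are dropped entirely
    (counted in the log).  Positions are 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "strand": str},
                     comment="#")
    required = {"chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    if df.empty:
        return df[["chrom", "pos", "strand"]]
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}: line {line}: strand must be '+' or '-'")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    nstrand = df.groupby(["chrom", "pos"])["strand"].nunique()
    conflicted = nstrand[nstrand > 1]
    if len(conflicted):
        logger.warning("read_editing_catalog: dropped %d position(s) with conflicting strands",
                       len(conflicted))
        df = df.set_index(["chrom", "pos"]).drop(index=conflicted.index).reset_index()
    return (df.drop_duplicates(["chrom", "pos"])
              .sort_values(["chrom", "pos"]).reset_index(drop=True)[["chrom", "pos", "strand"]])


# ---------------------------------------------------------------------------
# annotation catalogs
# ---------------------------------------------------------------------------

XCI_LABELS = ("escapee", "non_escapee", "unknown")


@dataclass
class AnnotationCatalogs:
    """Local reference inputs: imprinting, XCI status, pathogenic variants, repeats."""

    imprinted_genes: set = field(default_factory=set)
    xci_status: dict = field(default_factory=dict)
    pathogenic_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "risk_allele", "condition_label"]))
    repeat_trees: dict = field(default_factory=dict)  # chrom -> IntervalTree, 1-based incl as [s, e+1)

    def in_repeat(self, chrom: str, pos: int) -> bool:
        tree = self.repeat_trees.get(chrom)
        return bool(tree and tree[pos])


def read_annotation_sets(imprinted: str | None = None, xci: str | None = None,
                         pathogenic: str | None = None, repeats: str | None = None,
                         ) -> AnnotationCatalogs:
    """Load the four optional annotation files; absent paths yield empty components.

    * imprinted: TSV/plain list, first column = gene_id.
    * xci: TSV with columns gene_id, status (escapee / non_escapee / unknown).
    * pathogenic: TSV with columns chrom, pos, risk_allele, condition_label.
    * repeats: BED3, 0-based half-open, converted to 1-based inclusive.
    """
    cats = AnnotationCatalogs()
    if imprinted and os.path.exists(imprinted):
        col = pd.read_csv(imprinted, sep="\t", header=None, comment="#", dtype=str)[0]
        cats.imprinted_genes = set(col.str.strip())
    if xci and os.path.exists(xci):
        df = pd.read_csv(xci, sep="\t", header=None, names=["gene_id", "status"],
                         comment="#", dtype=str)
        bad = ~df["status"].isin(XCI_LABELS)
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise FormatError(f"{xci}: line {line}: status must be one of {XCI_LABELS}")
        cats.xci_status = dict(zip(df["gene_id"], df["status"]))
    if pathogenic and os.path.exists(pathogenic):
        df = pd.read_csv(pathogenic, sep="\t", comment="#",
                         dtype={"chrom": str, "pos": int, "risk_allele": str,
                                "condition_label": str})
        missing = {"chrom", "pos", "risk_allele", "condition_label"} - set(df.columns)
        if missing:
            raise FormatError(f"{pathogenic}: missing column(s) {sorted(missing)}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        cats.pathogenic_variants = df
    if repeats and os.path.exists(repeats):
        bed = pd.read_csv(repeats, sep="\t", header=None, comment="#",
                          names=["chrom", "start", "end"], usecols=[0, 1, 2],
                          dtype={0: str, 1: int, 2: int})
        if (bed["start"] >= bed["end"]).any():
            raise FormatError(f"{repeats}: repeat interval with start >= end")
        for _, row in bed.iterrows():
            chrom = normalize_chrom(row["chrom"])
            # BED half-open [start, end) -> 1-based inclusive [start+1, end]
            cats.repeat_trees.setdefault(chrom, IntervalTree()).addi(
                int(row["start"]) + 1, int(row["end"]) + 1, True)
    return cats


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_site_table(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an aggregated ASE site table (stable header, TSV)."""
    sites.reindex(columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    """Re-read a site table written by :func:`write_site_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pattern": str,
                                            "gene_ids": str, "region_class": str})
    df["gene_ids"] = df["gene_ids"].fillna("")
    return df
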