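import numpy as np
import pandas as pd
import pytest

from twinase.io import COUNT_COLUMNS


@pytest.fixture
def make_counts_file(tmp_path):
    """Write rows in the ASEReadCounter dialect; returns the path."""

    def _make(rows, name="counts.tsv", header=None):
        header = header or ["contig", "position", "refAllele", "altAllele",
                            "refCount", "altCount"]
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return _make


@pytest.fixture
def make_gtf(tmp_path):
    """Write GTF feature rows (chrom, type, start, end, gene_id); returns the path."""

    def _make(features, name="genes.gtf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, ftype, start, end, gid in features:
                fh.write(f"{chrom}\ttest\t{ftype}\t{start}\t{end}\t.\t+\t.\t"
                         f'gene_id "{gid}";\n')
        return path

    return _make


def counts_frame(rows, sample_id="s1", run_id="r1"):
    """Build a canonical count table from (chrom, pos, ref, alt, rc, ac) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "ref_count", "alt_count"])
    df["sample_id"] = sample_id
    df["run_id"] = run_id
    return df[COUNT_COLUMNS]


def sites_frame(rows):
    """Build a site table from (chrom, pos, ref, alt, rc, ac, ase, p, pattern) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ref_count",
                                     "alt_count", "ase", "p_value", "pattern"])
    df["n_support"] = 1
    df["gene_ids"] = ""
    df["region_class"] = "exon"
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
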