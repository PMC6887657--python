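from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinase.ase import (AseParams, aggregate_replicates, annotate_region,
                         binomial_pvalue, call_ase_sites, classify_pattern,
                         compute_ase, filter_informative)
from twinase.io import read_gene_model
from tests.conftest import counts_frame


def enumeration_pvalue(k, n):
    """Brute-force two-sided binomial p at p=0.5: sum of all outcomes whose
    (integer) binomial coefficient does not exceed the observed one."""
    ck = comb(n, k)
    return sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= ck) / 2 ** n


class TestComputeAse:
    @pytest.mark.parametrize("ref,alt,expected", [
        (6, 6, 0.0), (12, 0, 0.5), (0, 12, 0.5), (9, 3, 0.25), (3, 9, 0.25),
    ])
    def test_values(self, ref, alt, expected):
        assert compute_ase(ref, alt) == pytest.approx(expected, abs=1e-15)

    def test_zero_depth_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_ase(0, 0)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_attainment(self, r, a):
        if r + a == 0:
            return
        v = compute_ase(r, a)
        assert 0.0 <= v <= 0.5
        assert (v == 0.0) == (r == a)
        assert (v == 0.5) == (min(r, a) == 0)


class TestBinomialPvalue:
    def test_balanced_is_one(self):
        assert binomial_pvalue(6, 6) == 1.0

    def test_monoallelic_tail(self):
        assert binomial_pvalue(12, 0) == pytest.approx(2 * 0.5 ** 12, abs=1e-15)

    def test_ten_two(self):
        assert binomial_pvalue(10, 2) == pytest.approx(158 / 4096, abs=1e-15)

    def test_enumeration_oracle_all_depths_to_40(self):
        for n in range(1, 41):
            for k in range(n + 1):
                assert binomial_pvalue(k, n - k) == pytest.approx(
                    enumeration_pvalue(k, n), abs=1e-12), (k, n)

    @pytest.mark.parametrize("k,n", [(10, 12), (3, 60), (30, 60), (45, 100), (7, 13)])
    def test_agrees_with_scipy(self, k, n):
        expected = stats.binomtest(k, n, 0.5).pvalue
        assert binomial_pvalue(k, n - k) == pytest.approx(expected, rel=1e-9)


class TestClassifyPattern:
    @pytest.mark.parametrize("ref,alt,expected", [
        (12, 0, "MONOALLELIC"),
        (0, 12, "MONOALLELIC"),
        (10, 2, "BIALLELIC_IMBALANCE"),
        (7, 5, "BIALLELIC"),
        (6, 6, "BIALLELIC"),
    ])
    def test_examples(self, ref, alt, expected):
        assert classify_pattern(ref, alt) == expected

    def test_mono_minor_max_relaxation(self):
        params = AseParams(mono_minor_max=1)
        assert classify_pattern(19, 1, params) == "MONOALLELIC"

    @pytest.mark.parametrize("depth", [12, 16, 20, 30])
    def test_monotone_in_imbalance_at_fixed_depth(self, depth):
        # once imbalanced, shifting further toward ref while keeping alt >= 1
        # can only stay imbalanced or become monoallelic
        order = ["BIALLELIC", "BIALLELIC_IMBALANCE", "MONOALLELIC"]
        seen_imbalance = False
        for ref in range(depth // 2, depth):
            alt = depth - ref
            label = classify_pattern(ref, alt)
            if seen_imbalance:
                assert label in ("BIALLELIC_IMBALANCE", "MONOALLELIC")
            if label == "BIALLELIC_IMBALANCE":
                seen_imbalance = True
            assert order.index(label) >= 0

    def test_classification_accuracy_on_simulated_classes(self, rng):
        # depth >= 40, true ref fraction 0.5 / 0.8 / 1.0
        n = 2000
        depth = 40
        for p, expected in ((1.0, "MONOALLELIC"), (0.8, "BIALLELIC_IMBALANCE")):
            refs = rng.binomial(depth, p, size=n)
            labels = [classify_pattern(r, depth - r) for r in refs]
            acc = np.mean([l == expected for l in labels])
            assert acc > 0.90, (p, acc)
        refs = rng.binomial(depth, 0.5, size=n)
        labels = [classify_pattern(r, depth - r) for r in refs]
        assert np.mean([l == "BIALLELIC" for l in labels]) > 0.90


class TestFilterInformative:
    def test_depth_boundary(self):
        counts = counts_frame([("chr1", 1, "A", "G", 6, 5),
                               ("chr1", 2, "A", "G", 6, 6)])
        kept = filter_informative(counts)
        assert kept["pos"].tolist() == [2]

    def test_empty_input(self):
        assert filter_informative(counts_frame([])).empty


class TestAggregateReplicates:
    def test_single_run_passthrough(self):
        one = counts_frame([("chr1", 1, "A", "G", 9, 3)])
        r, a, ase, n = aggregate_replicates(one)
        assert (r, a, n) == (9, 3, 1)
        assert ase == pytest.approx(0.25)

    def test_identical_replicas(self):
        runs = pd.concat([counts_frame([("chr1", 1, "A", "G", 6, 6)], run_id=f"r{i}")
                          for i in range(4)], ignore_index=True)
        r, a, ase, n = aggregate_replicates(runs)
        assert (r, a, ase, n) == (6, 6, 0.0, 4)

    def test_q1_linear_interpolation(self):
        # per-run ASE values 0.1, 0.2, 0.3, 0.4 -> Q1 = 0.175 (type-7 quartile)
        counts = [(12, 8), (14, 6), (16, 4), (18, 2)]  # ASE 0.1/0.2/0.3/0.4 at depth 20
        runs = pd.concat([counts_frame([("chr1", 1, "A", "G", rc, ac)], run_id=f"r{i}")
                          for i, (rc, ac) in enumerate(counts)], ignore_index=True)
        r, a, ase, n = aggregate_replicates(runs)
        assert ase == pytest.approx(np.percentile([0.1, 0.2, 0.3, 0.4], 25))
        assert ase == pytest.approx(0.175)
        assert (r, a) == (14, 6)  # run with ASE 0.2, closest to 0.175
        assert n == 4

    def test_sum_counts_mode(self):
        runs = pd.concat([counts_frame([("chr1", 1, "A", "G", 9, 3)], run_id="r1"),
                          counts_frame([("chr1", 1, "A", "G", 3, 9)], run_id="r2")],
                         ignore_index=True)
        r, a, ase, n = aggregate_replicates(runs, method="sum_counts")
        assert (r, a, ase, n) == (12, 12, 0.0, 2)

    def test_mixed_alleles_error(self):
        runs = pd.concat([counts_frame([("chr1", 1, "A", "G", 9, 3)], run_id="r1"),
                          counts_frame([("chr1", 1, "A", "C", 9, 3)], run_id="r2")],
                         ignore_index=True)
        with pytest.raises(ValueError):
            aggregate_replicates(runs)


class TestCallAseSites:
    def test_table_aggregation_matches_scalar_path(self, rng):
        rows = []
        for pos in range(1, 30):
            for run in range(3):
                d = 20 + int(rng.integers(0, 20))
                rc = int(rng.binomial(d, 0.6))
                rows.append(("chr1", pos, "A", "G", rc, d - rc, "s1", f"r{run}"))
        counts = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                             "ref_count", "alt_count",
                                             "sample_id", "run_id"])
        sites = call_ase_sites(counts)
        for _, site in sites.iterrows():
            per_run = counts[(counts["pos"] == site["pos"])]
            per_run = per_run[(per_run["ref_count"] + per_run["alt_count"]) >= 12]
            r, a, ase, n = aggregate_replicates(per_run)
            assert (site["ref_count"], site["alt_count"]) == (r, a)
            assert site["ase"] == pytest.approx(ase)
            assert site["n_support"] == n
            assert site["p_value"] == pytest.approx(binomial_pvalue(r, a))

    def test_pattern_invariants(self, rng):
        depth = rng.integers(12, 60, size=300)
        refs = rng.binomial(depth, rng.uniform(0, 1, size=300))
        counts = counts_frame([("chr1", i + 1, "A", "G", int(r), int(d - r))
                               for i, (r, d) in enumerate(zip(refs, depth))])
        sites = call_ase_sites(counts)
        mono = sites["pattern"] == "MONOALLELIC"
        assert (sites.loc[mono, ["ref_count", "alt_count"]].min(axis=1) == 0).all()
        imb = sites["pattern"] == "BIALLELIC_IMBALANCE"
        assert (sites.loc[imb, "p_value"] < 0.05).all()
        assert (sites.loc[imb, ["ref_count", "alt_count"]].min(axis=1) > 0).all()
        assert sites["ase"].between(0, 0.5).all()


class TestAnnotateRegion:
    def test_precedence_and_intergenic(self, make_gtf):
        model = read_gene_model(make_gtf([
            ("chr1", "gene", 100, 300, "G1"),
            ("chr1", "exon", 100, 300, "G1"),
            ("chr1", "three_prime_utr", 250, 300, "G1"),
        ]))
        sites = counts_frame([("chr1", 260, "A", "G", 9, 9),
                              ("chr1", 150, "A", "G", 9, 9),
                              ("chr1", 5000, "A", "G", 9, 9)])
        out = annotate_region(sites, model)
        assert out["region_class"].tolist() == ["three_prime_utr", "exon", "intergenic"]
        assert out["gene_ids"].tolist() == ["G1", "G1", ""]
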