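import numpy as np
import pandas as pd
import pytest

from twinase.ase import call_ase_sites
from twinase.compare import pair_sites, summarize_pair
from twinase.editing import match_editing_sites
from twinase.io import read_annotation_sets, read_editing_catalog, read_gene_model
from twinase.simulate import (SimulationConfig, build_gene_table, emit_catalogs,
                              simulate_pair, write_pair)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_fractions={"biallelic": 0.5, "monoallelic": 0.4})

    def test_bad_pair_mode_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pair_mode="siblings")


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=7, n_sites=500)
        a1, b1, t1 = simulate_pair(cfg)
        a2, b2, t2 = simulate_pair(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_written_files_hash_equal(self, tmp_path):
        import hashlib

        def digest(d):
            h = hashlib.sha256()
            for p in sorted(d.glob("**/*")):
                if p.is_file():
                    h.update(p.read_bytes())
            return h.hexdigest()

        cfg = SimulationConfig(seed=3, n_sites=300)
        write_pair(cfg, str(tmp_path / "one"))
        write_pair(cfg, str(tmp_path / "two"))
        assert digest(tmp_path / "one") == digest(tmp_path / "two")

    def test_different_seeds_differ(self):
        a1, _, _ = simulate_pair(SimulationConfig(seed=1, n_sites=300))
        a2, _, _ = simulate_pair(SimulationConfig(seed=2, n_sites=300))
        assert not a1.equals(a2)


class TestCalibration:
    def test_biallelic_marginal_fraction(self):
        cfg = SimulationConfig(
            seed=11, n_sites=12000,
            class_fractions={"biallelic": 1.0, "imbalance": 0, "monoallelic": 0,
                             "imprinted_gene": 0, "xci_gene": 0, "edited_site": 0,
                             "mito_heteroplasmic": 0},
            replicates_per_twin=1)
        counts, _, _ = simulate_pair(cfg)
        depth = counts["ref_count"] + counts["alt_count"]
        frac = counts["ref_count"].sum() / depth.sum()
        se = np.sqrt(0.25 / depth.sum())
        assert abs(frac - 0.5) < 3 * se

    def test_trisomy_dosage_mean_ase_at_high_depth(self):
        cfg = SimulationConfig(
            seed=13, n_sites=4000, depth_mean=200.0, trisomy_chrom="chr21",
            discordance_injection=0.0)
        counts_a, _, truth = simulate_pair(cfg)
        sites = call_ase_sites(counts_a)
        tri = truth.loc[truth["trisomy"]
                        & (truth["p_ref_a"] > 0) & (truth["p_ref_a"] < 1),
                        ["chrom", "pos"]]
        onto = sites.merge(tri, on=["chrom", "pos"])
        assert abs(onto["ase"].mean() - abs(0.5 - 1.0 / 3.0)) < 0.01

    def test_no_injection_discordance_below_one_percent(self):
        cfg = SimulationConfig(seed=17, n_sites=6000, discordance_injection=0.0)
        ca, cb, _ = simulate_pair(cfg)
        pairs, _ = pair_sites(call_ase_sites(ca), call_ase_sites(cb))
        assert summarize_pair(pairs).pct_discordant < 1.0

    def test_unrelated_discordance_exceeds_mz(self):
        mz = SimulationConfig(seed=19, n_sites=4000)
        un = SimulationConfig(seed=19, n_sites=4000, pair_mode="unrelated")
        rates = {}
        for name, cfg in (("mz", mz), ("un", un)):
            ca, cb, _ = simulate_pair(cfg)
            pairs, _ = pair_sites(call_ase_sites(ca), call_ase_sites(cb))
            rates[name] = summarize_pair(pairs).pct_discordant
        assert rates["un"] > rates["mz"]


class TestCatalogs:
    def test_catalog_contains_planted_plus_decoys(self, tmp_path):
        cfg = SimulationConfig(seed=23, n_sites=2000, n_decoy_editing=5)
        _, _, truth = simulate_pair(cfg)
        paths = emit_catalogs(cfg, truth, str(tmp_path))
        cat = read_editing_catalog(paths["editing_catalog"])
        n_planted = truth["class_a"].eq("edited_site").sum()
        assert len(cat) == n_planted + 5

    def test_decoy_in_repeat_filtered_downstream(self, tmp_path):
        cfg = SimulationConfig(seed=29, n_sites=2000, n_decoy_editing=10,
                               decoy_repeat_fraction=1.0)
        ca, cb, truth = simulate_pair(cfg)
        paths = emit_catalogs(cfg, truth, str(tmp_path))
        cats = read_annotation_sets(repeats=paths["repeats"])
        catalog = read_editing_catalog(paths["editing_catalog"])
        pairs, _ = pair_sites(call_ase_sites(ca), call_ase_sites(cb))
        matched = match_editing_sites(pairs, catalog, cats.repeat_trees)
        planted = set(map(tuple, truth.loc[truth["class_a"] == "edited_site",
                                           ["chrom", "pos"]].itertuples(index=False)))
        got = set(map(tuple, matched[["chrom", "pos"]].itertuples(index=False)))
        assert got <= planted  # every decoy is repeat-masked, none can match

    def test_zero_imprinted_genes_gives_empty_list(self, tmp_path):
        cfg = SimulationConfig(seed=31, n_sites=500, n_imprinted_genes=1,
                               class_fractions={**SimulationConfig().class_fractions})
        # remove imprinted mass entirely
        cf = dict(cfg.class_fractions)
        cf["biallelic"] += cf.pop("imprinted_gene")
        cfg = SimulationConfig(seed=31, n_sites=500, n_imprinted_genes=0,
                               class_fractions=cf)
        _, _, truth = simulate_pair(cfg)
        paths = emit_catalogs(cfg, truth, str(tmp_path))
        imp = open(paths["imprinted"]).read().strip()
        assert imp == ""

    def test_gene_model_annotates_planted_genes(self, tmp_path):
        cfg = SimulationConfig(seed=37, n_sites=1500)
        ca, _, truth = simulate_pair(cfg)
        paths = emit_catalogs(cfg, truth, str(tmp_path))
        model = read_gene_model(paths["gtf"])
        sites = call_ase_sites(ca, gene_model=model)
        merged = sites.merge(truth[["chrom", "pos", "gene_id"]], on=["chrom", "pos"])
        with_gene = merged.loc[merged["gene_id"].astype(str).str.len() > 0]
        hit = [g in ids.split(",") for g, ids in
               zip(with_gene["gene_id"], with_gene["gene_ids"])]
        assert np.mean(hit) == 1.0


class TestGeneLayout:
    def test_special_genes_present(self):
        genes = build_gene_table(SimulationConfig())
        kinds = genes["kind"].value_counts()
        assert kinds["imprinted"] == 3
        assert kinds["xci_non_escapee"] == 3
        assert kinds["xci_escapee"] == 2

    def test_imprinted_sites_land_in_imprinted_genes(self):
        cfg = SimulationConfig(seed=41, n_sites=3000)
        _, _, truth = simulate_pair(cfg)
        imp = truth.loc[truth["class_a"] == "imprinted_gene"]
        assert imp["gene_id"].str.startswith("IMP_").all()
        # gene-wide monoallelic with one shared direction per gene
        per_gene = imp.groupby("gene_id")["p_ref_a"].nunique()
        assert (per_gene == 1).all()
        assert imp["p_ref_a"].isin([0.0, 1.0]).all()
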