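import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import chromaging as cg
from chromaging import io as cio


class TestSimulateGenome:
    def test_zero_coverage_gives_empty_domains(self):
        cfg = cg.SimConfig(seed=1, domain_coverage_fraction=0.0)
        _, domains, _, _ = cg.simulate_genome(cfg)
        assert len(domains) == 0

    def test_domain_coverage_near_target(self):
        cfg = cg.SimConfig(seed=2)  # 5 x 20 Mb genome, 3% target
        layout, domains, _, _ = cg.simulate_genome(cfg)
        assert 2_700_000 <= domains.total_bp <= 3_300_000

    def test_coverage_of_one_rejected(self):
        with pytest.raises(cg.ConfigError):
            cg.SimConfig(domain_coverage_fraction=1.0).validate()

    def test_same_seed_is_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            cfg = cg.SimConfig(seed=42)
            _, domains, tes, _ = cg.simulate_genome(cfg)
            p = tmp_path / f"domains_{run}.bed"
            domains.to_bed(p)
            tes.to_bed(p.with_suffix(".te.bed"), extra_cols=["subfamily"])
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert paths[0].with_suffix(".te.bed").read_bytes() == \
            paths[1].with_suffix(".te.bed").read_bytes()

    def test_annotation_carries_required_labels(self):
        cfg = cg.SimConfig(seed=3)
        _, _, tes, genes = cg.simulate_genome(cfg)
        assert "subfamily" in tes.df.columns
        assert {"lncRNA", "pseudogene"} <= set(genes["biotype"])


class TestSimulateDars:
    def test_neutral_enrichment_matches_coverage(self):
        """enrichment=1: domain fraction of background DARs ~ Binomial(n, coverage)."""
        cfg = cg.SimConfig(seed=5, n_background_dars=10_000, domain_dar_enrichment=1.0)
        layout, domains, _, _ = cg.simulate_genome(cfg)
        dars = cg.simulate_dars(layout, domains, cfg)
        cov = domains.total_bp / layout.total_bp
        k = int(dars["in_domain"].sum())
        lo, hi = binom.ppf([0.025, 0.975], 10_000, cov)
        assert lo <= k <= hi

    def test_planted_counts_exact(self):
        spans = [(f"chr{i+1}", 5_000_000, 500_000) for i in range(5)]
        cfg = cg.SimConfig(seed=6, planted_hotspots=tuple(
            cg.HotspotSpec(c, ctr, sp, 50) for c, ctr, sp in spans))
        layout, domains, _, _ = cg.simulate_genome(cfg)
        dars = cg.simulate_dars(layout, domains, cfg)
        assert int(dars["planted"].sum()) == 250
        for c, ctr, sp in spans:
            sub = dars[dars["planted"] & (dars["chrom"] == c)]
            mid = (sub["start"] + sub["end"]) // 2
            assert len(sub) == 50
            assert mid.between(ctr - sp // 2, ctr + sp // 2).all()

    def test_zero_enrichment_excludes_domains(self):
        cfg = cg.SimConfig(seed=7, n_background_dars=5_000, domain_dar_enrichment=0.0)
        layout, domains, _, _ = cg.simulate_genome(cfg)
        dars = cg.simulate_dars(layout, domains, cfg)
        assert int(dars["in_domain"].sum()) == 0

    def test_span_capacity_checked(self):
        cfg = cg.SimConfig(seed=8, planted_hotspots=(
            cg.HotspotSpec("chr1", 5_000_000, 10_000, 50),))  # 50*500 > 10k
        layout, domains, _, _ = cg.simulate_genome(cg.SimConfig(seed=8))
        with pytest.raises(cg.ConfigError):
            cg.simulate_dars(layout, domains, cfg)

    def test_domain_direction_forcing(self):
        cfg = cg.SimConfig(seed=9, n_background_dars=20_000,
                           domain_dar_enrichment=15.0, domain_dars_up_fraction=0.85)
        layout, domains, _, _ = cg.simulate_genome(cfg)
        dars = cg.simulate_dars(layout, domains, cfg)
        inside = dars[dars["in_domain"]]
        assert abs((inside["direction"] == "up").mean() - 0.85) < 0.03
        assert abs((dars.loc[~dars["in_domain"], "direction"] == "up").mean() - 0.5) < 0.03


class TestSimulateCells:
    def test_zero_probability_peak_is_empty_column(self, small_layout):
        peaks = cg.RegionSet(pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 1000, 2000], "end": [500, 1500, 2500],
             "name": ["p0", "p1", "p2"]}), small_layout)
        probs = {a: [0.0, 0.5, 1.0] for a in (2, 9, 18)}
        cfg = cg.SimConfig(seed=10, n_peaks=3,
                           accessibility=cg.AccessibilitySpec(probs=probs))
        cells, X = cg.simulate_cells(small_layout, peaks, cfg)
        dense = np.asarray(X.todense())
        assert dense[:, 0].sum() == 0
        assert dense[:, 2].sum() == len(cells)

    def test_composition_counts_within_binomial_interval(self):
        """~3% cell type with 10,000 cells/age lands in the 99% binomial interval."""
        comp = cg.CompositionSpec(cells_per_sample=1250)  # 8 samples x 1250 = 10k/age
        cfg = cg.SimConfig(seed=11, n_peaks=5, composition=comp)
        layout = cfg.layout()
        peaks = cg.simulate_peaks(layout, cfg)
        cells, _ = cg.simulate_cells(layout, peaks, cfg)
        young = cells[cells["age"] == 2]
        n_prog = (young["cell_type"] == "DG progenitor").sum()
        lo, hi = binom.ppf([0.005, 0.995], len(young), 0.03)
        assert lo <= n_prog <= hi

    def test_progenitor_decline_is_monotone(self, study_config):
        layout = study_config.layout()
        peaks = cg.simulate_peaks(layout, study_config)
        cells, _ = cg.simulate_cells(layout, peaks, study_config)
        props = [
            (cells.loc[cells["age"] == a, "cell_type"] == "DG progenitor").mean()
            for a in (2, 9, 18)
        ]
        assert props[0] > props[1] > props[2]

    def test_determinism_of_cells_and_matrix(self, study_config):
        layout = study_config.layout()
        peaks = cg.simulate_peaks(layout, study_config)
        c1, X1 = cg.simulate_cells(layout, peaks, study_config)
        c2, X2 = cg.simulate_cells(layout, peaks, study_config)
        pd.testing.assert_frame_equal(c1, c2)
        assert (X1 != X2).nnz == 0

    def test_proportions_converge_at_large_n(self):
        """Per-age composition converges to config within 3 binomial SDs at n = 1e5."""
        comp = cg.CompositionSpec(cells_per_sample=12_500, ages=(2,),
                                  proportions={"A": (0.03,), "B": (0.97,)})
        cfg = cg.SimConfig(seed=12, n_peaks=1, composition=comp)
        layout = cfg.layout()
        peaks = cg.simulate_peaks(layout, cfg)
        cells, _ = cg.simulate_cells(layout, peaks, cfg)
        n = len(cells)
        assert n == 100_000
        obs = (cells["cell_type"] == "A").mean()
        sd = np.sqrt(0.03 * 0.97 / n)
        assert abs(obs - 0.03) < 3 * sd


class TestSimulateTECounts:
    def test_planted_subfamilies_scaled_in_old_cells(self, study_config):
        layout = study_config.layout()
        peaks = cg.simulate_peaks(layout, study_config)
        cells, _ = cg.simulate_cells(layout, peaks, study_config)
        info, counts, names = cg.simulate_te_counts(cells, study_config)
        assert counts.shape == (len(cells), 500)
        diff = info.loc[info["age_differential"], "subfamily"].index.to_numpy()
        old = cells["age"].to_numpy() == 18
        young = cells["age"].to_numpy() == 2
        ratio = counts[old][:, diff].mean() / counts[young][:, diff].mean()
        assert 3.0 < ratio < 5.0


class TestSimulateLabelProfiles:
    def test_noiseless_query_equals_reference(self):
        cfg = cg.SimConfig(seed=13, labels=cg.LabelSpec(noise_sd=0.0, confusion_rate=0.0))
        ref, query, true_map = cg.simulate_label_profiles(cfg)
        for q, r in true_map.items():
            np.testing.assert_array_equal(query.loc[q].to_numpy(), ref.loc[r].to_numpy())
        assert all(q.split("_")[1] == r.split("_")[1] for q, r in true_map.items())

    def test_full_confusion_two_clusters_is_swap(self):
        cfg = cg.SimConfig(seed=14, labels=cg.LabelSpec(
            n_clusters=2, n_genes=10, confusion_rate=1.0))
        _, _, true_map = cg.simulate_label_profiles(cfg)
        assert true_map == {"query_00": "ref_01", "query_01": "ref_00"}

    def test_degenerate_configs_rejected(self):
        with pytest.raises(cg.ConfigError):
            cg.SimConfig(labels=cg.LabelSpec(n_clusters=1)).validate()
        with pytest.raises(cg.ConfigError):
            cg.SimConfig(labels=cg.LabelSpec(n_genes=1)).validate()


def test_matrix_io_roundtrip(tmp_path, study_config):
    layout = study_config.layout()
    peaks = cg.simulate_peaks(layout, study_config)
    cells, X = cg.simulate_cells(layout, peaks, study_config)
    prefix = tmp_path / "acc"
    cio.write_matrix(prefix, X, cells["cell_id"], peaks.df["name"])
    cio.write_cells(tmp_path / "cells.tsv", cells)
    X2, rows, cols = cio.read_matrix(prefix)
    assert (X != X2).nnz == 0
    assert rows == cells["cell_id"].tolist()
    back = cio.read_cells(tmp_path / "cells.tsv")
    assert len(back) == len(cells)
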