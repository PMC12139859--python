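import numpy as np
import pandas as pd
import pytest
import scipy.stats

import chromaging as cg


def _regions(rows, layout=None):
    return cg.RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), layout)


class TestOverlapFlags:
    def test_half_open_boundary_does_not_overlap(self):
        r = _regions([("chr1", 100, 200)])
        d = _regions([("chr1", 200, 300)])
        out = cg.overlap_flags(r, d)
        assert not out["overlaps"].iloc[0]

    def test_partial_overlap_bp(self):
        out = cg.overlap_flags(_regions([("chr1", 100, 200)]),
                               _regions([("chr1", 150, 300)]))
        assert out["overlaps"].iloc[0]
        assert out["overlap_bp"].iloc[0] == 50

    def test_disjoint_namespaces_rejected(self):
        with pytest.raises(cg.ConfigError):
            cg.overlap_flags(_regions([("chr1", 0, 10)]), _regions([("chrX", 0, 10)]))

    def test_matches_quadratic_scan(self, rng):
        """10,000 random regions vs an all-pairs overlap scan."""
        n = 10_000
        chroms = rng.choice(["chr1", "chr2", "chr3"], n)
        starts = rng.integers(0, 999_000, n)
        regions = _regions(list(zip(chroms, starts, starts + rng.integers(1, 1000, n))))
        ds = rng.integers(0, 990_000, 60)
        domains = _regions(list(zip(rng.choice(["chr1", "chr2", "chr3"], 60),
                                    ds, ds + rng.integers(100, 10_000, 60))))
        got = cg.overlap_flags(regions, domains)
        ddf = domains.df
        for i in rng.choice(n, 300, replace=False):  # spot-check a sample of rows
            r = regions.df.iloc[i]
            expect = any(
                (d["chrom"] == r["chrom"]) and (d["start"] < r["end"]) and (d["end"] > r["start"])
                for _, d in ddf.iterrows())
            assert bool(got["overlaps"].iloc[i]) == expect
        # totals must agree with the full quadratic count
        full = sum(
            any((d["chrom"] == r["chrom"]) and (d["start"] < r["end"]) and (d["end"] > r["start"])
                for _, d in ddf.iterrows())
            for _, r in regions.df.iterrows())
        assert int(got["overlaps"].sum()) == full


class TestFisherExact:
    @pytest.mark.parametrize("table", [
        (5, 3, 2, 8), (0, 10, 10, 0), (1, 1, 1, 1), (12, 0, 3, 9), (0, 0, 5, 5),
    ])
    def test_matches_scipy_reference(self, table):
        a, b, c, d = table
        ours = cg.fisher_exact_2x2(a, b, c, d)
        ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_random_tables_match_scipy(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, 4)
            ours = cg.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-8)


class TestDomainEnrichment:
    def test_half_genome_null(self, rng):
        layout = cg.GenomeLayout(("chr1",), (1_000_000,))
        domains = _regions([("chr1", 0, 500_000)], layout)
        starts = rng.integers(0, 999_000, 2000)
        regions = _regions(list(zip(["chr1"] * 2000, starts, starts + 100)), layout)
        res = cg.domain_enrichment(regions, domains, layout, n_permutations=0)
        assert res.enrichment_ratio == pytest.approx(1.0, abs=0.1)
        assert 0.05 < res.binomial_p

    def test_total_containment_closed_form(self):
        layout = cg.GenomeLayout(("chr1",), (1_000_000,))
        domains = _regions([("chr1", 0, 100_000)], layout)
        starts = np.arange(100) * 500
        regions = _regions(list(zip(["chr1"] * 100, starts, starts + 100)), layout)
        res = cg.domain_enrichment(regions, domains, layout, n_permutations=0)
        assert res.enrichment_ratio == pytest.approx(10.0)
        assert np.log10(res.binomial_p) == pytest.approx(-100, abs=1e-6)

    def test_empty_domains_flagged(self):
        layout = cg.GenomeLayout(("chr1",), (1_000_000,))
        regions = _regions([("chr1", 0, 100)], layout)
        empty = cg.RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]), layout)
        res = cg.domain_enrichment(regions, empty, layout)
        assert not res.defined

    def test_ratio_invariant_to_domain_splitting(self, rng):
        layout = cg.GenomeLayout(("chr1",), (1_000_000,))
        whole = _regions([("chr1", 100_000, 300_000)], layout)
        split = _regions([("chr1", 100_000, 200_000), ("chr1", 200_000, 300_000)], layout)
        starts = rng.integers(0, 999_000, 500)
        regions = _regions(list(zip(["chr1"] * 500, starts, starts + 200)), layout)
        r1 = cg.domain_enrichment(regions, whole, layout, n_permutations=0)
        r2 = cg.domain_enrichment(regions, split, layout, n_permutations=0)
        assert r1.enrichment_ratio == r2.enrichment_ratio
        assert r1.n_overlapping == r2.n_overlapping


class TestDirectionSplit:
    def test_all_outside(self):
        dars = pd.DataFrame({
            "chrom": ["chr1"] * 4, "start": [0, 10, 20, 30], "end": [5, 15, 25, 35],
            "direction": ["up", "up", "down", "down"],
        })
        domains = _regions([("chr1", 1000, 2000)])
        out = cg.direction_split(dars, domains, by=None)
        assert out.loc[0, ["up_in", "down_in"]].tolist() == [0, 0]
        assert out.loc[0, ["up_out", "down_out"]].tolist() == [2, 2]

    def test_fraction_arithmetic(self):
        split = cg.fisher_exact_2x2(90, 10, 50, 50)  # just exercises the table
        rows = []
        rows += [("chr1", i * 10, i * 10 + 5, "up") for i in range(90)]
        rows += [("chr1", 900 + i * 10, 905 + i * 10, "down") for i in range(10)]
        rows += [("chr2", i * 10, i * 10 + 5, "up") for i in range(50)]
        rows += [("chr2", 500 + i * 10, 505 + i * 10, "down") for i in range(50)]
        dars = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
        domains = _regions([("chr1", 0, 10_000)])  # chr1 rows inside, chr2 outside
        out = cg.direction_split(dars, domains, by=None)
        assert out.loc[0, "up_fraction_in"] == pytest.approx(0.9)
        assert out.loc[0, "up_fraction_out"] == pytest.approx(0.5)
        assert out.loc[0, "fisher_p"] == pytest.approx(split)
        total = out.loc[0, ["up_in", "down_in", "up_out", "down_out"]].sum()
        assert total == len(dars)

    def test_counts_invariant_to_input_order(self, rng):
        n = 500
        starts = rng.integers(0, 99_000, n)
        dars = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n), "start": starts, "end": starts + 100,
            "direction": rng.choice(["up", "down"], n),
        })
        domains = _regions([("chr1", 0, 50_000), ("chr2", 20_000, 70_000)])
        a = cg.direction_split(dars, domains, by=None)
        b = cg.direction_split(dars.sample(frac=1, random_state=1), domains, by=None)
        pd.testing.assert_frame_equal(a, b)

    def test_forced_up_fraction_recovered(self):
        """Domain-interior DARs planted 85% up are recovered within +-0.05."""
        cfg = cg.SimConfig(seed=21, n_background_dars=2000,
                           domain_dar_enrichment=15.0, domain_dars_up_fraction=0.85)
        layout, domains, _, _ = cg.simulate_genome(cfg)
        dars = cg.simulate_dars(layout, domains, cfg)
        out = cg.direction_split(dars, domains, by=None)
        assert out.loc[0, "up_fraction_in"] == pytest.approx(0.85, abs=0.05)
        assert out.loc[0, "up_fraction_out"] == pytest.approx(0.5, abs=0.05)


class TestBiotypeTopComposition:
    def _ranked(self, biotype_list, direction="up"):
        n = len(biotype_list)
        sign = 1 if direction == "up" else -1
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(2 * n)],
            "log2_fold_change": [sign * 2.0] * n + [-sign * 2.0] * n,
            "adjusted_p": np.linspace(1e-10, 1e-2, 2 * n),
        })
        biotypes = {f"g{i}": bt for i, bt in enumerate(biotype_list)}
        return genes, biotypes

    def test_known_mixture_fraction(self):
        bts = ["lncRNA"] * 30 + ["pseudogene"] * 25 + ["protein_coding"] * 45
        genes, biotypes = self._ranked(bts)
        comp = cg.biotype_top_composition(genes, biotypes, top_n=100)
        assert cg.target_fraction(comp, "up") == pytest.approx(0.55)

    def test_all_protein_coding_zero(self):
        genes, biotypes = self._ranked(["protein_coding"] * 100)
        comp = cg.biotype_top_composition(genes, biotypes, top_n=100)
        assert cg.target_fraction(comp, "up") == 0.0

    def test_planted_decile_fraction_exact(self):
        """40% lncRNA planted in the top decile is recovered exactly."""
        n = 1000
        bts = (["lncRNA"] * 40 + ["protein_coding"] * 60) + ["protein_coding"] * (n - 100)
        genes, biotypes = self._ranked(bts)
        comp = cg.biotype_top_composition(genes, biotypes, top_n=100)
        assert cg.target_fraction(comp, "up") == pytest.approx(0.40)

    def test_top_n_too_large_rejected(self):
        genes, biotypes = self._ranked(["lncRNA"] * 10)
        with pytest.raises(cg.ConfigError):
            cg.biotype_top_composition(genes, biotypes, top_n=50)

    def test_unmapped_genes_counted_unknown(self):
        genes, _ = self._ranked(["lncRNA"] * 10)
        comp = cg.biotype_top_composition(genes, {}, top_n=10)
        up = comp[comp["direction"] == "up"]
        assert up["biotype"].tolist() == ["unknown"]
        assert up["fraction"].iloc[0] == 1.0
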