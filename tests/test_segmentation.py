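import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methcompare import segmentation as seg

from _oracles import brute_umrs


def table(pos, pct, chrom="c"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "n_meth": 0,
            "n_total": 10,
            "percent": pct,
        }
    )


class TestUMRs:
    def test_low_run_flanked_by_high(self):
        pos = np.arange(20) * 50
        pct = np.array([90.0] * 5 + [0.0] * 10 + [90.0] * 5)
        umrs = seg.detect_umrs(table(pos, pct))
        assert len(umrs) == 1
        u = umrs.iloc[0]
        # smoothing keeps the 10 zero CpGs below 0.5 and their neighbours above
        assert (u["start"], u["end"], u["n_cpg"]) == (250, 701, 10)

    def test_short_run_below_cutoff_rejected(self):
        pct = np.array([90.0] * 5 + [0.0] * 4 + [90.0] * 5)
        umrs = seg.detect_umrs(table(np.arange(14) * 50, pct))
        assert len(umrs) == 0

    def test_fully_methylated_chromosome_has_no_umr(self):
        umrs = seg.detect_umrs(table(np.arange(50) * 10, np.full(50, 80.0)))
        assert len(umrs) == 0

    def test_matches_run_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            pos = np.sort(rng.choice(np.arange(5000), size=n, replace=False))
            pct = rng.choice([0.0, 20.0, 45.0, 60.0, 90.0], size=n)
            got = seg.detect_umrs(table(pos, pct))
            want = brute_umrs(pos, pct / 100.0)
            assert len(got) == len(want)
            for row, (s, e, k, m) in zip(got.itertuples(index=False), want):
                assert (row.start, row.end, row.n_cpg) == (s, e, k)
                assert row.mean_meth == pytest.approx(m)

    def test_umrs_disjoint_and_below_cutoff(self, result_small):
        umrs = result_small.umrs.sort_values(["chrom", "start"])
        assert (umrs["mean_meth"] < 0.5).all()
        assert (umrs["n_cpg"] >= 5).all()
        for _, sub in umrs.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_pmd_mask_breaks_runs(self):
        pos = np.arange(20) * 50
        pct = np.zeros(20)
        pmds = pd.DataFrame({"chrom": ["c"], "start": [475], "end": [525]})  # masks CpG 10
        umrs = seg.detect_umrs(table(pos, pct), pmds)
        assert len(umrs) == 2
        assert (umrs["end"] <= 501).any() and (umrs["start"] >= 550).any()


class TestDMVs:
    def test_size_threshold_inclusive(self):
        umrs = pd.DataFrame(
            {
                "chrom": "c",
                "start": [0, 10_000, 30_000],
                "end": [6_000, 14_999, 35_000],
                "n_cpg": [50, 50, 50],
                "mean_meth": [0.01, 0.01, 0.01],
            }
        )
        dmvs = seg.call_dmvs(umrs, min_size_bp=5000)
        assert list(dmvs["end"] - dmvs["start"]) == [6000, 5000]

    def test_empty_umrs_give_empty_dmvs(self):
        assert len(seg.call_dmvs(pd.DataFrame(columns=["chrom", "start", "end"]))) == 0

    def test_count_monotone_in_threshold(self, result_small):
        counts = [len(seg.call_dmvs(result_small.umrs, t)) for t in (1000, 3000, 5000, 8000)]
        assert counts == sorted(counts, reverse=True)

    def test_implanted_valleys_recovered(self, result_small):
        truth = result_small.data.truth.valleys
        dmvs = result_small.dmvs
        for _, v in truth.iterrows():
            hit = dmvs[(dmvs["chrom"] == v["chrom"]) & (dmvs["start"] < v["end"])
                       & (dmvs["end"] > v["start"])]
            assert len(hit) == 1
            h = hit.iloc[0]
            inter = min(h["end"], v["end"]) - max(h["start"], v["start"])
            assert inter / (v["end"] - v["start"]) >= 0.9
            assert inter / (h["end"] - h["start"]) >= 0.9


class TestGeneOverlapAndConservation:
    def test_overlap_rules(self, result_small):
        from methcompare.io import GeneModel

        dmvs = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [2000]})
        inside = GeneModel("gi", "gi", "c", "+", 1200, body=(1200, 1400))
        edge = GeneModel("ge", "ge", "c", "+", 1999, body=(1999, 3000))
        outside = GeneModel("go", "go", "c", "+", 2000, body=(2000, 3000))
        assert seg.dmv_gene_overlap(dmvs, [inside, edge, outside]) == {"gi", "ge"}
        assert seg.dmv_gene_overlap(dmvs.iloc[0:0], [inside]) == set()

    def test_conservation_formula(self):
        omap = {f"g{i}": f"OG{i}" for i in range(10)}
        a = {"g1", "g2", "g3", "g4"}
        b = {"g1", "g2", "g9"}
        assert seg.conservation_percent(a, b, omap) == pytest.approx(100 * 2 / 3)
        assert seg.conservation_percent(a, a, omap) == 100.0
        assert seg.conservation_percent(a, {"g5"}, omap) == 0.0
        assert seg.conservation_percent(a, b, omap) == seg.conservation_percent(b, a, omap)
        assert seg.conservation_percent(a, {"g1", "g2"}, omap) == 100.0  # subset
        assert np.isnan(seg.conservation_percent(a, {"unmapped"}, omap))

    @given(
        a=st.sets(st.integers(0, 20), min_size=1),
        b=st.sets(st.integers(0, 20), min_size=1),
    )
    def test_conservation_bounds(self, a, b):
        omap = {i: f"OG{i}" for i in range(21)}
        v = seg.conservation_percent(a, b, omap)
        assert 0.0 <= v <= 100.0


class TestPMDs:
    def test_bimodal_methylome_has_no_pmds(self, rng):
        pct = rng.choice([2.0, 95.0], size=500)
        pmds = seg.detect_pmds(table(np.arange(500) * 20, pct))
        assert len(pmds) == 0

    def test_unreachable_cutoff_gives_none(self, result_small):
        pmds = seg.detect_pmds(result_small.cpg_table, frac_cutoff=1.01)
        assert len(pmds) == 0

    def test_few_cpgs_warns_no_call(self):
        with pytest.warns(UserWarning, match="fewer than"):
            pmds = seg.detect_pmds(table(np.arange(10) * 50, np.full(10, 50.0)))
        assert len(pmds) == 0

    def test_implanted_pmd_recovered_at_20x(self):
        from methcompare.simulate import SimConfig, simulate_species

        cfg = SimConfig(
            species="P",
            seed=21,
            depth=20.0,
            autosome_len=500_000,
            x_len=150_000,
            n_imprinted=2,
            n_valleys=1,
            pmd_len=80_000,
            n_germline_genes=2,
            n_methylated_cgi_genes=2,
            n_ordinary_genes=6,
            n_lcp_genes=2,
            n_extra_cgis=2,
            n_te=10,
            n_x_subject=4,
            n_x_escapee=2,
        )
        data = simulate_species(cfg)
        from methcompare.io import depth_filter

        cpg = depth_filter(data.cov, 5)
        pmds = seg.detect_pmds(cpg[cpg["chrom"] == "chr1"])
        t = data.truth.pmds.iloc[0]
        best = 0.0
        for _, p in pmds.iterrows():
            inter = max(0, min(p["end"], t["end"]) - max(p["start"], t["start"]))
            union = max(p["end"], t["end"]) - min(p["start"], t["start"])
            best = max(best, inter / union)
        assert best > 0.8

    def test_genome_fraction(self):
        iv = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 50], "end": [100, 150]})
        assert seg.genome_fraction(iv, {"c": 300}) == pytest.approx(0.5)
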