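import numpy as np
import pandas as pd
import pytest

from methcompare import allelic
from methcompare.io import ReadCallSet, build_read_call_set

from _oracles import brute_window_gates


def make_calls(reads):
    """reads: list of (read_id, [(pos, meth), ...]) on chromosome c."""
    rows = [
        (rid, "c", pos, int(meth)) for rid, calls in reads for pos, meth in calls
    ]
    return build_read_call_set(
        pd.DataFrame(rows, columns=["read", "chrom", "pos", "meth"]), min_cpgs=3
    )


def cpg_table_from(rcs: ReadCallSet):
    from methcompare.simulate import aggregate_calls

    return aggregate_calls(rcs.calls)


class TestWindowScan:
    def test_symmetric_mixture(self):
        positions = [10, 20, 30]
        reads = [(f"m{i}", [(p, 1) for p in positions]) for i in range(6)]
        reads += [(f"u{i}", [(p, 0) for p in positions]) for i in range(6)]
        rcs = make_calls(reads)
        stats = allelic.window_scan(rcs, cpg_table_from(rcs))
        w = stats[stats["start"] == 0].iloc[0]
        assert w["n_reads"] == 12
        assert w["mean_meth"] == pytest.approx(50.0)
        assert w["pct_full"] == pytest.approx(100.0)
        assert w["delta"] == pytest.approx(0.0)

    def test_mosaic_reads_have_no_full(self):
        reads = [(f"r{i}", [(10, 1), (20, 0), (30, 1)]) for i in range(10)]
        rcs = make_calls(reads)
        stats = allelic.window_scan(rcs, cpg_table_from(rcs))
        assert (stats["pct_full"] == 0.0).all()

    def test_nine_to_one_composition(self):
        positions = [10, 20, 30]
        reads = [(f"m{i}", [(p, 1) for p in positions]) for i in range(9)]
        reads += [("u0", [(p, 0) for p in positions])]
        rcs = make_calls(reads)
        stats = allelic.window_scan(rcs, cpg_table_from(rcs))
        w = stats[stats["start"] == 0].iloc[0]
        assert w["pct_fully_m"] == pytest.approx(90.0)
        assert w["pct_fully_u"] == pytest.approx(10.0)
        assert w["delta"] == pytest.approx(80.0)
        assert w["mean_meth"] == pytest.approx(90.0)

    def test_full_status_judged_over_all_calls(self):
        # read has an unmethylated call outside the window; it still counts
        # as overlapping but not fully methylated
        reads = [("r0", [(10, 1), (20, 1), (200, 0)])] + [
            (f"m{i}", [(10, 1), (20, 1), (30, 1)]) for i in range(4)
        ]
        rcs = make_calls(reads)
        stats = allelic.window_scan(rcs, cpg_table_from(rcs))
        w = stats[stats["start"] == 0].iloc[0]
        assert w["n_reads"] == 5
        assert w["pct_fully_m"] == pytest.approx(80.0)

    def test_window_step_alignment(self):
        reads = [(f"r{i}", [(55, 1), (60, 1), (65, 1)]) for i in range(5)]
        rcs = make_calls(reads)
        stats = allelic.window_scan(rcs, cpg_table_from(rcs))
        assert stats["start"].min() == 10  # earliest window [10,60) contains pos 55
        assert stats["start"].max() == 60  # latest window [60,110) contains pos 65
        assert (stats["start"] % 10 == 0).all()


class TestFilterWindows:
    @pytest.mark.parametrize(
        "mean,full,delta,expected",
        [
            (50.0, 100.0, 0.0, True),
            (90.0, 100.0, 80.0, False),
            (45.0, 85.0, 10.0, False),
            (30.0, 95.0, 39.9, True),  # boundaries: mean inclusive, delta strict
            (60.0, 90.0, 10.0, False),  # pct_full strictly > 90
        ],
    )
    def test_gate_examples(self, mean, full, delta, expected):
        stats = pd.DataFrame(
            {
                "chrom": ["c"],
                "start": [0],
                "end": [50],
                "n_reads": [10],
                "pct_full": [full],
                "delta": [delta],
                "mean_meth": [mean],
            }
        )
        assert (len(allelic.filter_windows(stats)) == 1) is expected

    def test_matches_bruteforce_oracle_on_random_windows(self, rng):
        n = 10_000
        stats = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 10,
                "end": np.arange(n) * 10 + 50,
                "n_reads": rng.integers(0, 30, n),
                "pct_fully_m": rng.uniform(0, 100, n),
            }
        )
        stats["pct_fully_u"] = np.minimum(100 - stats["pct_fully_m"], rng.uniform(0, 100, n))
        stats["pct_full"] = stats["pct_fully_m"] + stats["pct_fully_u"]
        stats["delta"] = (stats["pct_fully_m"] - stats["pct_fully_u"]).abs()
        stats["mean_meth"] = rng.uniform(0, 100, n)
        stats.loc[rng.choice(n, 100, replace=False), "mean_meth"] = np.nan
        got = set(allelic.filter_windows(stats)["start"])
        want = {row["start"] for _, row in stats.iterrows() if brute_window_gates(row)}
        assert got == want


class TestMergeAndModes:
    def _cpgs(self, positions):
        return pd.DataFrame(
            {
                "chrom": "c",
                "pos": positions,
                "n_meth": 5,
                "n_total": 10,
                "percent": 50.0,
            }
        )

    def _windows(self, starts):
        return pd.DataFrame({"chrom": "c", "start": starts, "end": np.asarray(starts) + 50})

    def test_consecutive_windows_union(self):
        merged = allelic.merge_windows(self._windows([100, 110, 120]), self._cpgs([105, 125, 160]))
        assert len(merged) == 1
        assert (merged.loc[0, "start"], merged.loc[0, "end"]) == (100, 170)
        assert merged.loc[0, "n_cpg"] == 3

    def test_gap_breaks_merge(self):
        merged = allelic.merge_windows(self._windows([100, 200]), self._cpgs([110]))
        assert len(merged) == 2

    def test_single_window_passthrough(self):
        merged = allelic.merge_windows(self._windows([100]), self._cpgs([110]))
        assert (merged.loc[0, "start"], merged.loc[0, "end"]) == (100, 150)

    def test_merge_idempotent_and_order_independent(self, rng):
        starts = sorted(set(rng.integers(0, 2000, 60) * 10))
        win = self._windows(starts)
        shuffled = win.sample(frac=1.0, random_state=3)
        cpgs = self._cpgs(list(range(0, 25000, 100)))
        a = allelic.merge_windows(win, cpgs)
        b = allelic.merge_windows(shuffled, cpgs)
        pd.testing.assert_frame_equal(a, b)
        again = allelic.merge_windows(
            a.rename(columns={})[["chrom", "start", "end"]], cpgs
        )
        pd.testing.assert_frame_equal(a[["chrom", "start", "end"]], again[["chrom", "start", "end"]])

    def _candidates(self):
        return pd.DataFrame(
            {
                "chrom": ["c", "c", "chrX", "c"],
                "start": [0, 1000, 2000, 3000],
                "end": [400, 1360, 2500, 3500],
                "n_cpg": [19, 22, 30, 25],
                "size_bp": [400, 360, 500, 500],
                "mean_meth": [50.0] * 4,
            }
        )

    def test_mode_thresholds(self):
        lenient = allelic.apply_mode_filters(self._candidates(), "lenient")
        stringent = allelic.apply_mode_filters(self._candidates(), "stringent")
        assert set(lenient["start"]) == {0, 1000, 3000}  # X removed
        assert set(stringent["start"]) == {1000, 3000}  # 19 CpGs fails stringent
        assert set(stringent["start"]) <= set(lenient["start"])

    def test_size_gate_strict(self):
        cand = self._candidates()
        cand.loc[1, "size_bp"] = 350
        stringent = allelic.apply_mode_filters(cand, "stringent")
        assert 1000 not in set(stringent["start"])

    def test_exclusion_overlap_removed(self):
        excl = pd.DataFrame({"chrom": ["c"], "start": [3400], "end": [3600]})
        lenient = allelic.apply_mode_filters(self._candidates(), "lenient", exclusions=excl)
        assert 3000 not in set(lenient["start"])

    def test_unknown_chrx_name_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            allelic.apply_mode_filters(
                self._candidates(), "lenient", chrx_name="chrZ", chrom_names={"c", "chrX"}
            )


class TestGeneAssociation:
    def _genes(self):
        from methcompare.io import GeneModel

        return [
            GeneModel("near", "near", "c", "+", 10_000, body=(10_000, 14_000)),
            GeneModel("far", "far", "c", "+", 200_000, body=(200_000, 204_000)),
        ]

    def test_overlap_distance_zero(self):
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [11_000], "end": [11_500]})
        out = allelic.associate_genes(dmrs, self._genes())
        assert out.loc[0, "nearest_gene"] == "near"
        assert out.loc[0, "distance_bp"] == 0

    def test_within_max_distance_assigned(self):
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [24_000], "end": [24_500]})
        out = allelic.associate_genes(dmrs, self._genes(), max_distance_bp=50_000)
        assert out.loc[0, "nearest_gene"] == "near"
        assert out.loc[0, "distance_bp"] == 10_000

    def test_beyond_max_distance_unassigned(self):
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [100_000], "end": [100_500]})
        out = allelic.associate_genes(dmrs, self._genes(), max_distance_bp=50_000)
        assert out.loc[0, "nearest_gene"] == ""


class TestCrossSpecies:
    def _calls(self, genes, stringent):
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": range(len(genes)),
                "end": range(1, len(genes) + 1),
                "nearest_gene": genes,
                "stringent": stringent,
            }
        )

    def test_species_counting_and_ranking(self):
        omap = pd.DataFrame(
            {
                "gene_id": ["A_g1", "B_g1", "C_g1", "A_g2", "B_g2"],
                "ortholog": ["OG1", "OG1", "OG1", "OG2", "OG2"],
            }
        )
        per_species = {
            "A": self._calls(["A_g1", "A_g2"], [True, False]),
            "B": self._calls(["B_g1", "B_g2"], [True, True]),
            "C": self._calls(["C_g1"], [False]),
        }
        out = allelic.cross_species_dmr_genes(per_species, omap, min_species=2)
        assert list(out["ortholog"]) == ["OG1", "OG2"]
        assert list(out["n_species"]) == [3, 2]
        assert list(out["n_stringent"]) == [2, 1]

    def test_single_species_gene_excluded(self):
        omap = pd.DataFrame({"gene_id": ["A_g1"], "ortholog": ["OG1"]})
        out = allelic.cross_species_dmr_genes(
            {"A": self._calls(["A_g1"], [True])}, omap, min_species=2
        )
        assert len(out) == 0

    def test_empty_ortholog_map_warns(self):
        with pytest.warns(UserWarning, match="empty ortholog map"):
            out = allelic.cross_species_dmr_genes(
                {"A": self._calls(["A_g1"], [True])}, pd.DataFrame(columns=["gene_id", "ortholog"])
            )
        assert len(out) == 0


class TestEndToEnd:
    def test_stringent_subset_of_lenient_and_no_x(self, result_small):
        calls = result_small.dmr_calls
        assert calls["lenient"].all()
        assert (calls.loc[calls["stringent"], "n_cpg"] >= 20).all()
        assert (calls.loc[calls["stringent"], "size_bp"] > 350).all()
        assert (calls["n_cpg"] >= 10).all()
        assert (calls["chrom"] != "chrX").all()

    def test_no_calls_in_exclusions_or_pmds(self, result_small):
        calls = result_small.dmr_calls
        for frame in (result_small.data.exclusions, result_small.data.truth.pmds):
            for _, r in frame.iterrows():
                hits = calls[
                    (calls["chrom"] == r["chrom"])
                    & (calls["start"] < r["end"])
                    & (calls["end"] > r["start"])
                ]
                assert len(hits) == 0
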