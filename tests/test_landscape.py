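import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methcompare import landscape as ls
from methcompare.io import GeneModel

from _oracles import brute_cpg_ratio


def cov(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "percent"])
    df["n_meth"] = (df["percent"] / 100 * 10).round().astype(int)
    df["n_total"] = 10
    return df[["chrom", "pos", "n_meth", "n_total", "percent"]]


class TestCpGRatio:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CGCG", 2.0), ("ATATATAT", 0.0), ("CCCC", 0.0), ("CGNNCG", (2 * 4) / (2 * 2))],
    )
    def test_known_values(self, seq, expected):
        assert ls.cpg_ratio(seq) == pytest.approx(expected)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            ls.cpg_ratio("")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_matches_brute_force(self, seq):
        assert ls.cpg_ratio(seq) == pytest.approx(brute_cpg_ratio(seq))

    def test_brute_force_on_many_random_sequences(self, rng):
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGTN"), size=rng.integers(1, 60)))
            assert ls.cpg_ratio(seq) == pytest.approx(brute_cpg_ratio(seq))


class TestSlidingWindows:
    def test_uniform_sequence_ratio_near_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        win = ls.sliding_cg_ratio({"chr1": seq}, window=500)
        assert win["ratio"].mean() == pytest.approx(1.0, abs=0.05)

    def test_tiling_covers_chromosome(self):
        win = ls.sliding_cg_ratio({"c": "ACGT" * 500}, window=500, step=500)
        assert list(win["start"]) == [0, 500, 1000, 1500]
        assert (win["end"] - win["start"] == 500).all()

    def test_windows_inside_simulated_cgi_are_dense(self, species_a):
        cgi = species_a.cgis.iloc[0]
        seq = species_a.genome[cgi["chrom"]]
        win = ls.sliding_cg_ratio({"c": seq[cgi["start"] : cgi["end"]]}, window=500, step=500)
        assert (win["ratio"] > 0.6).all()

    def test_high_n_windows_dropped(self):
        seq = "N" * 400 + "ACGT" * 25  # 500 bp window is 80% N
        win = ls.sliding_cg_ratio({"c": seq}, window=500, step=500)
        assert len(win) == 0


class TestGlobalAndBinned:
    def test_global_mean_examples(self):
        assert ls.global_mean_methylation(cov([("c", 1, 0.0), ("c", 2, 100.0)])) == 50.0
        assert ls.global_mean_methylation(
            cov([("c", 1, 100.0), ("c", 2, 100.0), ("c", 3, 40.0)])
        ) == pytest.approx(80.0)

    def test_global_mean_empty_raises(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_total", "percent"])
        with pytest.raises(ValueError):
            ls.global_mean_methylation(empty)

    def test_methylation_by_cg_ratio_uniform(self):
        windows = pd.DataFrame(
            {"chrom": "c", "start": [0, 100], "end": [100, 200], "ratio": [0.2, 0.9]}
        )
        table = cov([("c", 50, 80.0), ("c", 150, 80.0)])
        med = ls.methylation_by_cg_ratio(windows, table, ratio_bins=[0, 0.5, 1.0])
        assert (med.dropna() == 80.0).all()

    def test_empty_bin_is_nan_and_single_window_is_its_mean(self):
        windows = pd.DataFrame({"chrom": "c", "start": [0], "end": [100], "ratio": [0.2]})
        table = cov([("c", 10, 30.0), ("c", 20, 50.0)])
        med = ls.methylation_by_cg_ratio(windows, table, ratio_bins=[0, 0.5, 1.0])
        assert med.iloc[0] == pytest.approx(40.0)
        assert np.isnan(med.iloc[1])


def mk_gene(gene_id, chrom, strand, tss, body, exons=None):
    return GeneModel(
        gene_id=gene_id,
        name=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        transcripts=[sorted(exons)] if exons else [[body]],
        body=body,
    )


class TestCGIFeatures:
    def test_precedence_promoter_over_cds(self):
        g = mk_gene("g1", "c", "+", 1000, (1000, 3000))
        cgis = pd.DataFrame({"chrom": ["c"], "start": [900], "end": [1200], "name": ["x"]})
        out = ls.annotate_cgi_features(cgis, [g])
        assert out.loc[0, "feature_class"] == "promoter"

    def test_intron_only_cgi(self):
        g = mk_gene("g1", "c", "+", 1000, (1000, 5000), exons=[(1000, 1500), (4000, 5000)])
        cgis = pd.DataFrame({"chrom": ["c"], "start": [2000], "end": [2500], "name": ["x"]})
        out = ls.annotate_cgi_features(cgis, [g])
        assert out.loc[0, "feature_class"] == "intron"

    def test_gene_desert_cgi_is_intergenic(self):
        g = mk_gene("g1", "c", "+", 1000, (1000, 2000))
        cgis = pd.DataFrame({"chrom": ["c"], "start": [9000], "end": [9500], "name": ["x"]})
        out = ls.annotate_cgi_features(cgis, [g])
        assert out.loc[0, "feature_class"] == "intergenic"

    def test_cds_overlap_without_tss(self):
        g = mk_gene("g1", "c", "+", 1000, (1000, 3000))
        cgis = pd.DataFrame({"chrom": ["c"], "start": [1500], "end": [1800], "name": ["x"]})
        out = ls.annotate_cgi_features(cgis, [g])
        assert out.loc[0, "feature_class"] == "CDS"


class TestCGIClasses:
    def _genome(self):
        # 10 CpGs at positions 0,2,..,18
        return {"c": "CG" * 10 + "A" * 100}

    def test_class_bounds(self):
        cgis = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [20], "name": ["x"]})
        for pct, expected in [(0.0, "unmethylated"), (9.9, "unmethylated"), (10.0, "low"),
                              (30.0, "low"), (50.0, "low"), (75.0, "high")]:
            table = cov([("c", p, pct) for p in range(0, 20, 2)])
            out = ls.classify_cgi_methylation(cgis, table, self._genome())
            assert out.loc[0, "meth_class"] == expected, pct

    def test_coverage_rule_excludes_undercovered(self):
        cgis = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [20], "name": ["x"]})
        table3 = cov([("c", p, 0.0) for p in (0, 2, 4)])  # 3 of 10 = 30% < 35%
        out = ls.classify_cgi_methylation(cgis, table3, self._genome())
        assert out.loc[0, "meth_class"] == "NA"
        table4 = cov([("c", p, 0.0) for p in (0, 2, 4, 6)])  # 40% >= 35%
        out = ls.classify_cgi_methylation(cgis, table4, self._genome())
        assert out.loc[0, "meth_class"] == "unmethylated"

    def test_cgi_without_cpgs_warns_na(self):
        cgis = pd.DataFrame({"chrom": ["c"], "start": [30], "end": [50], "name": ["x"]})
        with pytest.warns(UserWarning, match="no CpG"):
            out = ls.classify_cgi_methylation(cgis, cov([("c", 0, 0.0)]), self._genome())
        assert out.loc[0, "meth_class"] == "NA"

    def test_proportions_sum_to_100(self, result_small):
        props = ls.cgi_class_proportions(result_small.cgi_classes)
        assert props.sum() == pytest.approx(100.0, abs=1e-9)


class TestPromoters:
    def test_windows_strand_oriented(self):
        genome = {"c": "A" * 10_000}
        plus = mk_gene("gp", "c", "+", 5000, (5000, 6000))
        minus = mk_gene("gm", "c", "-", 5000, (4000, 5001))
        out = ls.define_promoters([plus, minus], genome)
        p = out.set_index("gene_id")
        assert (p.loc["gp", "start"], p.loc["gp", "end"]) == (4000, 5500)
        assert (p.loc["gm", "start"], p.loc["gm", "end"]) == (4500, 6000)

    def test_max_ratio_isoform_wins(self):
        seq = "A" * 4000 + "CG" * 750 + "A" * 4500
        g = mk_gene("g", "c", "+", 4500, (4500, 9000), exons=[(4500, 9000)])
        g.transcripts.append([(8000, 9000)])  # second isoform TSS at 8000, AT-only promoter
        out = ls.define_promoters([g], {"c": seq})
        assert out.loc[0, "tss"] == 4500
        assert out.loc[0, "cpg_ratio"] > 1.0

    def test_truncated_window_flagged(self):
        g = mk_gene("g", "c", "+", 300, (300, 1000))
        out = ls.define_promoters([g], {"c": "ACGT" * 500})
        assert bool(out.loc[0, "truncated"])

    @pytest.mark.parametrize(
        "ratio,gc,expected",
        [(0.8, 60.0, "HCP"), (0.8, 50.0, "ICP"), (0.1, 40.0, "LCP"), (0.45, 70.0, "ICP")],
    )
    def test_classification_rule(self, ratio, gc, expected):
        df = pd.DataFrame({"cpg_ratio": [ratio], "gc_percent": [gc]})
        out = ls.classify_promoters(df, lower=0.3, upper=0.6)
        assert out.loc[0, "promoter_class"] == expected

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            ls.classify_promoters(pd.DataFrame({"cpg_ratio": [], "gc_percent": []}), 0.6, 0.3)

    def test_every_promoter_gets_exactly_one_class(self, result_small):
        assert set(result_small.promoters["promoter_class"]) <= {"LCP", "ICP", "HCP"}
        assert result_small.promoters["promoter_class"].notna().all()

    def test_suggested_cutoffs_ordered(self, result_small):
        got = ls.suggest_promoter_cutoffs(result_small.promoters["cpg_ratio"])
        assert got["lower"] <= got["upper"]


class TestMetaplotAndBodies:
    def test_constant_methylome_gives_flat_profile(self):
        genes = [mk_gene("g", "c", "+", 12000, (12000, 16000))]
        table = cov([("c", p, 80.0) for p in range(0, 30000, 40)])
        meta = ls.gene_metaplot(genes, table)
        assert np.allclose(meta["profile"], 80.0)

    def test_short_gene_skipped_and_counted(self):
        genes = [mk_gene("g", "c", "+", 100, (100, 110))]
        meta = ls.gene_metaplot(genes, cov([("c", 105, 50.0)]))
        assert meta["n_skipped"] == 1

    def test_unmethylated_promoter_dips_at_tss(self, result_small):
        data = result_small.data
        meta = ls.gene_metaplot(data.genes, result_small.cpg_table, exclude_chroms={"chrX"})
        profile = meta["profile"]
        tss_region = np.nanmin(profile[8:14])
        assert tss_region < np.nanmean(profile[:5]) < 100

    def test_gene_body_region_arithmetic(self):
        g = mk_gene("g", "c", "+", 1000, (1000, 3000))
        table = cov([("c", 1200, 100.0), ("c", 2500, 50.0)])
        out = ls.gene_body_methylation([g], table)
        assert out.loc[0, "mean_meth"] == pytest.approx(50.0)  # CpG at 1200 < TSS+500

    def test_gene_body_no_cpg_is_nan(self):
        g = mk_gene("g", "c", "+", 1000, (1000, 3000))
        out = ls.gene_body_methylation([g], cov([("c", 1100, 100.0)]))
        assert np.isnan(out.loc[0, "mean_meth"])

    def test_minus_strand_mirrors_offset(self):
        g = mk_gene("g", "c", "-", 2999, (1000, 3000))
        # +500 after TSS on minus strand means region [1000, 2500)
        table = cov([("c", 2600, 100.0), ("c", 1500, 40.0)])
        out = ls.gene_body_methylation([g], table)
        assert out.loc[0, "mean_meth"] == pytest.approx(40.0)


class TestFeatureStratification:
    def test_precedence_and_te_layer(self):
        genes = [mk_gene("g", "c", "+", 1000, (1000, 5000), exons=[(1000, 2000), (4000, 5000)])]
        promoters = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1500]})
        tes = pd.DataFrame({"chrom": ["c"], "start": [2500], "end": [2700]})
        table = cov([("c", 1200, 10.0), ("c", 2600, 90.0), ("c", 8000, 70.0)])
        out = ls.feature_stratified_methylation(table, promoters, genes, tes)
        assert list(out["promoter"]) == [10.0]  # in promoter and exon -> promoter
        assert list(out["intron"]) == [90.0]
        assert list(out["TE"]) == [90.0]  # TE layer independent of intron class
        assert list(out["intergenic"]) == [70.0]

    def test_empty_te_annotation(self):
        genes = [mk_gene("g", "c", "+", 1000, (1000, 2000))]
        promoters = pd.DataFrame({"chrom": [], "start": [], "end": []})
        out = ls.feature_stratified_methylation(cov([("c", 1500, 50.0)]), promoters, genes, None)
        assert len(out["TE"]) == 0
        assert list(out["exon"]) == [50.0]
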