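import numpy as np
import pandas as pd
import pytest

from helpers_oracles import bh_adjust_oracle

from ubmzt.genome_model import GenomicInterval, PromoterRegion
from ubmzt.promoter_diff import (
    PromoterSignalMatrix,
    background_norm_factors,
    call_changes,
    derive_ub_gene_sets,
    nb_wald_test,
    promoter_counts,
    size_factors,
)
from ubmzt.synthetic_data import ReadSet, SampleInfo


def _info(sid):
    return SampleInfo(sid, "GV", "WT", "H2AK119ub1", 1)


def _readset(sid, rows):
    return ReadSet(_info(sid), pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]))


def _matrix(counts: pd.DataFrame, factors=None) -> PromoterSignalMatrix:
    return PromoterSignalMatrix(
        counts,
        {c: _info(c) for c in counts.columns},
        pd.Series(4000, index=counts.index),
        norm_factors=pd.Series(factors, index=counts.columns) if factors is not None else None,
    )


def _nb_counts(rng, mean, disp, shape):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean), size=shape)


class TestPromoterCounts:
    PROMOTERS = {
        "gA": PromoterRegion("gA", GenomicInterval("chr1", 1000, 5000)),
        "gB": PromoterRegion("gB", GenomicInterval("chr1", 9000, 13_000)),
    }

    def test_read_at_promoter_center_counted(self):
        rs = _readset("s1", [("chr1", 2975, 3025, "+")])
        m = promoter_counts([rs], self.PROMOTERS)
        assert m.counts.loc["gA", "s1"] == 1
        assert m.counts.loc["gB", "s1"] == 0

    def test_midpoint_at_promoter_end_excluded(self):
        # midpoint (4975 + 5025) // 2 = 5000 == half-open promoter end
        rs = _readset("s1", [("chr1", 4975, 5025, "+")])
        m = promoter_counts([rs], self.PROMOTERS)
        assert m.counts["s1"].sum() == 0

    def test_midpoint_at_promoter_start_included(self):
        rs = _readset("s1", [("chr1", 975, 1025, "+")])
        m = promoter_counts([rs], self.PROMOTERS)
        assert m.counts.loc["gA", "s1"] == 1

    def test_total_bounded_by_read_count(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s) + 50, "+") for s in rng.integers(0, 15_000, 500)]
        m = promoter_counts([_readset("s1", rows)], self.PROMOTERS)
        assert m.counts["s1"].sum() <= 500


class TestSizeFactors:
    def test_threefold_sample_gets_threefold_factor(self):
        counts = pd.DataFrame({"A": [10, 20, 5], "B": [30, 60, 15]}, index=list("xyz"))
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(3.0)

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"A": [10, 20], "B": [10, 20], "C": [10, 20]})
        f = size_factors(counts)
        assert f.nunique() == 1

    def test_hand_computed_two_gene_example(self):
        counts = pd.DataFrame({"A": [2, 8], "B": [4, 16]})
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [3, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            size_factors(counts)


class TestBackgroundNormFactors:
    def test_factors_proportional_to_background(self):
        counts = pd.DataFrame({"A": [5, 5], "B": [5, 5]})
        m = _matrix(counts)
        f = background_norm_factors(m, {"A": 10.0, "B": 40.0})
        assert f["B"] / f["A"] == pytest.approx(4.0)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


class TestNbWaldTest:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        block = _nb_counts(rng, 50, 0.05, (200, 3))
        counts = pd.DataFrame(
            np.hstack([block, block]), columns=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        res = nb_wald_test(_matrix(counts, 1.0), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert (res["log2_fc"] == 0).all()
        assert (res["p_value"] > 0.999).all()

    def test_label_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            _nb_counts(rng, 80, 0.05, (300, 6)),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        m = _matrix(counts, 1.0)
        fwd = nb_wald_test(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        rev = nb_wald_test(m, ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_qvalues_match_bh_oracle(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            _nb_counts(rng, 60, 0.1, (500, 4)), columns=["a1", "a2", "b1", "b2"]
        )
        res = nb_wald_test(_matrix(counts, 1.0), ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(
            res["q_value"], bh_adjust_oracle(res["p_value"].to_numpy()), rtol=1e-12
        )

    def test_scaling_one_sample_leaves_calls_unchanged(self):
        """Median-of-ratios absorbs a per-sample scale factor."""
        rng = np.random.default_rng(4)
        base = _nb_counts(rng, 100, 0.05, (300, 6)).astype(float)
        base[:40, 3:] *= 8.0  # 40 genes truly up in group B
        counts = pd.DataFrame(base, columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        scaled = counts.copy()
        scaled["b2"] = (scaled["b2"] * 5).round()
        res1 = nb_wald_test(_matrix(counts.round()), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        res2 = nb_wald_test(_matrix(scaled), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        calls1 = call_changes(res1)
        calls2 = call_changes(res2)
        assert (calls1 == calls2).mean() > 0.97

    def test_planted_eightfold_decrease_recovered(self):
        """>= 90 of 100 genes with a planted 8x drop reach q < 0.05."""
        rng = np.random.default_rng(5)
        n = 1000
        mean_a = np.full(n, 100.0)
        mean_b = mean_a.copy()
        mean_b[:100] /= 8.0
        a = np.column_stack([_nb_counts(rng, mean_a, 0.05, n) for _ in range(3)])
        b = np.column_stack([_nb_counts(rng, mean_b, 0.05, n) for _ in range(3)])
        counts = pd.DataFrame(
            np.hstack([a, b]), columns=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        res = nb_wald_test(_matrix(counts, 1.0), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        down = call_changes(res) == "down"
        assert down[:100].sum() >= 90
        assert down[100:].sum() <= 10

    def test_agrees_with_deseq2_on_planted_changes(self):
        """Independent cross-check: on planted 8x decreases the internal NB
        Wald test and DESeq2 (pyDESeq2) call essentially the same genes."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(6)
        n = 600
        mean_a = np.full(n, 100.0)
        mean_b = mean_a.copy()
        mean_b[:60] /= 8.0
        a = np.column_stack([_nb_counts(rng, mean_a, 0.05, n) for _ in range(3)])
        b = np.column_stack([_nb_counts(rng, mean_b, 0.05, n) for _ in range(3)])
        genes = [f"g{i}" for i in range(n)]
        counts = pd.DataFrame(
            np.hstack([a, b]), index=genes, columns=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        res = nb_wald_test(_matrix(counts), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        mine = set(res.index[(res["q_value"] < 0.05) & (res["log2_fc"] < -1)])

        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=counts.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            stat.summary()
        ref = stat.results_df
        theirs = set(ref.index[(ref["padj"] < 0.05) & (ref["log2FoldChange"] < -1)])
        # the moment-based test is conservative relative to DESeq2's
        # shrinkage estimator: what it calls, DESeq2 also calls, and it
        # retains most of DESeq2's power
        assert len(mine & theirs) / len(mine) >= 0.95
        assert len(mine & theirs) / len(theirs) >= 0.75

    def test_single_replicate_group_errors(self):
        counts = pd.DataFrame({"a1": [5], "a2": [5], "b1": [5]})
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(_matrix(counts, 1.0), ["a1", "a2"], ["b1"])

    def test_low_signal_genes_not_tested(self):
        counts = pd.DataFrame(
            {"a1": [100, 1], "a2": [110, 2], "b1": [90, 1], "b2": [95, 0]},
            index=["hi", "lo"],
        )
        res = nb_wald_test(_matrix(counts, 1.0), ["a1", "a2"], ["b1", "b2"], min_signal=5)
        assert list(res.index) == ["hi"]


class TestDeriveUbGeneSets:
    @staticmethod
    def _result(down=(), up=()):
        genes = [f"g{i}" for i in range(10)]
        lfc = pd.Series(0.0, index=genes)
        q = pd.Series(1.0, index=genes)
        for g in down:
            lfc[g], q[g] = -3.0, 1e-6
        for g in up:
            lfc[g], q[g] = 3.0, 1e-6
        return pd.DataFrame({"base_mean": 100.0, "log2_fc": lfc, "stat": 0.0,
                             "p_value": q, "q_value": q})

    def test_sets_follow_contrast_directions(self):
        contrasts = {
            "GV_vs_MII": self._result(down=["g1", "g2"]),
            "GV_vs_twocell": self._result(down=["g1"]),
            "WTMII_vs_cKOMII": self._result(up=["g2", "g3"]),
        }
        catalog, venn = derive_ub_gene_sets(contrasts)
        assert catalog["MII-ub-down"] == {"g1", "g2"}
        assert catalog["two-cell-ub-down"] == {"g1"}
        assert catalog["cKO-MII-ub-up"] == {"g2", "g3"}
        assert venn["cKO-up&MII-down"] == 1

    def test_missing_contrast_errors(self):
        with pytest.raises(ValueError, match="GV_vs_twocell"):
            derive_ub_gene_sets({"GV_vs_MII": self._result(), "WTMII_vs_cKOMII": self._result()})

    def test_empty_input_gives_empty_sets(self):
        empty = self._result()
        catalog, _ = derive_ub_gene_sets(
            {k: empty for k in ("GV_vs_MII", "GV_vs_twocell", "WTMII_vs_cKOMII")}
        )
        assert all(len(catalog[n]) == 0 for n in catalog.names)
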