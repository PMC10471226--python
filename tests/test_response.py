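import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from homeovar import (
    ValidationError,
    build_response_records,
    classify_parental_bias,
    compare_class_expression,
    filter_expressed_pairs,
    filter_stratum,
    fold_change_he,
    fold_change_wgd,
    group_response_variance,
    transfer_go_annotations,
)


class TestFilterExpressedPairs:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "pair_id", "tpm_C",
                                           "tpm_A"])

    def test_sum_rule(self):
        expr = self._expr([("s1", "p0", 6.0, 3.0),   # sum 9: removed
                           ("s1", "p1", 10.0, 0.0),  # one copy silenced: kept
                           ("s1", "p2", 5.0, 5.0)])
        out = filter_expressed_pairs(expr)
        assert out["pair_id"].tolist() == ["p1", "p2"]

    def test_everything_below_threshold_warns(self, caplog):
        expr = self._expr([("s1", "p0", 1.0, 2.0)])
        with caplog.at_level("WARNING", logger="homeovar.response"):
            out = filter_expressed_pairs(expr)
        assert out.empty
        assert any("removed every pair" in m for m in caplog.messages)


class TestFoldChanges:
    def test_he_examples(self):
        assert fold_change_he(30, 10, 20, 20) == pytest.approx(1.0)
        assert np.isnan(fold_change_he(10, 10, 0, 0))

    def test_wgd_examples(self):
        assert fold_change_wgd(20, 20, 20, 20) == pytest.approx(2.0)
        assert fold_change_wgd(5, 5, 0, 40) == pytest.approx(0.5)
        assert np.isnan(fold_change_wgd(10, 10, 0, 0))

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError):
            fold_change_he(-1, 0, 1, 1)

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=4, max_size=4).filter(
            lambda v: v[2] + v[3] > 0
        )
    )
    def test_wgd_is_exactly_twice_he(self, tpms):
        c, a, o, r = tpms
        assert fold_change_wgd(c, a, o, r) == 2.0 * fold_change_he(c, a, o, r)


class TestParentalBias:
    @pytest.mark.parametrize(
        "o,r,expected",
        [
            (160, 10, "BnC"),   # log2 FC = 4 > 3.5
            (10, 160, "BnA"),
            (50, 50, "unbiased"),
            (2 ** 3.5, 1.0, "unbiased"),  # boundary is strict
        ],
    )
    def test_classes(self, o, r, expected):
        got = classify_parental_bias(o, r, pseudocount=0.0)
        assert got == expected

    def test_both_zero_unclassifiable(self):
        assert classify_parental_bias(0.0, 0.0) is None

    def test_single_zero_parent_tolerated(self):
        assert classify_parental_bias(100.0, 0.0) == "BnC"

    def test_infinite_threshold_makes_everything_unbiased(self, rng):
        o = rng.random(50) * 100
        r = rng.random(50) * 100
        got = classify_parental_bias(o, r, threshold_log2fc=np.inf)
        assert (got == "unbiased").all()

    def test_partition_of_classifiable_pairs(self, rng):
        o = np.r_[rng.random(100) * 200, 0.0]
        r = np.r_[rng.random(100) * 200, 0.0]
        got = classify_parental_bias(o, r)
        assert got[-1] is None
        assert set(got[:-1]) <= {"BnC", "BnA", "unbiased"}


class TestTransferGo:
    def _go(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "go_id", "go_class"])

    def test_direct_pair_and_subgenome_ids(self, pair_frame):
        go = self._go([("p000", "GO:1", "I"), ("BoC1g1", "GO:2", "II"),
                       ("BrA1g2", "GO:3", "I")])
        out = transfer_go_annotations(pair_frame, go)
        got = dict(zip(out["go_id"], out["pair_id"]))
        assert got == {"GO:1": "p000", "GO:2": "p001", "GO:3": "p002"}

    def test_thaliana_chain_and_union(self, pair_frame):
        # one thaliana gene hits two oleracea orthologs -> both pairs
        ortho = pd.DataFrame({
            "thaliana_gene": ["AT1", "AT1", "AT2"],
            "oleracea_gene": ["BoC1g0", "BoC1g1", "BoC2g0"],
        })
        go = self._go([("AT1", "GO:7", "II"), ("AT2", "GO:8", "I")])
        out = transfer_go_annotations(pair_frame, go, ortho)
        go7 = set(out.loc[out["go_id"] == "GO:7", "pair_id"])
        assert go7 == {"p000", "p001"}
        assert set(out.loc[out["go_id"] == "GO:8", "pair_id"]) == {"p004"}

    def test_disjoint_go_sets_union_on_shared_pair(self, pair_frame):
        ortho = pd.DataFrame({"thaliana_gene": ["AT1", "AT2"],
                              "oleracea_gene": ["BoC1g0", "BoC1g0"]})
        go = self._go([("AT1", "GO:1", "I"), ("AT2", "GO:2", "II")])
        out = transfer_go_annotations(pair_frame, go, ortho)
        assert set(out.loc[out["pair_id"] == "p000", "go_id"]) == {"GO:1",
                                                                   "GO:2"}

    def test_unresolvable_gene_dropped(self, pair_frame):
        out = transfer_go_annotations(pair_frame,
                                      self._go([("nope", "GO:1", "I")]))
        assert out.empty


def _records(fold_changes_by_pair, dosage="3:1", sample="s1", bias="unbiased"):
    rows = []
    for pair_id, fcs in fold_changes_by_pair.items():
        for i, fc in enumerate(np.atleast_1d(fcs)):
            rows.append((pair_id, f"{sample}{i}", 1, "HE", dosage, fc, bias))
    return pd.DataFrame(
        rows, columns=["pair_id", "sample_id", "generation", "mode",
                       "dosage_class", "fold_change", "bias_class"],
    )


def _go_map(pair_ids, go_id="GO:1", go_class="I"):
    return pd.DataFrame({"pair_id": list(pair_ids), "go_id": go_id,
                         "go_class": go_class})


class TestGroupResponseVariance:
    def test_undersized_go_term_dropped(self):
        recs = _records({f"p{i}": 1.0 + 0.01 * i for i in range(19)})
        out = group_response_variance(recs, _go_map(recs["pair_id"]),
                                      min_go_genes=20)
        assert out.empty

    def test_cv_of_identical_fold_changes_is_zero(self):
        recs = _records({f"p{i}": 2.0 for i in range(20)})
        out = group_response_variance(recs, _go_map(recs["pair_id"]),
                                      min_go_genes=20)
        assert out["cv"].tolist() == [0.0]
        assert out["n_pairs"].tolist() == [20]

    def test_cv_arithmetic(self):
        recs = _records({"p0": 1.0, "p1": 2.0, "p2": 3.0})
        out = group_response_variance(recs, _go_map(["p0", "p1", "p2"]),
                                      min_go_genes=3)
        assert out["cv"].iloc[0] == pytest.approx(0.5)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_cv_scale_invariance(self, scale):
        base = {f"p{i}": v for i, v in enumerate([1.0, 2.0, 4.0, 0.5])}
        scaled = {k: v * scale for k, v in base.items()}
        a = group_response_variance(_records(base), _go_map(base),
                                    min_go_genes=4)
        b = group_response_variance(_records(scaled), _go_map(scaled),
                                    min_go_genes=4)
        assert b["cv"].iloc[0] == pytest.approx(a["cv"].iloc[0], rel=1e-9)

    def test_size_filter_counts_pairs_not_observations(self):
        # 10 pairs x 3 samples = 30 observations but only 10 genes
        recs = _records({f"p{i}": [1.0, 1.5, 2.0] for i in range(10)})
        assert len(recs) == 30
        out = group_response_variance(recs, _go_map(recs["pair_id"].unique()),
                                      min_go_genes=11)
        assert out.empty
        out = group_response_variance(recs, _go_map(recs["pair_id"].unique()),
                                      min_go_genes=10)
        assert out["n_pairs"].tolist() == [10]
        assert out["n_obs"].tolist() == [30]

    def test_collapse_pairs_mean(self):
        recs = _records({"p0": [1.0, 3.0], "p1": [2.0, 2.0], "p2": [4.0, 2.0]})
        out = group_response_variance(recs, _go_map(["p0", "p1", "p2"]),
                                      min_go_genes=3, collapse_pairs="mean")
        # per-pair means are 2, 2, 3 -> mean 7/3, sd 1/sqrt(3)
        assert out["cv"].iloc[0] == pytest.approx((1 / np.sqrt(3)) / (7 / 3))


class TestCompareClassExpression:
    def _expr(self, means_by_class):
        rows, go_rows = [], []
        p = 0
        for go_class, means in means_by_class.items():
            for g, mean in enumerate(means):
                go_id = f"GO:{go_class}{g}"
                for _ in range(2):  # two genes per term
                    rows.append(("s1", f"p{p}", mean, mean))
                    go_rows.append((f"p{p}", go_id, go_class))
                    p += 1
        expr = pd.DataFrame(rows, columns=["sample_id", "pair_id", "tpm_C",
                                           "tpm_A"])
        go_map = pd.DataFrame(go_rows, columns=["pair_id", "go_id",
                                                "go_class"])
        return expr, go_map

    def test_identical_distributions_not_significant(self):
        expr, go_map = self._expr({"I": [10, 20, 30], "II": [10, 20, 30]})
        res = compare_class_expression(expr, go_map, min_go_genes=2)
        assert res.p_value > 0.5

    def test_separated_classes_detected_with_direction(self):
        # per-GO mean TPMs are {8,10,12} (I) vs {2,4,6} (II): the clean
        # rank split gives H = 27/7 and its chi-square(1) p
        expr, go_map = self._expr({"I": [4, 5, 6], "II": [1, 2, 3]})
        res = compare_class_expression(expr, go_map, min_go_genes=2)
        assert res.direction == "II < I"
        assert res.statistic == pytest.approx(27 / 7)
        assert res.p_value == pytest.approx(chi2.sf(27 / 7, df=1))

    def test_single_go_term_rejected(self):
        expr, go_map = self._expr({"I": [10]})
        with pytest.raises(ValidationError):
            compare_class_expression(expr, go_map, min_go_genes=2)

    def test_class_without_terms_rejected(self):
        expr, go_map = self._expr({"I": [10, 20]})
        with pytest.raises(ValidationError):
            compare_class_expression(expr, go_map, min_go_genes=2)


class TestBuildResponseRecords:
    def _inputs(self):
        expr = pd.DataFrame({
            "sample_id": ["s1"] * 4 + ["s2"] * 4,
            "pair_id": ["p0", "p1", "p2", "p3"] * 2,
            "tpm_C": [30.0, 5.0, 20.0, 3.0, 30.0, 5.0, 20.0, 3.0],
            "tpm_A": [10.0, 15.0, 20.0, 2.0, 10.0, 15.0, 20.0, 2.0],
        })
        parental = pd.DataFrame({
            "pair_id": ["p0", "p1", "p2", "p3"],
            "tpm_oleracea": [20.0, 10.0, 0.0, 10.0],
            "tpm_rapa": [20.0, 10.0, 0.0, 10.0],
        })
        states = pd.DataFrame({
            "sample_id": ["s1"] * 4 + ["s2"] * 4,
            "pair_id": ["p0", "p1", "p2", "p3"] * 2,
            "chrom_pair": "C1/A1",
            "order_index": [0, 1, 2, 3] * 2,
            # p0 is HE in s1 but balanced in s2
            "dosage_class": ["3:1", "2:2", "2:2", "2:2",
                             "2:2", "2:2", "2:2", "2:2"],
        })
        meta = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "line_id": ["L1", "L2"], "generation": [1, 10]})
        return expr, parental, states, meta

    def test_he_mode_keeps_only_he_classes(self):
        expr, parental, states, meta = self._inputs()
        recs = build_response_records(expr, parental, states, meta, "HE")
        assert recs["pair_id"].tolist() == ["p0"]
        assert recs["fold_change"].iloc[0] == pytest.approx(1.0)
        assert recs["generation"].tolist() == [1]

    def test_wgd_mode_uses_per_sample_dosage(self):
        # p0 contributes to the 2:2 dataset only from s2, where it is 2:2
        expr, parental, states, meta = self._inputs()
        recs = build_response_records(expr, parental, states, meta, "WGD")
        p0 = recs[recs["pair_id"] == "p0"]
        assert p0["sample_id"].tolist() == ["s2"]
        assert p0["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_zero_baseline_and_low_expression_dropped(self):
        expr, parental, states, meta = self._inputs()
        recs = build_response_records(expr, parental, states, meta, "WGD")
        # p2 has a zero parental baseline, p3 has summed TPM 5 < 10
        assert "p2" not in set(recs["pair_id"])
        assert "p3" not in set(recs["pair_id"])

    def test_stratum_filters_are_honest_subsets(self):
        expr, parental, states, meta = self._inputs()
        recs = build_response_records(expr, parental, states, meta, "WGD")
        g10 = filter_stratum(recs, generation=10)
        assert set(g10["sample_id"]) == {"s2"}
        pd.testing.assert_frame_equal(
            g10, recs[recs["generation"] == 10]
        )
        with pytest.raises(ValidationError):
            filter_stratum(recs, bias="sideways")
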