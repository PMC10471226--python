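import numpy as np
import pandas as pd
import pytest

from homeovar import ValidationError
from homeovar.response import fold_change_he, fold_change_wgd
from homeovar.simulate import (
    SimConfig,
    simulate_depths,
    simulate_dosage_mixture,
    simulate_expression,
    simulate_genome,
    simulate_study,
)


def _tiny_config(**overrides) -> SimConfig:
    base = dict(
        n_chromosome_pairs=2, pairs_per_chromosome=1000, n_lines=2,
        generations=(1, 10), he_rate_per_generation=1.0,
        n_go_per_class=10, genes_per_go=20, seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_pair_map_dimensions_and_density(self):
        truth = simulate_genome(_tiny_config())
        assert len(truth.pairs) == 2000
        per_chrom = truth.pairs.groupby("chrom_pair")["order_index"]
        for _, idx in per_chrom:
            assert sorted(idx) == list(range(1000))

    def test_zero_he_rate_leaves_everything_balanced(self):
        truth = simulate_genome(_tiny_config(he_rate_per_generation=0.0))
        assert truth.segments == []
        assert (truth.copies["c_C"] == 2).all()
        assert (truth.copies["c_A"] == 2).all()

    def test_seed_determinism(self):
        a = simulate_genome(_tiny_config())
        b = simulate_genome(_tiny_config())
        pd.testing.assert_frame_equal(a.copies, b.copies)
        assert a.segments == b.segments

    def test_infeasible_segment_length_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            _tiny_config(segment_min_length=5000)

    def test_go_universe_shape(self):
        truth = simulate_genome(_tiny_config())
        sizes = truth.go_map.groupby(["go_id", "go_class"]).size()
        assert len(sizes) == 20
        assert (sizes == 20).all()
        by_class = truth.go_map.drop_duplicates("go_id")["go_class"]
        assert (by_class == "I").sum() == 10 and (by_class == "II").sum() == 10
        # disjoint terms: every pair belongs to at most one
        assert not truth.go_map["pair_id"].duplicated().any()

    def test_segments_accumulate_within_a_line(self):
        truth = simulate_genome(_tiny_config(he_rate_per_generation=2.0))
        for line in ("L1", "L2"):
            early = {(s.chrom_pair, s.start_index, s.end_index, s.dosage_class)
                     for s in truth.segments if s.sample_id == f"{line}_g1"}
            late = {(s.chrom_pair, s.start_index, s.end_index, s.dosage_class)
                    for s in truth.segments if s.sample_id == f"{line}_g10"}
            assert early <= late

    def test_segments_disjoint_within_sample(self):
        truth = simulate_genome(_tiny_config(he_rate_per_generation=3.0))
        by_sample: dict = {}
        for seg in truth.segments:
            by_sample.setdefault((seg.sample_id, seg.chrom_pair), []).append(
                (seg.start_index, seg.end_index)
            )
        for spans in by_sample.values():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestSimulateDepths:
    def test_noiseless_balanced_ratio_exact(self):
        cfg = _tiny_config(he_rate_per_generation=0.0, depth_noise=False,
                           cross_mapping_rate=0.0)
        truth = simulate_genome(cfg)
        depths = simulate_depths(truth)
        ratio = depths["depth_C"] / (depths["depth_C"] + depths["depth_A"])
        assert (ratio == 0.5).all()

    def test_noiseless_extreme_dosage_without_crossmapping(self):
        cfg = _tiny_config(depth_noise=False, cross_mapping_rate=0.0,
                           he_rate_per_generation=2.0,
                           dosage_class_weights={"0:4": 1.0})
        truth = simulate_genome(cfg)
        depths = simulate_depths(truth).merge(truth.copies,
                                              on=["sample_id", "pair_id"])
        he = depths[depths["c_C"] == 0]
        assert len(he) > 0
        assert (he["depth_C"] == 0).all()
        assert (he["depth_A"] > 0).all()

    def test_mean_balanced_ratio_near_half_under_noise(self):
        cfg = _tiny_config(he_rate_per_generation=0.0, n_lines=3,
                           pairs_per_chromosome=2000)
        truth = simulate_genome(cfg)
        depths = simulate_depths(truth)
        sub = depths.head(10_000)
        ratio = sub["depth_C"] / (sub["depth_C"] + sub["depth_A"])
        assert abs(ratio.mean() - 0.5) < 0.01

    def test_cross_mapping_shifts_extreme_ratios_inward(self):
        cfg = _tiny_config(depth_noise=False, cross_mapping_rate=0.02,
                           he_rate_per_generation=2.0,
                           dosage_class_weights={"4:0": 1.0})
        truth = simulate_genome(cfg)
        depths = simulate_depths(truth).merge(truth.copies,
                                              on=["sample_id", "pair_id"])
        he = depths[depths["c_A"] == 0]
        ratio = he["depth_C"] / (he["depth_C"] + he["depth_A"])
        assert ((ratio > 0.95) & (ratio < 1.0)).all()


class TestSimulateExpression:
    def test_noiseless_fold_changes_follow_dosage_model(self):
        cfg = _tiny_config(response_noise_sd=0.0, he_rate_per_generation=2.0)
        truth = simulate_genome(cfg)
        expr, parental = simulate_expression(truth)
        df = (expr.merge(parental, on="pair_id")
                  .merge(truth.copies, on=["sample_id", "pair_id"]))
        fc = fold_change_he(df["tpm_C"], df["tpm_A"],
                            df["tpm_oleracea"], df["tpm_rapa"])
        expected = (
            df["c_C"] / 2 * df["tpm_oleracea"] + df["c_A"] / 2 * df["tpm_rapa"]
        ) / (df["tpm_oleracea"] + df["tpm_rapa"])
        assert np.allclose(fc, expected)
        balanced = (df["c_C"] == 2) & (df["c_A"] == 2)
        assert np.allclose(fc[balanced], 1.0)
        fcw = fold_change_wgd(df["tpm_C"], df["tpm_A"],
                              df["tpm_oleracea"], df["tpm_rapa"])
        assert np.allclose(fcw[balanced], 2.0)

    def test_biased_pairs_have_planted_magnitude(self):
        truth = simulate_genome(_tiny_config(biased_fraction=0.3))
        _, parental = simulate_expression(truth)
        df = parental.merge(truth.bias, on="pair_id")
        log2fc = np.log2(df["tpm_oleracea"] / df["tpm_rapa"])
        assert np.allclose(log2fc[df["bias_class"] == "BnC"], 5.0)
        assert np.allclose(log2fc[df["bias_class"] == "BnA"], -5.0)
        assert np.allclose(log2fc[df["bias_class"] == "unbiased"], 0.0)

    def test_constraint_factor_shrinks_class_ii_response_spread(self):
        cfg = _tiny_config(he_rate_per_generation=0.0, constraint_factor=0.4,
                           biased_fraction=0.0, n_go_per_class=20)
        truth = simulate_genome(cfg)
        expr, parental = simulate_expression(truth)
        df = (expr.merge(parental, on="pair_id")
                  .merge(truth.go_map, on="pair_id"))
        fc = fold_change_wgd(df["tpm_C"], df["tpm_A"],
                             df["tpm_oleracea"], df["tpm_rapa"])
        spread_i = np.log(fc[df["go_class"] == "I"]).std()
        spread_ii = np.log(fc[df["go_class"] == "II"]).std()
        assert spread_ii < 0.6 * spread_i


def test_bias_scoped_constraint_reproduces_stratified_pattern():
    """Constraining only BnC-biased and unbiased class-II genes makes the
    class difference appear in those strata but not in the BnA stratum."""
    from homeovar import response as R

    cfg = SimConfig(
        n_go_per_class=40, genes_per_go=100, biased_fraction=0.5,
        bias_c_share=0.5, constraint_factor=0.5,
        constraint_bias_scope=("BnC", "unbiased"),
        n_chromosome_pairs=1, pairs_per_chromosome=8000, seed=21,
    )
    study = simulate_dosage_mixture(
        cfg, {"0:4": 0.25, "1:3": 0.25, "3:1": 0.25, "4:0": 0.25},
        n_samples=8,
    )
    recs = R.build_response_records(
        study.expression, study.parental, study.truth.states(),
        study.truth.sample_meta, "HE",
    )
    p_by_bias = {}
    for bias in ("BnC", "BnA", "unbiased"):
        cv = R.group_response_variance(
            R.filter_stratum(recs, bias=bias), study.truth.go_map
        )
        p_by_bias[bias] = R.class_comparison(cv).p_value
    assert p_by_bias["BnC"] <= 0.05
    assert p_by_bias["unbiased"] <= 0.05
    assert p_by_bias["BnA"] > 0.05


class TestDosageMixture:
    def test_mixture_states_match_requested_probs(self):
        cfg = _tiny_config(n_go_per_class=20, genes_per_go=25)
        study = simulate_dosage_mixture(cfg, {"2:2": 0.5, "0:4": 0.5},
                                        n_samples=4)
        states = study.truth.states()
        freq = states["dosage_class"].value_counts(normalize=True)
        assert set(freq.index) == {"2:2", "0:4"}
        assert abs(freq["2:2"] - 0.5) < 0.05

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            simulate_dosage_mixture(_tiny_config(), {"5:0": 1.0})


def test_study_write_round_trips_through_readers(tmp_path):
    from homeovar import io

    cfg = _tiny_config(n_lines=1, generations=(1,))
    study = simulate_study(cfg, outdir=tmp_path)
    pairs = io.read_pair_table(tmp_path / "pairs.tsv")
    assert len(pairs) == len(study.truth.pairs)
    depths = io.read_depth_table(tmp_path / "depths.tsv")
    assert len(depths) == len(study.depths)
    go = io.read_go_tables(tmp_path / "go_genes.tsv",
                           tmp_path / "go_classes.tsv")
    assert go["go_id"].nunique() == 20
    segs = io.read_segments_bed(tmp_path / "truth_segments.bed")
    assert len(segs) == len(study.truth.segments)
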