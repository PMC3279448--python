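"""Generator contracts: bounds, determinism, calibration of moments."""

import numpy as np
import pandas as pd
import pytest

from repmeth.synthetic_data import (
    SimConfig,
    simulate_annotation,
    simulate_beta_matrix,
    simulate_cohort,
    structural_marker_effects,
)


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize("bad", [
        {"n_subjects": 0},
        {"marker_correlation": 1.0},
        {"residual_sd": 0.0},
        {"covariate_prevalences": {"male": 1.2}},
        {"class_beta_params": ((1.0, -2.0),) * 16},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestCohort:
    def test_bounds_and_shape(self, small_cohort):
        assert len(small_cohort) == 380
        pct = small_cohort["birth_weight_percentile"]
        assert ((pct > 0) & (pct < 100)).all()
        for col in ("line1_mean", "aluyb8_mean"):
            assert small_cohort[col].between(0, 100).all()

    def test_seeded_reproducibility(self, default_config):
        a = simulate_cohort(default_config, seed=4)
        b = simulate_cohort(default_config, seed=4)
        c = simulate_cohort(default_config, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert not a["line1_mean"].equals(c["line1_mean"])

    def test_zero_correlation_config(self):
        cfg = SimConfig(marker_correlation=0.0, n_subjects=10_000)
        c = simulate_cohort(cfg, seed=0)
        r = np.corrcoef(c["line1_mean"], c["aluyb8_mean"])[0, 1]
        assert abs(r) < 0.03

    def test_moments_converge_large_n(self):
        cfg = SimConfig(n_subjects=10_000)
        c = simulate_cohort(cfg, seed=1)
        assert c["line1_mean"].mean() == pytest.approx(51.7, abs=0.2)
        assert c["aluyb8_mean"].mean() == pytest.approx(65.0, abs=0.2)
        assert c["line1_mean"].std() == pytest.approx(4.6, abs=0.2)
        assert (c["tobacco"] == "yes").mean() == pytest.approx(36 / 380, abs=0.01)

    def test_degenerate_noise_gives_intercept(self):
        cfg = SimConfig(
            effect_line1_per10=0.0, effect_alu_per10=0.0,
            effect_male_sex=0.0, effect_white_ethnicity=0.0,
            residual_sd=1e-9, n_subjects=200,
        )
        c = simulate_cohort(cfg, seed=2)
        assert np.allclose(c["birth_weight_percentile"], 50.0, atol=1e-6)

    def test_structural_effects_reduce_to_marginal_when_uncorrelated(self):
        cfg = SimConfig(marker_correlation=0.0)
        b1, b2 = structural_marker_effects(cfg)
        assert b1 == pytest.approx(9.7)
        assert b2 == pytest.approx(14.5)


class TestBetaMatrix:
    def test_values_in_unit_interval(self, small_matrix):
        m, _ = small_matrix
        v = m.to_numpy()
        assert ((v > 0) & (v < 1)).all()

    def test_single_symmetric_class(self):
        cfg = SimConfig(n_latent_classes=1, class_beta_params=((50.0, 50.0),),
                        class_weights=(1.0,), n_loci=400, n_array_subjects=30)
        m, truth = simulate_beta_matrix(cfg, seed=0)
        assert m.to_numpy().mean() == pytest.approx(0.5, abs=0.01)
        assert set(truth.latent_class) == {1}

    def test_class_means_strictly_increasing(self, small_matrix):
        m, truth = small_matrix
        v = m.to_numpy()
        emp = [v[truth.latent_class == k].mean()
               for k in range(1, 17) if (truth.latent_class == k).any()]
        assert np.all(np.diff(emp) > 0)

    def test_default_matrix_mean_matches_array_scale(self, default_config):
        m, _ = simulate_beta_matrix(default_config, seed=9)
        assert 0.2 <= m.to_numpy().mean() <= 0.3

    def test_every_locus_has_one_class(self, small_matrix):
        m, truth = small_matrix
        assert truth.latent_class.shape == (m.shape[0],)
        assert np.all((truth.latent_class >= 1) & (truth.latent_class <= 16))


class TestAnnotation:
    def test_all_zero_frequencies(self):
        cfg = SimConfig(n_loci=50, attribute_frequencies={
            "cgi": 0.0, "pcg": 0.0, "tfbs": 0.0, "repeat": {}})
        ann = simulate_annotation(cfg, seed=0)
        assert not ann[["cgi", "pcg", "tfbs"]].any().any()
        assert (ann["tfbs_factors"] == "").all()

    def test_class_override_enriches_cgi(self):
        cfg = SimConfig(n_loci=4000, attribute_frequencies={
            "cgi": 0.3, "pcg": 0.1, "tfbs": 0.4, "repeat": {"alu": 0.1},
            "class_overrides": {9: {"cgi": 0.81}}})
        _, truth = simulate_beta_matrix(cfg, seed=5)
        ann = simulate_annotation(cfg, labels=truth, seed=5)
        frac = ann.loc[truth.latent_class == 9, "cgi"].mean()
        assert frac == pytest.approx(0.81, abs=0.06)

    def test_seeded_determinism(self):
        cfg = SimConfig(n_loci=100)
        a = simulate_annotation(cfg, seed=7)
        b = simulate_annotation(cfg, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_tfbs_set_nonempty_iff_flag(self):
        cfg = SimConfig(n_loci=300)
        ann = simulate_annotation(cfg, seed=1)
        assert ((ann["tfbs_factors"] != "") == ann["tfbs"]).all()

    def test_repeat_probabilities_must_sum_below_one(self):
        cfg = SimConfig(n_loci=10, attribute_frequencies={
            "repeat": {"alu": 0.6, "line1": 0.6}})
        with pytest.raises(ValueError, match="sum"):
            simulate_annotation(cfg, seed=0)
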