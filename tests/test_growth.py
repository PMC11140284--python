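"""Latent growth-curve model: implied moments, ML fit, fit indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vistraj import growth, synth
from vistraj.errors import EstimationError


def exact_moment_sample(mu, sigma, n, seed=0):
    """Data whose ML sample moments equal (mu, sigma) exactly."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(mu)))
    z -= z.mean(axis=0)
    chol_emp = np.linalg.cholesky(z.T @ z / n)
    z = z @ np.linalg.inv(chol_emp).T @ np.linalg.cholesky(sigma).T
    return z + mu


class TestImpliedMoments:
    def test_noiseless_flat_trajectory(self, design):
        params = growth.LgcmParams([4.0, 0.0], np.zeros((2, 2)), np.zeros(4))
        mu, sigma = growth.implied_moments(params, design)
        assert np.allclose(mu, 4.0)
        assert np.allclose(sigma, 0.0)

    def test_published_class_means_give_linear_profile(self, design):
        params = growth.LgcmParams([3.992, -0.174], np.zeros((2, 2)), np.zeros(4))
        mu, _ = growth.implied_moments(params, design)
        assert np.allclose(mu, [3.992, 3.818, 3.644, 3.470])

    def test_identity_psi_expansion(self, design):
        params = growth.LgcmParams([0.0, 0.0], np.eye(2), np.full(4, 0.2))
        _, sigma = growth.implied_moments(params, design)
        t = np.arange(4.0)
        expect = 1.0 + np.outer(t, t) + 0.2 * np.eye(4)
        assert np.allclose(sigma, expect)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        a=st.floats(-2, 2), b=st.floats(-2, 2), c=st.floats(0.1, 2.0),
        scale=st.floats(0.5, 3.0),
    )
    def test_linearity_in_parameters(self, design, a, b, c, scale):
        p1 = growth.LgcmParams([a, b], c * np.eye(2), np.full(4, c))
        mu1, s1 = growth.implied_moments(p1, design)
        p2 = growth.LgcmParams(
            [scale * a, scale * b], scale * c * np.eye(2), np.full(4, scale * c)
        )
        mu2, s2 = growth.implied_moments(p2, design)
        assert np.allclose(mu2, scale * mu1)
        assert np.allclose(s2, scale * s1)


class TestFit:
    def test_saturated_fit_recovers_params_with_perfect_indices(self, design):
        params = growth.LgcmParams([3.7, -0.1], np.diag([0.3, 0.01]), np.full(4, 0.2))
        mu, sigma = growth.implied_moments(params, design)
        y = exact_moment_sample(mu, sigma, 400)
        fit = growth.fit_lgcm(y, design)
        assert np.allclose(fit.params.alpha, params.alpha, atol=1e-3)
        assert np.allclose(fit.params.theta, params.theta, atol=1e-2)
        assert fit.indices.chi_square < 0.01
        assert fit.indices.cfi == 1.0
        assert fit.indices.rmsea == 0.0

    def test_recovery_of_generating_parameters(self):
        cfg = synth.null_one_class(seed=31, n_subjects=2000)
        y = synth.simulate_trajectories(cfg).vision_matrix()
        fit = growth.fit_lgcm(y)
        from conftest import ols_se

        se = ols_se(cfg)
        assert abs(fit.params.alpha[0] - 3.745) < 3 * se[0]
        assert abs(fit.params.alpha[1] - (-0.088)) < 3 * se[1]
        assert abs(fit.params.psi[0, 0] - 0.30) < 0.06
        assert np.all(np.abs(fit.params.theta - 0.20) < 0.05)

    def test_fiml_agrees_with_complete_data_fit(self):
        cfg = synth.null_one_class(seed=32, n_subjects=2000, missing_rate=0.2)
        table = synth.simulate_trajectories(cfg)
        full = growth.fit_lgcm(table.vision_matrix())
        masked = synth.apply_missingness(table, cfg)
        part = growth.fit_lgcm(masked.vision_matrix(), allow_partial=True)
        assert part.n_used < full.n_used  # some subjects drop below 3 waves
        assert np.allclose(part.params.alpha, full.params.alpha, atol=0.06)
        assert np.allclose(part.params.theta, full.params.theta, atol=0.06)

    def test_loglik_at_estimate_beats_generating_parameters(self, design):
        cfg = synth.null_one_class(seed=33, n_subjects=500)
        y = synth.simulate_trajectories(cfg).vision_matrix()
        fit = growth.fit_lgcm(y)
        gen = growth.LgcmParams([3.745, -0.088], cfg.psi, cfg.theta)
        mu, sigma = growth.implied_moments(gen, design)
        from vistraj import _mvn

        ll_gen = _mvn.gaussian_loglik(_mvn.pattern_groups(y), mu, sigma)
        assert fit.loglik >= ll_gen - 1e-6

    def test_indices_invariant_to_subject_order(self, paper_vision):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(paper_vision))
        f1 = growth.fit_lgcm(paper_vision)
        f2 = growth.fit_lgcm(paper_vision[perm])
        assert np.isclose(f1.indices.chi_square, f2.indices.chi_square, atol=1e-6)
        assert np.isclose(f1.indices.srmr, f2.indices.srmr, atol=1e-8)

    def test_too_few_subjects_raises(self, design):
        with pytest.raises(EstimationError):
            growth.fit_lgcm(np.full((5, 4), 3.0), design)


class TestFitIndices:
    S = np.eye(4)

    def test_perfect_fit_limit(self):
        idx = growth.fit_indices(5.0, 5, 100.0, 6, self.S, self.S, 1000)
        assert idx.rmsea == 0.0
        assert idx.cfi == 1.0

    def test_rmsea_closed_form_matches_published_report(self):
        # chi-square/df = 2.869 with df=5 at n=2235 prints RMSEA 0.029
        idx = growth.fit_indices(14.345, 5, 500.0, 6, self.S, self.S, 2235)
        assert abs(idx.rmsea - 0.0289) < 5e-4
        assert round(idx.rmsea, 3) == 0.029

    def test_cfi_closed_form(self):
        idx = growth.fit_indices(14.345, 5, 500.0, 6, self.S, self.S, 2235)
        assert np.isclose(idx.cfi, 1 - 9.345 / 494.0, atol=1e-9)

    def test_srmr_standardised_residuals(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        sig = np.array([[1.0, 0.3], [0.3, 1.0]])
        idx = growth.fit_indices(1.0, 1, 10.0, 2, s, sig, 100)
        # residuals: 0 on diagonal, 0.2 off-diagonal; lower triangle = (0, 0.2, 0)
        assert np.isclose(idx.srmr, np.sqrt(0.04 / 3))

    def test_baseline_df_must_exceed_model_df(self):
        with pytest.raises(EstimationError):
            growth.fit_indices(5.0, 5, 10.0, 5, self.S, self.S, 100)

    def test_sample_indices_meet_reporting_thresholds(self, one_class_fit):
        # the one-class fit on correctly specified synthetic data should
        # clear the published adequacy thresholds easily
        idx = one_class_fit.indices
        assert idx.chi_df_ratio < 3 and idx.cfi > 0.95 and idx.tli > 0.95
        assert idx.rmsea < 0.06 and idx.srmr < 0.08
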