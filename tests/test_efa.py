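"""Minres extraction, promax rotation, VSS and loading diagnostics."""

import numpy as np
import pandas as pd
import pytest

from microsem.efa import (
    complexity_scores,
    fit_efa,
    fit_minres,
    promax_rotate,
    varimax,
    vss_curve,
)
from microsem.errors import ValidationError


def _forward_r(lam: np.ndarray, phi: np.ndarray | None = None) -> np.ndarray:
    lam = np.atleast_2d(lam.T).T if lam.ndim == 1 else lam
    if lam.ndim == 1:
        lam = lam[:, None]
    if phi is None:
        phi = np.eye(lam.shape[1])
    common = lam @ phi @ lam.T
    r = common + np.diag(1.0 - np.diag(common))
    return r


def _oblique_factor_sample(rng, n, loadings, phi):
    chol = np.linalg.cholesky(phi)
    f = rng.normal(size=(n, phi.shape[0])) @ chol.T
    u = np.sqrt(1.0 - np.diag(loadings @ phi @ loadings.T))
    return f @ loadings.T + rng.normal(size=(n, loadings.shape[0])) * u


class TestMinres:
    def test_identity_has_no_common_variance(self):
        fit = fit_minres(np.eye(5), 1)
        assert np.abs(fit.loadings.to_numpy()).max() <= 0.05
        assert fit.h2.max() <= 0.05

    def test_forward_constructed_recovery(self):
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        fit = fit_minres(_forward_r(lam[:, None]), 1)
        np.testing.assert_allclose(
            np.abs(fit.loadings.to_numpy().ravel()), lam, atol=0.01
        )

    def test_beats_eigen_truncation(self, rng):
        x = rng.normal(size=(200, 6))
        x[:, 1] += x[:, 0]
        x[:, 3] += 0.5 * x[:, 2]
        r = np.corrcoef(x, rowvar=False)
        fit = fit_minres(r, 2)
        lam = fit.loadings.to_numpy()
        resid_fit = r - lam @ lam.T
        vals, vecs = np.linalg.eigh(r)
        top = vecs[:, -2:] * np.sqrt(vals[-2:])
        resid_eig = r - top @ top.T
        def offsq(m):
            return ((m - np.diag(np.diag(m))) ** 2).sum()
        assert offsq(resid_fit) <= offsq(resid_eig) + 1e-10

    def test_nfactors_bounds(self):
        with pytest.raises(ValidationError):
            fit_minres(np.eye(4), 4)

    def test_h2_u2_sum_to_one(self, rng):
        x = rng.normal(size=(300, 6))
        x[:, 1] += x[:, 0]
        r = np.corrcoef(x, rowvar=False)
        fit = fit_efa(r, 2, rotation="promax")
        np.testing.assert_allclose(fit.h2 + fit.u2, 1.0, atol=1e-8)


class TestPromax:
    def test_simple_structure_is_fixed_point(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.8
        lam[3:, 1] = 0.8
        pattern, phi = promax_rotate(lam, 4)
        np.testing.assert_allclose(np.abs(pattern), lam, atol=1e-8)
        assert abs(phi[0, 1]) <= 0.05

    def test_kappa_one_reduces_to_varimax(self, rng):
        lam = rng.normal(size=(8, 3))
        v, _ = varimax(lam)
        pattern, phi = promax_rotate(lam, 1)
        np.testing.assert_allclose(np.abs(pattern), np.abs(v), atol=1e-6)
        np.testing.assert_allclose(phi, np.eye(3), atol=1e-6)

    def test_recovers_factor_correlation(self, rng):
        loadings = np.zeros((8, 2))
        loadings[:4, 0] = 0.8
        loadings[4:, 1] = 0.8
        phi_true = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = _oblique_factor_sample(rng, 2000, loadings, phi_true)
        r = np.corrcoef(x, rowvar=False)
        fit = fit_efa(r, 2, rotation="promax")
        assert abs(abs(fit.phi[0, 1]) - 0.5) < 0.1

    def test_single_factor_passthrough_warns(self):
        lam = np.array([[0.7], [0.6]])
        with pytest.warns(UserWarning):
            pattern, phi = promax_rotate(lam, 4)
        np.testing.assert_allclose(pattern, lam)

    def test_rotation_preserves_implied_correlation(self, rng):
        x = rng.normal(size=(500, 6))
        x[:, 1] += x[:, 0]
        x[:, 4] += x[:, 3]
        r = np.corrcoef(x, rowvar=False)
        unrot = fit_efa(r, 2, rotation="none")
        rot = fit_efa(r, 2, rotation="promax")
        np.testing.assert_allclose(
            unrot.implied_correlation(), rot.implied_correlation(), atol=1e-6
        )


class TestVss:
    def test_two_factor_recovery(self):
        hits = 0
        loadings = np.zeros((8, 2))
        loadings[:4, 0] = 0.8
        loadings[4:, 1] = 0.8
        for rep in range(100):
            r_ = np.random.default_rng(rep)
            x = _oblique_factor_sample(r_, 2000, loadings, np.eye(2))
            curve, best = vss_curve(np.corrcoef(x, rowvar=False), 4)
            hits += best == 2
        assert hits >= 90

    def test_pure_noise_prefers_one_factor(self):
        hits = 0
        for rep in range(100):
            r_ = np.random.default_rng(1000 + rep)
            x = r_.normal(size=(200, 8))
            curve, best = vss_curve(np.corrcoef(x, rowvar=False), 4)
            hits += best == 1
        assert hits >= 70

    def test_curve_bounded_on_factor_data(self, rng):
        loadings = np.zeros((8, 2))
        loadings[:4, 0] = 0.7
        loadings[4:, 1] = 0.7
        x = _oblique_factor_sample(rng, 1000, loadings, np.eye(2))
        curve, _ = vss_curve(np.corrcoef(x, rowvar=False), 4)
        assert all(0.0 <= v <= 1.0 for v in curve.values())

    def test_max_nfactors_capped(self):
        with pytest.raises(ValidationError):
            vss_curve(np.eye(6), 4)


class TestComplexity:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.8, 0.0], 1.0),
            ([0.5, 0.5], 2.0),
            ([0.6, 0.3], (0.45) ** 2 / (0.1296 + 0.0081)),
        ],
    )
    def test_closed_forms(self, row, expected):
        com = complexity_scores(np.array([row]))
        np.testing.assert_allclose(com.iloc[0], expected, rtol=1e-9)

    def test_zero_row_reported_missing(self):
        with pytest.warns(UserWarning):
            com = complexity_scores(np.array([[0.0, 0.0], [0.5, 0.0]]))
        assert np.isnan(com.iloc[0]) and com.iloc[1] == 1.0

    def test_minimum_is_one(self, rng):
        lam = rng.normal(size=(20, 3))
        assert (complexity_scores(lam) >= 1.0 - 1e-12).all()


class TestAutoRotation:
    def test_correlated_components_pick_promax(self, rng):
        loadings = np.zeros((6, 2))
        loadings[:3, 0] = 0.85
        loadings[3:, 1] = 0.85
        phi = np.array([[1.0, 0.6], [0.6, 1.0]])
        x = _oblique_factor_sample(rng, 3000, loadings, phi)
        fit = fit_efa(np.corrcoef(x, rowvar=False), 2, rotation="auto")
        assert fit.rotation == "promax"

    def test_weakly_correlated_pick_varimax(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.3
        fit = fit_efa(r, 2, rotation="auto")
        assert fit.rotation == "varimax"


class TestFactorScores:
    def test_scores_correlate_with_generating_factors(self, rng):
        from microsem.efa import factor_scores

        loadings = np.zeros((8, 2))
        loadings[:4, 0] = 0.8
        loadings[4:, 1] = 0.8
        chol = np.eye(2)
        f = rng.normal(size=(1500, 2))
        u = np.sqrt(1.0 - np.diag(loadings @ loadings.T))
        x = f @ loadings.T + rng.normal(size=(1500, 8)) * u
        frame = pd.DataFrame(x, columns=[f"v{j}" for j in range(8)])
        fit = fit_efa(np.corrcoef(x, rowvar=False), 2, rotation="varimax")
        scores = factor_scores(frame, fit)
        # each generating factor is well tracked by one score column
        corr = np.corrcoef(np.column_stack([f, scores.to_numpy()]), rowvar=False)
        cross = np.abs(corr[:2, 2:])
        assert cross.max(axis=1).min() > 0.8
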