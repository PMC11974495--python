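import numpy as np
import pandas as pd
import pytest
from scipy.special import log_ndtr
from scipy.stats import ortho_group

from metasandy.jsdm import (
    JSDMFit,
    JSDMSpec,
    association_matrix,
    fit_jsdm,
    mc_probit_negloglik,
    pseudo_r2,
    trend_surface,
    wald_significance,
)


class TestTrendSurface:
    def test_scaled_columns(self, rng):
        lon = rng.uniform(3, 9, 40)
        lat = rng.uniform(51, 55, 40)
        S = trend_surface(lon, lat)
        assert list(S.columns) == ["x", "y", "x2", "y2", "xy"]
        for c in ("x", "y"):
            assert S[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert S[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_parity(self, rng):
        lon = rng.uniform(0, 1, 20)
        lat = rng.uniform(0, 1, 20)
        S1 = trend_surface(lon, lat)
        S2 = trend_surface(-lon, lat)
        assert np.allclose(S2["x"], -S1["x"])
        assert np.allclose(S2["xy"], -S1["xy"])
        assert np.allclose(S2["x2"], S1["x2"])

    def test_constant_coordinate_dropped(self, rng):
        lat = rng.uniform(0, 1, 10)
        with pytest.warns(UserWarning, match="longitude"):
            S = trend_surface(np.full(10, 4.0), lat)
        assert list(S.columns) == ["y", "y2"]


class TestLikelihood:
    def test_single_species_closed_form_any_M(self, rng):
        n = 40
        X = rng.standard_normal((n, 3))
        a = np.array([0.2])
        B = rng.standard_normal((3, 1))
        Y = (rng.random((n, 1)) < 0.5).astype(float)
        mu = a + X @ B
        exact = -float(np.sum(np.where(Y == 1, log_ndtr(mu), log_ndtr(-mu))))
        for M in (1, 7, 50):
            h = rng.standard_normal((M, 1))
            nll, _ = mc_probit_negloglik(
                a, B, np.zeros((0, 1)), np.zeros((1, 1)), Y, X, np.zeros((n, 0)), h
            )
            assert nll == pytest.approx(exact, abs=1e-10)

    def test_saturated_limit(self):
        n, S = 10, 3
        Y = np.ones((n, S))
        a = np.full(S, 30.0)
        h = np.random.default_rng(0).standard_normal((20, 1))
        nll, _ = mc_probit_negloglik(
            a,
            np.zeros((0, S)),
            np.zeros((0, S)),
            np.zeros((S, 1)),
            Y,
            np.zeros((n, 0)),
            np.zeros((n, 0)),
            h,
        )
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_mc_convergence_in_M(self, rng):
        """Doubling M changes the likelihood by < 0.1% at M = 1e4."""
        n, S, r = 10, 4, 2
        X = rng.standard_normal((n, 2))
        a = rng.normal(0, 0.5, S)
        B = rng.standard_normal((2, S))
        L = 0.8 * rng.standard_normal((S, r))
        Y = (rng.random((n, S)) < 0.5).astype(float)
        h = rng.standard_normal((20_000, r))
        nll1, _ = mc_probit_negloglik(a, B, np.zeros((0, S)), L, Y, X, np.zeros((n, 0)), h[:10_000])
        nll2, _ = mc_probit_negloglik(a, B, np.zeros((0, S)), L, Y, X, np.zeros((n, 0)), h)
        assert abs(nll2 - nll1) / nll1 < 1e-3

    def test_rotation_invariance_of_loadings(self, rng):
        n, S, r = 15, 5, 3
        X = rng.standard_normal((n, 2))
        a = np.zeros(S)
        B = rng.standard_normal((2, S))
        L = rng.standard_normal((S, r))
        Q = ortho_group.rvs(r, random_state=1)
        Y = (rng.random((n, S)) < 0.5).astype(float)
        h = rng.standard_normal((5000, r))
        # same Sigma => same distribution; with rotated common draws h Q the
        # simulated likelihood values agree draw for draw
        nll1, _ = mc_probit_negloglik(a, B, np.zeros((0, S)), L, Y, X, np.zeros((n, 0)), h)
        nll2, _ = mc_probit_negloglik(a, B, np.zeros((0, S)), L @ Q, Y, X, np.zeros((n, 0)), h @ Q)
        assert nll1 == pytest.approx(nll2, abs=1e-8)
        S1 = L @ L.T + np.eye(S)
        S2 = (L @ Q) @ (L @ Q).T + np.eye(S)
        assert np.allclose(S1, S2)

    def test_nonfinite_parameters_raise(self, rng):
        with pytest.raises(FloatingPointError):
            mc_probit_negloglik(
                np.array([np.nan]),
                np.zeros((0, 1)),
                np.zeros((0, 1)),
                np.zeros((1, 1)),
                np.zeros((3, 1)),
                np.zeros((3, 0)),
                np.zeros((3, 0)),
                np.zeros((5, 1)),
            )


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    n, S, r = 120, 8, 2
    X = rng.standard_normal((n, 3))
    a = rng.normal(0, 0.3, S)
    B = rng.standard_normal((3, S))
    L = 0.8 * rng.standard_normal((S, r))
    Y = ((a + X @ B + rng.standard_normal((n, r)) @ L.T + rng.standard_normal((n, S))) > 0).astype(float)
    spec = JSDMSpec(mc_samples=50, rank=r, iterations=200, seed=0, mc_samples_report=2000)
    return fit_jsdm(Y, X, None, spec), Y, B


@pytest.fixture(scope="module")
def strong_pair_fit():
    """Two species driven by one strong shared loading plus bystanders."""
    rng = np.random.default_rng(3)
    n, S = 300, 8
    L_true = np.zeros((S, 1))
    L_true[0, 0] = L_true[1, 0] = 2.5
    X = rng.standard_normal((n, 2))
    Y = (
        (rng.standard_normal((n, 1)) @ L_true.T + rng.standard_normal((n, S))) > 0
    ).astype(float)
    spec = JSDMSpec(mc_samples=50, rank=2, iterations=200, seed=1, mc_samples_report=1000)
    return fit_jsdm(Y, X, None, spec)


class TestFit:

    def test_loss_decreases(self, fitted):
        fit, _, _ = fitted
        assert fit.loss_path[-1] <= fit.loss_path[0]

    def test_correlation_matrix_valid(self, fitted):
        fit, _, _ = fitted
        R = fit.correlation
        assert np.allclose(np.diag(R), 1.0)
        assert np.abs(R).max() <= 1.0 + 1e-12
        assert np.linalg.eigvalsh(R).min() > -1e-10
        assert np.allclose(R, R.T)

    def test_coefficients_recovered_in_direction(self, fitted):
        fit, _, B = fitted
        assert np.corrcoef(B.ravel(), fit.B.ravel())[0, 1] > 0.8

    def test_rank_exceeds_species_raises(self, rng):
        Y = (rng.random((10, 3)) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank"):
            fit_jsdm(Y, rng.standard_normal((10, 2)), None, JSDMSpec(rank=5, iterations=2))

    def test_nonbinary_y_raises(self, rng):
        with pytest.raises(ValueError, match="binary"):
            fit_jsdm(
                rng.random((10, 3)), rng.standard_normal((10, 2)), None, JSDMSpec(iterations=2)
            )


class TestWald:
    def _make_fit(self, coef, se):
        fit = JSDMFit(
            intercepts=np.zeros(1),
            B=np.array([[coef]]),
            G=np.zeros((0, 1)),
            L=np.zeros((1, 1)),
            env_names=["x"],
            spatial_names=[],
            species=["sp"],
            log_likelihood=0.0,
            loglik_per_site=np.zeros(1),
            se_intercepts=np.array([1.0]),
            se_B=np.array([[se]]),
            se_G=np.zeros((0, 1)),
        )
        return fit

    def test_zero_coefficient(self):
        w = wald_significance(self._make_fit(0.0, 1.0))
        assert w.z.iloc[0] == 0.0
        assert w.p.iloc[0] == 1.0

    def test_halved_se_doubles_z(self):
        z1 = wald_significance(self._make_fit(0.7, 1.0)).z.iloc[0]
        z2 = wald_significance(self._make_fit(0.7, 0.5)).z.iloc[0]
        assert z2 == pytest.approx(2 * z1)

    def test_star_codes(self):
        w = wald_significance(self._make_fit(4.0, 1.0))
        assert w.stars.iloc[0] == "***"


class TestAssociations:
    def test_tail_fraction_and_shape(self, strong_pair_fit):
        A = association_matrix(strong_pair_fit, tail=0.025)
        vals = A.to_numpy()
        assert np.allclose(np.diag(vals), 1.0)
        assert np.allclose(vals, vals.T, equal_nan=True)
        off = vals[~np.eye(len(A), dtype=bool)]
        frac = np.isfinite(off).mean()
        assert frac == pytest.approx(0.05, abs=0.04)

    def test_planted_pair_retained_positive(self, strong_pair_fit):
        A = association_matrix(strong_pair_fit, tail=0.025)
        assert A.iloc[0, 1] > 0.3

    def test_group_ordering(self, strong_pair_fit):
        groups = pd.Series(
            ["b", "a", "b", "a", "b", "a", "b", "a"], index=strong_pair_fit.species
        )
        A = association_matrix(strong_pair_fit, groups=groups)
        labels = groups.loc[list(A.index)].to_numpy()
        assert (np.sort(np.where(labels == "a")[0]) < np.where(labels == "b")[0].min()).all()


class TestPseudoR2:
    def test_null_model_zero(self, rng):
        Y = (rng.random((50, 4)) < 0.4).astype(float)
        from metasandy.jsdm import _null_loglik

        ll_null, per_site = _null_loglik(Y)
        fit = JSDMFit(
            intercepts=np.zeros(4),
            B=np.zeros((0, 4)),
            G=np.zeros((0, 4)),
            L=np.zeros((4, 1)),
            env_names=[],
            spatial_names=[],
            species=list("abcd"),
            log_likelihood=ll_null,
            loglik_per_site=per_site,
        )
        assert pseudo_r2(fit, Y)["mcfadden"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_model_approaches_one(self, rng):
        Y = (rng.random((50, 4)) < 0.4).astype(float)
        fit = JSDMFit(
            intercepts=np.zeros(4),
            B=np.zeros((0, 4)),
            G=np.zeros((0, 4)),
            L=np.zeros((4, 1)),
            env_names=[],
            spatial_names=[],
            species=list("abcd"),
            log_likelihood=-1e-9,
            loglik_per_site=np.zeros(50),
        )
        assert pseudo_r2(fit, Y)["mcfadden"] == pytest.approx(1.0, abs=1e-9)
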