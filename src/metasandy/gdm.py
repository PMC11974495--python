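"""Generalised Dissimilarity Modelling (GDM).

GDM regresses pairwise compositional dissimilarity d_ij on between-site
differences of monotone I-spline transforms of the predictors through a
negative-exponential link:

    eta_ij = alpha + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|
    dhat_ij = 1 - exp(-eta_ij),    alpha >= 0, beta_pk >= 0

and minimises the binomial-type deviance

    D = sum_ij 2 [ d ln(d/dhat) + (1-d) ln((1-d)/(1-dhat)) ]

with the 0*ln 0 = 0 convention. Non-negative coefficients make every
partial turnover curve f_p(x) = sum_k beta_pk I_pk(x) non-decreasing, so
the curve's total rise (the sum of spline coefficients) measures the
predictor's importance for community turnover. Geographic distance enters
through its own I-spline basis evaluated on the pairwise km distance
itself rather than on a difference of site values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

_EPS = 1e-9


def jaccard_matrix(pa: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Jaccard dissimilarity d = 1 - |A∩B| / |A∪B| on presences."""
    X = pa.to_numpy() if isinstance(pa, pd.DataFrame) else np.asarray(pa)
    X = X.astype(bool)
    empty = np.where(~X.any(axis=1))[0]
    if len(empty) > 0:
        names = (
            [pa.index[i] for i in empty] if isinstance(pa, pd.DataFrame) else list(empty)
        )
        raise ValueError(f"site(s) with zero OTUs: {names}")
    return squareform(pdist(X, metric="jaccard"))


class ISplineBasis:
    """Monotone I-spline basis on the observed range of one predictor.

    Each of the K basis functions is 0 at the predictor minimum, 1 at the
    maximum and non-decreasing in between. Built as right partial sums of
    a degree-2 B-spline basis (degree 1 when K == 1) with interior knots
    at quantiles of the observed values — K = 3 puts the single interior
    knot at the median, i.e. knots at the 0/50/100 percentiles.
    """

    def __init__(self, values: np.ndarray, K: int = 3):
        values = np.asarray(values, dtype=float)
        if np.unique(values).size < max(K, 2):
            raise ValueError("predictor has too few distinct values")
        self.K = K
        self.lo = float(values.min())
        self.hi = float(values.max())
        degree = 1 if K == 1 else 2
        n_interior = K - degree
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(values, qs)
        else:
            interior = np.array([])
        self.knots = np.concatenate(
            [[self.lo] * (degree + 1), interior, [self.hi] * (degree + 1)]
        )
        self.degree = degree

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the K monotone basis functions; clamps outside the range."""
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        dm = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        # right partial sums of the B-spline partition of unity rise 0 -> 1
        out = np.cumsum(dm[:, ::-1], axis=1)[:, ::-1][:, 1:]
        return np.clip(out, 0.0, 1.0)


def ispline_basis(values: np.ndarray, K: int = 3) -> tuple[ISplineBasis, np.ndarray]:
    """Construct the basis and evaluate it at the supplied values."""
    basis = ISplineBasis(values, K=K)
    return basis, basis(values)


@dataclass
class GDMFit:
    intercept: float
    coefficients: dict  # predictor -> array of K non-negative spline coefficients
    bases: dict  # predictor -> ISplineBasis
    null_deviance: float
    model_deviance: float
    pct_deviance_explained: float
    n_pairs: int
    converged: bool
    deviance_path: list = field(default_factory=list)

    def importance(self) -> pd.Series:
        """Sum of spline coefficients per predictor, sorted descending."""
        s = pd.Series({p: float(c.sum()) for p, c in self.coefficients.items()})
        return s.sort_values(ascending=False)


def _deviance_and_grad(theta, Z, d):
    eta = Z @ theta
    dhat = 1.0 - np.exp(-eta)
    dhat_c = np.clip(dhat, _EPS, 1.0 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / dhat_c), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - dhat_c)), 0.0)
    dev = 2.0 * float(np.sum(t1 + t2))
    # d(dev)/d(eta); d(dhat)/d(eta) = exp(-eta) = 1 - dhat
    ddev_ddhat = 2.0 * ((1.0 - d) / (1.0 - dhat_c) - d / dhat_c)
    grad = Z.T @ (ddev_ddhat * (1.0 - dhat))
    return dev, grad


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _build_design(
    env: pd.DataFrame | None,
    geo: np.ndarray | None,
    K: int,
    bases: dict | None = None,
) -> tuple[np.ndarray, dict, list, int]:
    """Pairwise GDM design: intercept column + K spline-difference columns
    per predictor (geographic distance gets its basis on the distances)."""
    if env is None and geo is None:
        raise ValueError("need environmental predictors and/or a geo matrix")
    n = env.shape[0] if env is not None else geo.shape[0]
    ii, jj = _pair_index(n)
    cols = [np.ones(len(ii))]
    names: list[str] = []
    fit_bases = {} if bases is None else bases
    if env is not None:
        for p in env.columns:
            vals = env[p].to_numpy(dtype=float)
            if bases is None:
                fit_bases[p] = ISplineBasis(vals, K=K)
            I = fit_bases[p](vals)
            cols.append(np.abs(I[ii] - I[jj]))
            names.append(p)
    if geo is not None:
        dists = geo[ii, jj]
        if bases is None:
            fit_bases["geographic_distance"] = ISplineBasis(dists, K=K)
        cols.append(fit_bases["geographic_distance"](dists))
        names.append("geographic_distance")
    Z = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
    return Z, fit_bases, names, n


def fit_gdm(
    d: np.ndarray,
    env: pd.DataFrame | None = None,
    geo: np.ndarray | None = None,
    K: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> GDMFit:
    """Fit the GDM by bound-constrained deviance minimisation.

    The exact deviance objective and its analytic gradient are minimised
    with L-BFGS-B under alpha, beta >= 0. The null deviance comes from the
    intercept-only model fitted the same way.
    """
    d = np.asarray(d, dtype=float)
    Z, bases, names, n = _build_design(env, geo, K)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix does not match predictor sites")
    ii, jj = _pair_index(n)
    dv = d[ii, jj]
    if np.any(dv < 0) or np.any(dv > 1):
        raise ValueError("dissimilarities must lie in [0, 1]")

    path: list[float] = []

    def track(theta):
        path.append(_deviance_and_grad(theta, Z, dv)[0])

    x0 = np.zeros(Z.shape[1])
    x0[0] = max(-np.log(1.0 - np.clip(dv.mean(), _EPS, 1 - _EPS)), _EPS)
    res = minimize(
        _deviance_and_grad,
        x0,
        args=(Z, dv),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * Z.shape[1],
        callback=track,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(
            f"GDM did not converge: {res.message} (|grad| = {np.linalg.norm(res.jac):.3g})"
        )
    # intercept-only null model on the same objective
    Z0 = np.ones((len(dv), 1))
    res0 = minimize(
        _deviance_and_grad,
        x0[:1],
        args=(Z0, dv),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)],
        options={"maxiter": max_iter, "ftol": tol},
    )
    null_dev = float(res0.fun)
    model_dev = float(res.fun)
    coefs = {}
    pos = 1
    for p in names:
        coefs[p] = np.maximum(res.x[pos : pos + K], 0.0)
        pos += K
    pct = 100.0 * (1.0 - model_dev / null_dev) if null_dev > 0 else 0.0
    return GDMFit(
        intercept=float(res.x[0]),
        coefficients=coefs,
        bases=bases,
        null_deviance=null_dev,
        model_deviance=model_dev,
        pct_deviance_explained=float(np.clip(pct, 0.0, 100.0)),
        n_pairs=len(dv),
        converged=bool(res.success),
        deviance_path=path,
    )


def gdm_transform_and_importance(
    fit: GDMFit, n_grid: int = 200
) -> tuple[pd.DataFrame, pd.Series]:
    """Partial turnover curves f_p(x) = sum_k beta_pk I_pk(x) on a grid,
    plus the per-predictor coefficient sums (importance), ranked."""
    rows = []
    for p, basis in fit.bases.items():
        grid = np.linspace(basis.lo, basis.hi, n_grid)
        f = basis(grid) @ fit.coefficients[p]
        rows.append(
            pd.DataFrame({"predictor": p, "x": grid, "partial_distance": f})
        )
    return pd.concat(rows, ignore_index=True), fit.importance()


def gdm_predict(
    fit: GDMFit,
    env_i: pd.DataFrame | None = None,
    env_j: pd.DataFrame | None = None,
    geo_km: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted dissimilarity for site pairs given their covariates.

    Covariate values outside the training range are clamped to it with a
    warning (the spline transform is undefined beyond its knots).
    """
    n = len(env_i) if env_i is not None else len(np.atleast_1d(geo_km))
    eta = np.full(n, fit.intercept, dtype=float)
    for p, basis in fit.bases.items():
        if p == "geographic_distance":
            if geo_km is None:
                raise ValueError("fit used geographic distance: pass geo_km")
            x = np.atleast_1d(np.asarray(geo_km, dtype=float))
            if np.any(x < basis.lo) or np.any(x > basis.hi):
                warnings.warn(f"clamping {p} to training range", stacklevel=2)
            eta += basis(x) @ fit.coefficients[p]
        else:
            xi = env_i[p].to_numpy(dtype=float)
            xj = env_j[p].to_numpy(dtype=float)
            for x in (xi, xj):
                if np.any(x < basis.lo) or np.any(x > basis.hi):
                    warnings.warn(f"clamping {p} to training range", stacklevel=2)
            eta += np.abs(basis(xi) - basis(xj)) @ fit.coefficients[p]
    return 1.0 - np.exp(-eta)
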