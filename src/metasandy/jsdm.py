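"""Scalable joint species distribution model (JSDM): a multivariate probit
for presence/absence communities with linear environmental responses, a
second-order spatial trend surface, and a low-rank latent covariance that
captures residual species co-occurrence ("biotic association").

Model. For site i and species j,

    y_ij = 1{ a_j + (X B)_ij + (S G)_ij + (L h_i)_j + eps_ij > 0 }

with h_i ~ N(0, I_r), eps_ij ~ N(0, 1), so that conditionally on h the
species are independent probits and the residual covariance on the latent
scale is Sigma = L L^T + I. The marginal likelihood integrates h out; it
is approximated by Monte Carlo with M draws shared across iterations
(common random numbers), which makes the objective a smooth deterministic
function of the parameters:

    loglik = sum_i log (1/M) sum_m prod_j Phi((2 y_ij - 1)(mu_ij + (L h_m)_j))

Optimisation is Adam with a reduce-on-plateau learning-rate scheduler.
Reported quantities follow community-ecology practice: the species
correlation matrix R = D^{-1/2} Sigma D^{-1/2}, Wald tests for the fixed
effects, McFadden (and Nagelkerke) pseudo-R^2 against the intercept-only
model, and the sparsified association matrix keeping only the extreme
tails of the off-diagonal correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import norm

log = logging.getLogger(__name__)

_CLIP = 1e-10


def trend_surface(lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
    """Second-order polynomial spatial design on z-scored coordinates.

    Columns (x, y, x^2, y^2, xy). A constant coordinate is dropped (with
    its powers and the interaction) with a warning.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    cols = {}
    sx, sy = lon.std(ddof=0), lat.std(ddof=0)
    have_x = sx > 0
    have_y = sy > 0
    if not have_x:
        warnings.warn("longitude is constant: its trend-surface columns dropped")
    if not have_y:
        warnings.warn("latitude is constant: its trend-surface columns dropped")
    if have_x:
        x = (lon - lon.mean()) / sx
        cols["x"] = x
        cols["x2"] = x**2
    if have_y:
        y = (lat - lat.mean()) / sy
        cols["y"] = y
        cols["y2"] = y**2
    if have_x and have_y:
        cols["xy"] = cols["x"] * cols["y"]
    if not cols:
        raise ValueError("both coordinates constant: no spatial design")
    return pd.DataFrame(cols, columns=["x", "y", "x2", "y2", "xy"][: len(cols)] if (have_x and have_y) else list(cols))


@dataclass
class JSDMSpec:
    """Fitting configuration.

    mc_samples is the number of Monte-Carlo draws used during optimisation;
    mc_samples_report is used for the final reported log-likelihood. rank
    defaults to ceil(S/2) when None.
    """

    mc_samples: int = 100
    rank: int | None = None
    iterations: int = 500
    learning_rate: float = 0.05
    patience: int = 10
    reduce_factor: float = 0.9
    mc_samples_report: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.mc_samples < 1 or self.iterations < 1:
            raise ValueError("mc_samples and iterations must be >= 1")
        if not 0.0 < self.reduce_factor < 1.0:
            raise ValueError("reduce_factor must lie in (0, 1)")


@dataclass
class JSDMFit:
    intercepts: np.ndarray  # (S,)
    B: np.ndarray  # (K_env, S)
    G: np.ndarray  # (P_spatial, S)
    L: np.ndarray  # (S, r)
    env_names: list
    spatial_names: list
    species: list
    log_likelihood: float  # at mc_samples_report draws
    loglik_per_site: np.ndarray  # (n,)
    loss_path: list = field(default_factory=list)
    se_intercepts: np.ndarray | None = None
    se_B: np.ndarray | None = None
    se_G: np.ndarray | None = None
    spec: JSDMSpec | None = None

    @property
    def sigma(self) -> np.ndarray:
        """Latent-scale residual covariance Sigma = L L^T + I."""
        return self.L @ self.L.T + np.eye(self.L.shape[0])

    @property
    def correlation(self) -> np.ndarray:
        """Sigma normalised to a correlation matrix."""
        s = self.sigma
        d = np.sqrt(np.diag(s))
        return s / np.outer(d, d)


def _unpack(theta, n_env, n_spat, S, r):
    pos = 0
    a = theta[pos : pos + S]
    pos += S
    B = theta[pos : pos + n_env * S].reshape(n_env, S)
    pos += n_env * S
    G = theta[pos : pos + n_spat * S].reshape(n_spat, S)
    pos += n_spat * S
    L = theta[pos:].reshape(S, r)
    return a, B, G, L


def mc_probit_negloglik(
    a: np.ndarray,
    B: np.ndarray,
    G: np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    X: np.ndarray,
    S_design: np.ndarray,
    h: np.ndarray,
    grad: bool = False,
):
    """Monte-Carlo negative log-likelihood (and optionally its gradient).

    ``h`` is the fixed (M, r) matrix of latent draws — passing the same
    draws across calls gives a deterministic smooth objective.
    """
    if not (np.isfinite(a).all() and np.isfinite(B).all() and np.isfinite(L).all()):
        raise FloatingPointError("non-finite parameters")
    n, S = Y.shape
    M = h.shape[0]
    sign = 2.0 * Y - 1.0  # (n, S)
    mu = a[None, :] + X @ B + (S_design @ G if S_design.size else 0.0)  # (n, S)
    if not grad:
        # chunk over draws to bound memory; logsumexp accumulated per site
        chunk = max(1, int(2e7 // max(n * S, 1)))
        ll_parts = []
        for start in range(0, M, chunk):
            lat = h[start : start + chunk] @ L.T
            z = sign[None, :, :] * (mu[None, :, :] + lat[:, None, :])
            ll_parts.append(log_ndtr(z).sum(axis=2))
        ll_m = np.concatenate(ll_parts, axis=0)  # (M, n)
        ll_max = ll_m.max(axis=0)
        site_ll = ll_max + np.log(np.exp(ll_m - ll_max[None, :]).mean(axis=0))
        return -float(site_ll.sum()), site_ll
    lat = h @ L.T  # (M, S)
    z = sign[None, :, :] * (mu[None, :, :] + lat[:, None, :])  # (M, n, S)
    logphi = log_ndtr(z)
    ll_m = logphi.sum(axis=2)  # (M, n) log prod_j Phi
    ll_max = ll_m.max(axis=0)
    w_un = np.exp(ll_m - ll_max[None, :])
    site_ll = ll_max + np.log(w_un.mean(axis=0))  # (n,)
    nll = -float(site_ll.sum())
    w = w_un / w_un.sum(axis=0, keepdims=True)  # (M, n) softmax weights
    # inverse Mills ratio phi(z)/Phi(z), numerically via logs
    mills = np.exp(-0.5 * z * z - 0.9189385332046727 - logphi)
    core = w[:, :, None] * sign[None, :, :] * mills  # (M, n, S)
    d_mu = core.sum(axis=0)  # (n, S)
    g_a = -d_mu.sum(axis=0)
    g_B = -X.T @ d_mu
    g_G = -S_design.T @ d_mu if S_design.size else np.zeros_like(G)
    g_L = -np.einsum("mns,mr->sr", core, h)
    return nll, site_ll, (g_a, g_B, g_G, g_L)


def _null_loglik(Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact intercept-only (independent Bernoulli-probit) log-likelihood."""
    p = Y.mean(axis=0)
    p = np.clip(p, _CLIP, 1 - _CLIP)
    per_site = (Y * np.log(p)[None, :] + (1 - Y) * np.log(1 - p)[None, :]).sum(axis=1)
    return float(per_site.sum()), per_site


def fit_jsdm(
    Y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    S_design: np.ndarray | pd.DataFrame | None,
    spec: JSDMSpec,
    compute_se: bool = True,
) -> JSDMFit:
    """Fit the model by Adam on the Monte-Carlo likelihood.

    The learning rate is multiplied by ``reduce_factor`` whenever the loss
    has not improved for ``patience`` consecutive iterations (plateau
    scheduler). The final reported log-likelihood re-evaluates the fitted
    parameters with ``mc_samples_report`` fresh draws.
    """
    species = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"sp{j}" for j in range(np.asarray(Y).shape[1])]
    env_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{k}" for k in range(np.asarray(X).shape[1])]
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if S_design is None:
        Sv = np.zeros((Yv.shape[0], 0))
        spatial_names: list = []
    else:
        spatial_names = list(S_design.columns) if isinstance(S_design, pd.DataFrame) else [f"s{k}" for k in range(np.asarray(S_design).shape[1])]
        Sv = np.asarray(S_design, dtype=float)
    if not np.isin(Yv, [0.0, 1.0]).all():
        raise ValueError("Y must be binary")
    n, S = Yv.shape
    r = spec.rank if spec.rank is not None else int(np.ceil(S / 2))
    if r > S:
        raise ValueError(f"latent rank {r} exceeds number of species {S}")

    rng = np.random.default_rng(spec.seed)
    h = rng.standard_normal((spec.mc_samples, r)) if r > 0 else np.zeros((spec.mc_samples, 0))

    a = ndtri(np.clip(Yv.mean(axis=0), 0.01, 0.99))
    B = np.zeros((Xv.shape[1], S))
    G = np.zeros((Sv.shape[1], S))
    L = 0.01 * rng.standard_normal((S, r))
    params = [a, B, G, L]

    # Adam state
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    best = np.inf
    stall = 0
    path = []
    for t in range(1, spec.iterations + 1):
        nll, _, grads = mc_probit_negloglik(*params, Yv, Xv, Sv, h, grad=True)
        if not np.isfinite(nll):
            raise RuntimeError("loss diverged (NaN/inf); try a smaller learning rate")
        path.append(nll)
        if nll < best - 1e-7:
            best = nll
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                lr *= spec.reduce_factor
                stall = 0
        for k, g in enumerate(grads):
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1**t)
            vhat = v[k] / (1 - b2**t)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
    a, B, G, L = params

    h_rep = rng.standard_normal((spec.mc_samples_report, r)) if r > 0 else np.zeros((1, 0))
    nll_rep, site_ll = mc_probit_negloglik(a, B, G, L, Yv, Xv, Sv, h_rep)
    fit = JSDMFit(
        intercepts=a,
        B=B,
        G=G,
        L=L,
        env_names=env_names,
        spatial_names=spatial_names,
        species=species,
        log_likelihood=-nll_rep,
        loglik_per_site=site_ll,
        loss_path=path,
        spec=spec,
    )
    if compute_se:
        _attach_standard_errors(fit, Yv, Xv, Sv)
    return fit


def _attach_standard_errors(fit: JSDMFit, Y, X, Sv) -> None:
    """Observed-information SEs for (intercepts, B, G), per species.

    Profile approximation: the latent loadings are held fixed and each
    species' marginal success probability Phi(mu_j / c_j), with
    c_j = sqrt(1 + ||L_j||^2), yields a probit-GLM information matrix for
    that species' fixed effects on the latent (unattenuated) scale.
    """
    n, S = Y.shape
    D = np.column_stack([np.ones(n), X, Sv]) if Sv.size else np.column_stack([np.ones(n), X])
    P = D.shape[1]
    c = np.sqrt(1.0 + (fit.L**2).sum(axis=1))
    mu = fit.intercepts[None, :] + X @ fit.B + (Sv @ fit.G if Sv.size else 0.0)
    se = np.full((P, S), np.nan)
    rank_deficient = np.linalg.matrix_rank(D) < P
    if rank_deficient:
        # e.g. exactly collinear coordinates in the trend surface; the
        # pseudo-inverse gives SEs for the estimable directions only
        log.warning(
            "fixed-effect design is rank deficient (%d < %d); "
            "standard errors use the pseudo-inverse",
            np.linalg.matrix_rank(D),
            P,
        )
    for j in range(S):
        zj = mu[:, j] / c[j]
        pj = np.clip(ndtr(zj), _CLIP, 1 - _CLIP)
        wj = norm.pdf(zj) ** 2 / (pj * (1 - pj))
        info = (D * wj[:, None]).T @ D / (c[j] ** 2)
        cov = np.linalg.pinv(info, hermitian=True)
        diag = np.diag(cov)
        valid = diag > 0
        se[valid, j] = np.sqrt(diag[valid])
    fit.se_intercepts = se[0]
    fit.se_B = se[1 : 1 + X.shape[1]]
    fit.se_G = se[1 + X.shape[1] :]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wald_significance(fit: JSDMFit) -> pd.DataFrame:
    """Wald z-tests for every environmental and spatial coefficient."""
    if fit.se_B is None:
        raise ValueError("fit has no standard errors (compute_se=False)")
    rows = []
    for block, coefs, ses, names in (
        ("environment", fit.B, fit.se_B, fit.env_names),
        ("space", fit.G, fit.se_G, fit.spatial_names),
    ):
        for k, name in enumerate(names):
            for j, sp in enumerate(fit.species):
                coef, se = coefs[k, j], ses[k, j]
                if np.isnan(se) or se == 0:
                    z, p = np.nan, np.nan
                else:
                    z = coef / se
                    p = 2.0 * norm.sf(abs(z))
                rows.append(
                    {
                        "block": block,
                        "covariate": name,
                        "species": sp,
                        "coef": coef,
                        "se": se,
                        "z": z,
                        "p": p,
                        "stars": _stars(p) if np.isfinite(p) else "",
                    }
                )
    return pd.DataFrame(rows)


def association_matrix(
    fit: JSDMFit,
    tail: float = 0.025,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Sparsified species-correlation matrix keeping only the tails.

    Off-diagonal entries of R inside the [tail, 1-tail] quantile band are
    masked to NaN; rows/columns are ordered by higher-taxon group when
    ``groups`` is given.
    """
    R = fit.correlation
    S = R.shape[0]
    order = np.arange(S)
    species = list(fit.species)
    if groups is not None:
        labels = pd.Series(groups).reindex(species).to_numpy()
        order = np.lexsort((species, labels))
    Rs = R[np.ix_(order, order)]
    names = [species[i] for i in order]
    off = Rs[~np.eye(S, dtype=bool)]
    lo, hi = np.quantile(off, [tail, 1.0 - tail])
    masked = np.where((Rs <= lo) | (Rs >= hi), Rs, np.nan)
    np.fill_diagonal(masked, 1.0)
    return pd.DataFrame(masked, index=names, columns=names)


def pseudo_r2(fit: JSDMFit, Y: np.ndarray | pd.DataFrame) -> dict:
    """McFadden and Nagelkerke pseudo-R^2 against the intercept-only model."""
    Yv = np.asarray(Y, dtype=float)
    ll_null, _ = _null_loglik(Yv)
    if ll_null == 0:
        raise ZeroDivisionError("null log-likelihood is zero")
    ll = fit.log_likelihood
    n = Yv.shape[0]
    mcfadden = 1.0 - ll / ll_null
    nagelkerke = (1.0 - np.exp(2.0 * (ll_null - ll) / n)) / (
        1.0 - np.exp(2.0 * ll_null / n)
    )
    return {
        "mcfadden": float(np.clip(mcfadden, 0.0, 1.0)),
        "nagelkerke": float(np.clip(nagelkerke, 0.0, 1.0)),
    }
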