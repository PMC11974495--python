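"""Internal-structure variation partitioning and its downstream analysis.

The explained variation of the fitted community model is decomposed, per
sampling site and per OTU, into the three assembly processes

    E — environment (species sorting along measured covariates),
    S — space (the trend-surface component, a dispersal proxy),
    C — biotic association (the latent low-rank covariance).

All 2^3 = 8 models over subsets of {E, S, C} are fitted with a shared
seed; per-site (and per-OTU) McFadden R^2 against the intercept-only
model defines a set function, and each process' partial R^2 is its
Shapley value — the average marginal R^2 gain over the 3! orders in
which the processes can enter the model. Shapley allocation is exact:
the three partials sum to the full-model R^2 (efficiency), reduce to
solo gains when processes do not overlap, and are symmetric in the
process labels. Shares are the absolute partials normalised to sum 1.

Assembly-process shares are then regressed against site-level predictors
(environmental and spatial distinctiveness, OTU richness, individual
covariates) with median (tau = 0.5) quantile regression, robust to the
skewed share distributions; p-values come from a seeded case-resampling
bootstrap.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jsdm import JSDMSpec, JSDMFit, fit_jsdm, mc_probit_negloglik, _null_loglik
from scipy.special import ndtr

log = logging.getLogger(__name__)

COMPONENTS = ("E", "S", "C")
_SUBSETS = [frozenset(c) for k in range(4) for c in itertools.combinations(COMPONENTS, k)]


@dataclass
class ComponentGrid:
    """Per-site and per-species log-likelihoods of the 8 subset models."""

    site_loglik: dict  # frozenset -> (n,) array
    species_loglik: dict  # frozenset -> (S,) array
    fits: dict  # frozenset -> JSDMFit
    sites: list
    species: list

    def site_r2(self) -> dict:
        """McFadden R^2 per site for every subset vs the empty model."""
        base = self.site_loglik[frozenset()]
        return {
            sub: 1.0 - ll / base for sub, ll in self.site_loglik.items()
        }

    def species_r2(self) -> dict:
        base = self.species_loglik[frozenset()]
        return {
            sub: 1.0 - ll / base for sub, ll in self.species_loglik.items()
        }


@dataclass
class PartitionResult:
    per_site: pd.DataFrame  # partial_E/S/C, share_E/S/C, richness, full_r2
    per_species: pd.DataFrame
    method: str = "shapley"


@dataclass
class QuantRegFit:
    tau: float
    degree: int
    coefficients: np.ndarray  # intercept first, then ascending powers
    p_values: np.ndarray  # per non-intercept coefficient (bootstrap)
    significant: bool
    n_boot: int


def _marginal_species_loglik(fit: JSDMFit, Y, X, Sv) -> np.ndarray:
    """Exact per-species marginal log-likelihood: P(y=1) = Phi(mu/c)."""
    c = np.sqrt(1.0 + (fit.L**2).sum(axis=1))
    mu = fit.intercepts[None, :] + X @ fit.B + (Sv @ fit.G if Sv.size else 0.0)
    p = np.clip(ndtr(mu / c[None, :]), 1e-10, 1 - 1e-10)
    return (Y * np.log(p) + (1 - Y) * np.log(1 - p)).sum(axis=0)


def component_loglik_grid(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    S_design: pd.DataFrame | np.ndarray,
    spec: JSDMSpec,
) -> ComponentGrid:
    """Fit the 8 subset models of {environment, space, biotic covariance}.

    Every subset shares the JSDMSpec (and seed). Excluding C removes the
    latent loadings entirely (rank 0); excluding E or S removes that
    design block. The empty subset is the exact intercept-only model.
    """
    sites = list(Y.index) if isinstance(Y, pd.DataFrame) else list(range(np.asarray(Y).shape[0]))
    species = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"sp{j}" for j in range(np.asarray(Y).shape[1])]
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    Sv = np.asarray(S_design, dtype=float)
    n, S = Yv.shape
    site_ll: dict = {}
    sp_ll: dict = {}
    fits: dict = {}
    # exact intercept-only baseline
    _, base_site = _null_loglik(Yv)
    p0 = np.clip(Yv.mean(axis=0), 1e-10, 1 - 1e-10)
    base_sp = (Yv * np.log(p0) + (1 - Yv) * np.log(1 - p0)).sum(axis=0)
    site_ll[frozenset()] = base_site
    sp_ll[frozenset()] = base_sp
    for sub in _SUBSETS:
        if not sub:
            continue
        Xs = Xv if "E" in sub else np.zeros((n, 0))
        Ss = Sv if "S" in sub else np.zeros((n, 0))
        sub_spec = dataclasses.replace(spec, rank=spec.rank if "C" in sub else 0)
        try:
            fit = fit_jsdm(Yv, Xs, Ss, sub_spec, compute_se=False)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"subset model {set(sub)} failed: {exc}") from exc
        fits[sub] = fit
        site_ll[sub] = fit.loglik_per_site
        sp_ll[sub] = _marginal_species_loglik(fit, Yv, Xs, Ss)
    return ComponentGrid(
        site_loglik=site_ll, species_loglik=sp_ll, fits=fits, sites=sites, species=species
    )


def _shapley(r2_by_subset: dict) -> dict:
    """Shapley value of each component for an arbitrary-shaped payoff."""
    partials = {}
    orders = list(itertools.permutations(COMPONENTS))
    for comp in COMPONENTS:
        total = 0.0
        for order in orders:
            before = frozenset(order[: order.index(comp)])
            total = total + (
                r2_by_subset[before | {comp}] - r2_by_subset[before]
            )
        partials[comp] = total / len(orders)
    return partials


def _unique(r2_by_subset: dict) -> dict:
    """Full-model R^2 minus the leave-one-out model (unique contribution)."""
    full = frozenset(COMPONENTS)
    return {
        comp: r2_by_subset[full] - r2_by_subset[full - {comp}] for comp in COMPONENTS
    }


def partition_r2(
    grid: ComponentGrid, method: str = "shapley", richness: np.ndarray | None = None
) -> PartitionResult:
    """Allocate per-site and per-species R^2 to E, S and C.

    Shares are |partial| / sum |partial|; a site whose partials are all
    zero is flagged (share NaN) and excluded from downstream regressions.
    """
    alloc = {"shapley": _shapley, "unique": _unique}[method]

    def table(r2_dict, index):
        rows = []
        for i in range(len(index)):
            by_subset = {sub: float(v[i]) for sub, v in r2_dict.items()}
            partials = alloc(by_subset)
            absed = {c: abs(v) for c, v in partials.items()}
            denom = sum(absed.values())
            shares = (
                {c: absed[c] / denom for c in COMPONENTS}
                if denom > 0
                else {c: np.nan for c in COMPONENTS}
            )
            if denom == 0:
                log.warning("zero partial R^2 at %s: shares undefined", index[i])
            rows.append(
                {
                    "id": index[i],
                    "full_r2": by_subset[frozenset(COMPONENTS)],
                    **{f"partial_{c}": partials[c] for c in COMPONENTS},
                    **{f"share_{c}": shares[c] for c in COMPONENTS},
                }
            )
        return pd.DataFrame(rows).set_index("id")

    per_site = table(grid.site_r2(), grid.sites)
    per_species = table(grid.species_r2(), grid.species)
    if richness is not None:
        per_site["richness"] = np.asarray(richness)
    return PartitionResult(per_site=per_site, per_species=per_species, method=method)


def _pinball(resid: np.ndarray, tau: float = 0.5) -> float:
    return float(np.sum(np.where(resid >= 0, tau * resid, (tau - 1) * resid)))


def median_quantile_regression(
    y: np.ndarray,
    x: np.ndarray,
    degree: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
) -> QuantRegFit:
    """Median (tau = 0.5) polynomial quantile regression with bootstrap
    p-values for the slope (and curvature) coefficients."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < max(degree + 3, 8):
        raise ValueError("quantile regression needs at least 8 sites")
    if x.std(ddof=0) == 0:
        raise ValueError("degenerate predictor (zero variance)")

    def design(xv):
        return np.column_stack([xv**d for d in range(degree + 1)])

    def fit_coefs(yv, xv):
        # pinball-loss minimisation as a linear programme (exact optimum):
        # min tau*1'u + (1-tau)*1'v  s.t.  X b + u - v = y,  u, v >= 0
        from scipy.optimize import linprog

        Xd = design(xv)
        m, p = Xd.shape
        c = np.r_[np.zeros(p), 0.5 * np.ones(m), 0.5 * np.ones(m)]
        A_eq = np.hstack([Xd, np.eye(m), -np.eye(m)])
        bounds = [(None, None)] * p + [(0, None)] * (2 * m)
        res = linprog(c, A_eq=A_eq, b_eq=yv, bounds=bounds, method="highs")
        if not res.success:
            raise RuntimeError(f"quantile regression LP failed: {res.message}")
        return res.x[:p]

    coefs = fit_coefs(y, x)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, degree + 1))
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots[b] = fit_coefs(y[idx], x[idx])
        except Exception:
            boots[b] = np.nan
    pvals = np.empty(degree)
    for k in range(1, degree + 1):
        bk = boots[:, k]
        bk = bk[np.isfinite(bk)]
        frac = min((bk <= 0).mean(), (bk >= 0).mean())
        pvals[k - 1] = min(1.0, 2.0 * frac)
    return QuantRegFit(
        tau=0.5,
        degree=degree,
        coefficients=np.asarray(coefs, dtype=float),
        p_values=pvals,
        significant=bool((pvals < 0.05).any()),
        n_boot=n_boot,
    )


def internal_structure_analysis(
    partition: PartitionResult,
    predictors: pd.DataFrame,
    degree: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
    value: str = "partial",
) -> pd.DataFrame:
    """Quantile-regress each component's importance on site-level predictors.

    ``value`` selects the regressed quantity: "partial" (default) uses the
    per-site partial R^2 of each assembly process — the individual sample
    R^2 values — while "share" uses the normalised shares (the axis of the
    usual stacked display). Shares are ratios and dilute a planted gradient
    whenever the other components' explained variation co-varies with it,
    so the partial R^2 is the better-behaved regression target.

    ``predictors`` is indexed like the per-site partition table, one
    column per panel (distinctiveness measures, richness, covariates).
    Returns one row per (predictor, component) with coefficients,
    bootstrap p-values and the p < 0.05 significance flag (solid vs
    dashed line in the usual display).
    """
    if value not in ("partial", "share"):
        raise ValueError("value must be 'partial' or 'share'")
    rows = []
    sites = partition.per_site
    common = sites.index.intersection(predictors.index)
    for panel in predictors.columns:
        x = predictors.loc[common, panel].to_numpy(dtype=float)
        for comp in COMPONENTS:
            yv = sites.loc[common, f"{value}_{comp}"].to_numpy(dtype=float)
            fit = median_quantile_regression(
                yv, x, degree=degree, n_boot=n_boot, seed=seed
            )
            rows.append(
                {
                    "panel": panel,
                    "component": comp,
                    **{f"beta_{d}": fit.coefficients[d] for d in range(degree + 1)},
                    **{f"p_beta_{d}": fit.p_values[d - 1] for d in range(1, degree + 1)},
                    "significant": fit.significant,
                }
            )
    return pd.DataFrame(rows)
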