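"""Environmental covariate handling: standardisation, collinearity-based
selection, geographic distances and site distinctiveness.

Covariate selection follows the two-stage protocol common in distribution
modelling: first prune pairs of covariates whose absolute Pearson
correlation exceeds ``r_max`` (default 0.7), then iteratively drop the
covariate with the largest variance inflation factor (VIF) until every
retained covariate has VIF below ``vif_max`` (default 2).

Distinctiveness summarises how unusual a site is relative to the rest of
the study: the mean distance from the site to all other sites, z-scored
across sites. Environmental distinctiveness uses Euclidean distance on
standardised covariates; spatial distinctiveness uses great-circle
distance in km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


@dataclass
class Standardisation:
    """Per-covariate mean and standard deviation used for z-scoring."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, env: pd.DataFrame) -> pd.DataFrame:
        return (env[self.mean.index] - self.mean) / self.sd


@dataclass
class SelectionReport:
    """Trace of the covariate-selection procedure."""

    dropped_by_correlation: list = field(default_factory=list)  # (name, |r|, partner)
    vif_trajectory: list = field(default_factory=list)  # list of {name: vif} per step
    dropped_by_vif: list = field(default_factory=list)  # (name, vif)
    retained: list = field(default_factory=list)
    final_vifs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_by_correlation": [
                {"column": c, "abs_r": r, "partner": p}
                for c, r, p in self.dropped_by_correlation
            ],
            "vif_trajectory": self.vif_trajectory,
            "dropped_by_vif": [{"column": c, "vif": v} for c, v in self.dropped_by_vif],
            "retained": list(self.retained),
            "final_vifs": self.final_vifs,
        }


def standardise(env: pd.DataFrame) -> tuple[pd.DataFrame, Standardisation]:
    """Z-score every column; raises on constant columns."""
    _check_no_constant(env)
    mean = env.mean()
    sd = env.std(ddof=0)
    record = Standardisation(mean=mean, sd=sd)
    return record.apply(env), record


def _check_no_constant(env: pd.DataFrame) -> None:
    sds = env.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")


def correlation_prune(
    env: pd.DataFrame, r_max: float = 0.7
) -> tuple[pd.DataFrame, SelectionReport]:
    """Greedily drop one member of every covariate pair with |r| > r_max.

    From the pair with the largest absolute Pearson correlation above the
    threshold, the member with the larger mean absolute correlation to all
    other covariates is removed; ties break in column order.
    """
    if env.shape[1] < 2:
        raise ValueError("correlation pruning needs at least 2 columns")
    _check_no_constant(env)
    report = SelectionReport()
    kept = env.copy()
    while kept.shape[1] >= 2:
        corr = kept.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.values.max()
        if max_r <= r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        # mean absolute correlation with everything else decides the victim
        mean_a = corr[a].sum() / (kept.shape[1] - 1)
        mean_b = corr[b].sum() / (kept.shape[1] - 1)
        victim, partner = (a, b) if mean_a >= mean_b else (b, a)
        report.dropped_by_correlation.append((victim, float(max_r), partner))
        kept = kept.drop(columns=[victim])
    report.retained = kept.columns.tolist()
    return kept, report


def _vifs(env: pd.DataFrame) -> dict[str, float]:
    """VIF_k = 1 / (1 - R^2_k) from regressing column k on the others."""
    X = env.to_numpy(dtype=float)
    n, p = X.shape
    out: dict[str, float] = {}
    for k, name in enumerate(env.columns):
        yk = X[:, k]
        Z = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Z, yk, rcond=None)
        resid = yk - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yk - yk.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"constant covariate column(s): ['{name}']")
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_stepwise(
    env: pd.DataFrame, vif_max: float = 2.0
) -> tuple[pd.DataFrame, SelectionReport]:
    """Iteratively drop the covariate with the largest VIF while it is >= vif_max.

    Perfect collinearity shows up as an infinite VIF and is dropped first
    rather than raising.
    """
    if env.shape[1] < 2:
        raise ValueError("VIF selection needs at least 2 columns")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more sites than covariates for VIF")
    report = SelectionReport()
    kept = env.copy()
    while kept.shape[1] >= 2:
        vifs = _vifs(kept)
        report.vif_trajectory.append({k: v for k, v in vifs.items()})
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] < vif_max:
            break
        report.dropped_by_vif.append((worst, vifs[worst]))
        kept = kept.drop(columns=[worst])
    report.retained = kept.columns.tolist()
    report.final_vifs = _vifs(kept) if kept.shape[1] >= 2 else {kept.columns[0]: 1.0}
    return kept, report


def select_covariates(
    env: pd.DataFrame, r_max: float = 0.7, vif_max: float = 2.0
) -> tuple[pd.DataFrame, SelectionReport]:
    """Correlation pruning followed by stepwise VIF selection."""
    pruned, rep1 = correlation_prune(env, r_max=r_max)
    selected, rep2 = vif_stepwise(pruned, vif_max=vif_max)
    rep2.dropped_by_correlation = rep1.dropped_by_correlation
    return selected, rep2


def geo_distance_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Haversine great-circle distance matrix in km (R = 6371 km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude outside [-180, 180]")
    rlon, rlat = np.radians(lon), np.radians(lat)
    dlat = rlat[:, None] - rlat[None, :]
    dlon = rlon[:, None] - rlon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(rlat)[:, None] * np.cos(rlat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def distinctiveness(
    features: np.ndarray | pd.DataFrame | None = None,
    distance_matrix: np.ndarray | None = None,
    method: str = "mean_distance",
) -> np.ndarray:
    """Per-site distinctiveness, z-scored across sites.

    Either a site x feature matrix (Euclidean distances are computed) or a
    precomputed site x site distance matrix must be given.

    method="mean_distance" (default): mean distance to all other sites.
    method="centroid": Euclidean distance to the feature centroid
    (feature input only).
    """
    if (features is None) == (distance_matrix is None):
        raise ValueError("give exactly one of features or distance_matrix")
    if method == "centroid":
        if features is None:
            raise ValueError("centroid method needs a feature matrix")
        X = np.asarray(features, dtype=float)
        raw = np.linalg.norm(X - X.mean(axis=0), axis=1)
    else:
        if distance_matrix is not None:
            D = np.asarray(distance_matrix, dtype=float)
        else:
            from scipy.spatial.distance import pdist, squareform

            D = squareform(pdist(np.asarray(features, dtype=float)))
        n = D.shape[0]
        if n < 3:
            raise ValueError("distinctiveness needs at least 3 sites")
        raw = D.sum(axis=1) / (n - 1)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("all sites identical: distinctiveness is degenerate")
    return (raw - raw.mean()) / sd
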