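"""Synthetic sandy-beach metacommunity generator.

Emulates the study design the downstream models assume: beaches spread
along a ~650 km stretch of coastline, three parallel transects per beach
with eight tidal levels each (dune foot = 100% distance from low tide,
low-tide line = 0%), beach-level environmental covariates with
along-coast autocorrelation, presence/absence communities drawn from a
probit model with linear environmental responses, a smooth spatial trend
and a low-rank latent covariance, and finally noisy read-count tables
with log-normal sequencing depth, sub-threshold contamination reads and
a fraction of low-depth samples — exactly the artefacts the
post-clustering filters are designed to remove.

Group labels for the simulated OTUs follow the observed composition of
sandy-beach meiofauna communities (Nematoda and Copepoda dominating,
down to singleton groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import standardise
from .jsdm import trend_surface

#: higher-taxon composition used for simulated taxonomy (observed counts
#: in a 127-OTU sandy-beach meiofauna community)
GROUP_COMPOSITION = {
    "Nematoda": 42,
    "Copepoda": 21,
    "Clitellata": 16,
    "Polychaeta": 12,
    "Gastrotricha": 9,
    "Platyhelminthes": 8,
    "Acoela": 7,
    "Collembola": 4,
    "Rotifera": 3,
    "Branchiopoda": 2,
    "Nemertea": 1,
    "Tardigrada": 1,
    "Arachnida": 1,
}

ENV_COVARIATES = [
    "grain_size",
    "dist_low_tide",
    "spring_tide_range",
    "beach_slope",
    "salinity",
    "annual_temp",
]

#: affine maps from unit-variance latent fields to field-realistic units
_ENV_SCALES = {
    "grain_size": (300.0, 80.0),  # μm
    "spring_tide_range": (2.5, 0.8),  # m
    "beach_slope": (3.0, 1.5),  # degrees
    "salinity": (30.0, 1.5),  # PSS
    "annual_temp": (10.0, 0.7),  # °C
}

# coastline endpoints: straight segment roughly Zeeland -> Sylt
_COAST_START = (3.5, 51.5)  # lon, lat
_COAST_END = (8.5, 55.0)
COAST_LENGTH_KM = 650.0


@dataclass
class SimulationConfig:
    """Study-design and noise parameters; the defaults are the field
    study's conditions (24 beaches x 3 transects x 8 tidal levels,
    127 OTUs, ~2% low-depth samples)."""

    n_beaches: int = 24
    n_transects: int = 3
    n_levels: int = 8
    n_species: int = 127
    effect_scale: float = 1.0
    spatial_scale: float = 0.0
    loading_scale: float = 0.7
    rank: int = 5
    env_range_km: float = 100.0
    depth_log_mean: float = float(np.log(20_000.0))
    depth_log_sd: float = 0.6
    contamination_rate: float = 0.01
    low_depth_fraction: float = 0.02
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_beaches", "n_transects", "n_levels", "n_species"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("contamination_rate", "low_depth_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rank < 0 or self.rank > self.n_species:
            raise ValueError("rank must lie in [0, n_species]")


@dataclass
class LatentCommunityParams:
    """Generative twin of the JSDM parameters."""

    intercepts: np.ndarray  # (S,)
    B: np.ndarray  # (n_env, S) environmental coefficients
    G: np.ndarray  # (5, S) trend-surface coefficients
    L: np.ndarray  # (S, rank) latent loadings
    rank: int

    def sigma(self) -> np.ndarray:
        S = self.L.shape[0]
        return self.L @ self.L.T + np.eye(S)

    def correlation(self) -> np.ndarray:
        s = self.sigma()
        d = np.sqrt(np.diag(s))
        return s / np.outer(d, d)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercepts": self.intercepts.tolist(),
                "B": self.B.tolist(),
                "G": self.G.tolist(),
                "L": self.L.tolist(),
                "rank": self.rank,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LatentCommunityParams":
        d = json.loads(text)
        return cls(
            intercepts=np.asarray(d["intercepts"]),
            B=np.asarray(d["B"]),
            G=np.asarray(d["G"]),
            L=np.asarray(d["L"]),
            rank=int(d["rank"]),
        )


def _gp_along_coast(positions_km, range_km, rng):
    """Zero-mean unit-variance Gaussian process with exponential kernel."""
    d = np.abs(positions_km[:, None] - positions_km[None, :])
    K = np.exp(-d / range_km) + 1e-9 * np.eye(len(positions_km))
    return np.linalg.cholesky(K) @ rng.standard_normal(len(positions_km))


def generate_design(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """One row per physical sample; beaches equidistant along the coast.

    Beach-level covariates are draws from an along-coast Gaussian process
    (exponential covariance, range ``env_range_km``), mapped to realistic
    units; ``dist_low_tide`` runs equidistantly from 100 (dune foot,
    tidal level 1) down to 0 (low-tide line) within every transect.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    # irregular beach spacing (real coastlines cluster): sorted uniform
    # positions, endpoints pinned so the full extent is always covered
    if config.n_beaches > 2:
        interior = np.sort(rng.uniform(0.0, COAST_LENGTH_KM, config.n_beaches - 2))
        pos = np.concatenate([[0.0], interior, [COAST_LENGTH_KM]])
    else:
        pos = np.linspace(0.0, COAST_LENGTH_KM, config.n_beaches)
    frac = pos / COAST_LENGTH_KM
    lon = _COAST_START[0] + frac * (_COAST_END[0] - _COAST_START[0])
    lat = _COAST_START[1] + frac * (_COAST_END[1] - _COAST_START[1])
    beach_env = {
        name: mu + sd * _gp_along_coast(pos, config.env_range_km, rng)
        for name, (mu, sd) in _ENV_SCALES.items()
    }
    beach_env["grain_size"] = np.maximum(beach_env["grain_size"], 50.0)
    if config.n_levels > 1:
        dist = np.linspace(100.0, 0.0, config.n_levels)
    else:
        dist = np.array([0.0])
    rows = []
    for b in range(config.n_beaches):
        for t in range(1, config.n_transects + 1):
            for lv in range(1, config.n_levels + 1):
                row = {
                    "beach_id": b + 1,
                    "transect_id": t,
                    "tidal_level": lv,
                    "coast_position_km": pos[b],
                    "lon": lon[b],
                    "lat": lat[b],
                    "dist_low_tide": dist[lv - 1],
                }
                for name in _ENV_SCALES:
                    row[name] = beach_env[name][b]
                rows.append(row)
    df = pd.DataFrame(rows)
    df["sample_id"] = (
        "b" + df.beach_id.astype(str) + "_l" + df.tidal_level.astype(str) + "_t" + df.transect_id.astype(str)
    )
    df["composite_id"] = "b" + df.beach_id.astype(str) + "_l" + df.tidal_level.astype(str)
    return df.set_index("sample_id")[
        ["beach_id", "transect_id", "tidal_level", "composite_id", "coast_position_km", "lon", "lat"]
        + ENV_COVARIATES
    ]


def composite_design(design: pd.DataFrame) -> pd.DataFrame:
    """Collapse physical samples to the unique beach x tidal-level sites
    (covariates are shared across transects, so 'first' is exact)."""
    return design.groupby("composite_id", sort=False).first()


def draw_params(
    config: SimulationConfig, seed: int | None = None
) -> LatentCommunityParams:
    """Random generative parameters at the configured effect scales."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    S = config.n_species
    intercepts = rng.normal(0.0, 0.5, S)
    B = config.effect_scale * rng.standard_normal((len(ENV_COVARIATES), S))
    G = config.spatial_scale * rng.standard_normal((5, S))
    L = config.loading_scale * rng.standard_normal((S, config.rank))
    return LatentCommunityParams(intercepts=intercepts, B=B, G=G, L=L, rank=config.rank)


def simulate_presence_absence(
    design: pd.DataFrame,
    params: LatentCommunityParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the binary community at the composite (beach x level) sites.

    y_ij = 1 iff a_j + (X B)_ij + (S G)_ij + (L h_i)_j + eps_ij > 0 with
    standardised covariates X and the same trend surface the fitting code
    builds; h_i is a standard-normal rank vector, eps standard normal.
    """
    sites = composite_design(design) if "composite_id" in design.columns else design
    X, _ = standardise(sites[ENV_COVARIATES])
    S_design = trend_surface(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    n = len(sites)
    S = params.B.shape[1]
    if params.B.shape[0] != X.shape[1] or params.G.shape[0] != S_design.shape[1]:
        raise ValueError("parameter dimensions do not match the design")
    rng = np.random.default_rng(seed)
    h = rng.standard_normal((n, params.rank))
    eps = rng.standard_normal((n, S))
    eta = (
        params.intercepts[None, :]
        + X.to_numpy() @ params.B
        + S_design.to_numpy() @ params.G
        + h @ params.L.T
        + eps
    )
    y = (eta > 0).astype(int)
    return pd.DataFrame(
        y, index=sites.index, columns=[f"OTU{j + 1}" for j in range(S)]
    )


def simulate_taxonomy(
    config: SimulationConfig,
    seed: int | None = None,
    n_contaminant_otus: int = 12,
) -> pd.DataFrame:
    """Per-OTU taxonomy: meiofauna OTUs with group labels drawn from the
    observed community composition and high best-hit identities, plus
    contaminant OTUs (non-meiofauna or sub-85% identity) that downstream
    taxonomy filters must remove."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    names = list(GROUP_COMPOSITION)
    weights = np.array(list(GROUP_COMPOSITION.values()), dtype=float)
    weights /= weights.sum()
    groups = rng.choice(names, size=config.n_species, p=weights)
    rows = []
    for j in range(config.n_species):
        rows.append(
            {
                "otu_id": f"OTU{j + 1}",
                "best_identity_pct": float(rng.uniform(86.0, 100.0)),
                "group": groups[j],
                "is_meiofauna": True,
            }
        )
    for k in range(n_contaminant_otus):
        non_meio = rng.random() < 0.5
        rows.append(
            {
                "otu_id": f"CONTAM{k + 1}",
                "best_identity_pct": float(
                    rng.uniform(90.0, 100.0) if non_meio else rng.uniform(50.0, 85.0)
                ),
                "group": "Diatomea" if non_meio else "unknown",
                "is_meiofauna": False if non_meio else True,
            }
        )
    return pd.DataFrame(rows)


def simulate_read_counts(
    pa: pd.DataFrame,
    config: SimulationConfig,
    design: pd.DataFrame,
    seed: int = 0,
    taxonomy: pd.DataFrame | None = None,
    min_rel: float = 0.0003,
) -> pd.DataFrame:
    """Noisy read-count table at the physical-sample (replicate) level.

    Present OTUs receive log-normal relative abundances floored at
    2x ``min_rel`` (so genuine occurrences always survive the
    low-abundance filter); each sample's depth is log-normal with a
    configurable fraction of low-depth (< 3000 read) samples; absent OTUs
    receive contamination reads with probability ``contamination_rate``
    at a relative abundance strictly below ``min_rel``; contaminant OTUs
    from the taxonomy (if given) appear everywhere at moderate abundance.
    """
    rng = np.random.default_rng(seed + 3)
    if config.contamination_rate < 0:
        raise ValueError("negative contamination rate")
    samples = design.index.to_numpy()
    composites = design["composite_id"].to_numpy()
    otus = list(pa.columns)
    contam_otus = []
    if taxonomy is not None:
        contam_otus = [o for o in taxonomy["otu_id"] if o not in pa.columns]
    all_otus = otus + contam_otus
    counts = np.zeros((len(samples), len(all_otus)), dtype=int)
    S = len(otus)

    depths = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, len(samples)))
    low = rng.random(len(samples)) < config.low_depth_fraction
    depths[low] = rng.uniform(100, 2999, low.sum())
    depths = np.maximum(depths.astype(int), 50)

    for i, (sid, comp) in enumerate(zip(samples, composites)):
        present = pa.loc[comp].to_numpy().astype(bool)
        depth = depths[i]
        rel = np.zeros(S)
        if present.any():
            ab = np.exp(rng.normal(0.0, 1.0, present.sum()))
            r = ab / ab.sum()
            r = np.maximum(r, 2.0 * min_rel)
            rel[present] = r / r.sum()
        n_contam_cols = len(contam_otus)
        if n_contam_cols:
            # ubiquitous non-community OTUs at ~2% of reads in total
            c_ab = rng.dirichlet(np.ones(n_contam_cols)) * 0.02
        reads = np.round(rel * depth * (0.98 if n_contam_cols else 1.0)).astype(int)
        reads[present & (reads == 0)] = 1
        counts[i, :S] = reads
        if n_contam_cols:
            counts[i, S:] = np.round(c_ab * depth).astype(int)
        # low-level cross-talk: absent OTUs, strictly below the filter
        row_total = counts[i].sum()
        c_max = int(np.ceil(min_rel * row_total)) - 1
        if c_max >= 1:
            absent_idx = np.where(~present)[0]
            hit = absent_idx[rng.random(len(absent_idx)) < config.contamination_rate]
            counts[i, hit] = rng.integers(1, c_max + 1, len(hit))
    table = pd.DataFrame(counts, index=samples, columns=all_otus)
    if config.missing_fraction > 0:
        keep = rng.random(len(samples)) >= config.missing_fraction
        table = table.loc[samples[keep]]
    return table


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    design: pd.DataFrame
    params: LatentCommunityParams
    presence: pd.DataFrame  # composite x OTU truth
    counts: pd.DataFrame  # physical sample x OTU reads
    taxonomy: pd.DataFrame


def simulate_study(
    config: SimulationConfig, params: LatentCommunityParams | None = None
) -> SimulatedStudy:
    """Design + parameters + truth + noisy observations, all from one seed."""
    design = generate_design(config)
    if params is None:
        params = draw_params(config)
    pa = simulate_presence_absence(design, params, seed=config.seed + 10)
    taxonomy = simulate_taxonomy(config)
    counts = simulate_read_counts(
        pa, config, design, seed=config.seed + 20, taxonomy=taxonomy
    )
    return SimulatedStudy(
        config=config,
        design=design,
        params=params,
        presence=pa,
        counts=counts,
        taxonomy=taxonomy,
    )
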