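import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from metasandy.preprocess import preprocess_pipeline
from metasandy.simulate import (
    ENV_COVARIATES,
    LatentCommunityParams,
    SimulationConfig,
    composite_design,
    draw_params,
    generate_design,
    simulate_presence_absence,
    simulate_read_counts,
    simulate_study,
)


def _tetrachoric(y1, y2):
    """Brute-force tetrachoric correlation: 2x2 table + numeric inversion
    of the bivariate-normal orthant probability (oracle, not shipped API)."""
    p1, p2 = y1.mean(), y2.mean()
    p11 = float(np.mean(y1 * y2))
    t1, t2 = norm.ppf(p1), norm.ppf(p2)

    def f(rho):
        return (
            multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2]) - p11
        )

    lo, hi = -0.999, 0.999
    if f(lo) * f(hi) > 0:
        return np.sign(p11 - p1 * p2)
    return brentq(f, lo, hi, xtol=1e-6)


def _flat_sites(n_sites, seed=0):
    """A design with many composites for large-sample distribution checks."""
    cfg = SimulationConfig(
        n_beaches=n_sites // 8, n_transects=1, n_levels=8, n_species=2, rank=1, seed=seed
    )
    return generate_design(cfg)


class TestDesign:
    def test_full_design_dimensions(self):
        cfg = SimulationConfig(n_beaches=24, n_transects=3, n_levels=8)
        d = generate_design(cfg)
        assert len(d) == 576
        assert d["composite_id"].nunique() == 192

    def test_dist_low_tide_endpoints(self):
        d = generate_design(SimulationConfig(n_beaches=1, n_transects=1, n_levels=2))
        assert sorted(d["dist_low_tide"]) == [0.0, 100.0]

    def test_dist_spans_within_each_beach(self):
        d = generate_design(SimulationConfig(n_beaches=3, n_levels=8))
        for _, grp in d.groupby("beach_id"):
            assert grp["dist_low_tide"].min() == 0.0
            assert grp["dist_low_tide"].max() == 100.0

    def test_seed_determinism_bytewise(self):
        cfg = SimulationConfig(seed=5)
        assert generate_design(cfg).to_csv() == generate_design(cfg).to_csv()

    def test_coordinates_increase_with_coast_position(self):
        d = generate_design(SimulationConfig(n_beaches=10)).sort_values(
            "coast_position_km"
        )
        beaches = d.groupby("beach_id").first().sort_values("coast_position_km")
        assert (np.diff(beaches["lon"]) > 0).all()
        assert (np.diff(beaches["lat"]) > 0).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_beaches=0)


class TestPresenceAbsence:
    def test_zero_params_prevalence_half(self):
        design = _flat_sites(2000)
        S = 4
        params = LatentCommunityParams(
            intercepts=np.zeros(S),
            B=np.zeros((6, S)),
            G=np.zeros((5, S)),
            L=np.zeros((S, 1)),
            rank=1,
        )
        pa = simulate_presence_absence(design, params, seed=1)
        assert np.allclose(pa.mean(axis=0), 0.5, atol=0.04)

    def test_no_loadings_independent_species(self):
        design = _flat_sites(2000)
        S = 6
        params = LatentCommunityParams(
            intercepts=np.zeros(S),
            B=np.zeros((6, S)),
            G=np.zeros((5, S)),
            L=np.zeros((S, 2)),
            rank=2,
        )
        pa = simulate_presence_absence(design, params, seed=2).to_numpy()
        rhos = [
            abs(_tetrachoric(pa[:, i], pa[:, j]))
            for i in range(S)
            for j in range(i + 1, S)
        ]
        assert np.mean(rhos) < 0.05

    def test_shared_loading_positive_cooccurrence(self):
        design = _flat_sites(2000)
        S = 2
        L = np.array([[3.0], [3.0]])
        params = LatentCommunityParams(
            intercepts=np.zeros(S), B=np.zeros((6, S)), G=np.zeros((5, S)), L=L, rank=1
        )
        pa = simulate_presence_absence(design, params, seed=3).to_numpy()
        observed = np.corrcoef(pa[:, 0], pa[:, 1])[0, 1]
        assert observed > 0.5
        # oracle: latent correlation 9/10 -> tetrachoric should approach it
        rho = _tetrachoric(pa[:, 0], pa[:, 1])
        assert rho == pytest.approx(0.9, abs=0.08)

    def test_prevalence_monotone_in_intercept(self):
        design = _flat_sites(2000)
        prevalences = []
        for a in (-1.0, 0.0, 1.0):
            params = LatentCommunityParams(
                intercepts=np.array([a]),
                B=np.zeros((6, 1)),
                G=np.zeros((5, 1)),
                L=np.zeros((1, 1)),
                rank=1,
            )
            prevalences.append(
                simulate_presence_absence(design, params, seed=4).to_numpy().mean()
            )
        assert prevalences[0] < prevalences[1] < prevalences[2]

    def test_cooccurrence_monotone_in_shared_loading(self):
        design = _flat_sites(2000)
        corrs = []
        for load in (0.5, 1.5, 3.0):
            params = LatentCommunityParams(
                intercepts=np.zeros(2),
                B=np.zeros((6, 2)),
                G=np.zeros((5, 2)),
                L=np.full((2, 1), load),
                rank=1,
            )
            pa = simulate_presence_absence(design, params, seed=5).to_numpy()
            corrs.append(np.corrcoef(pa[:, 0], pa[:, 1])[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]

    def test_dimension_mismatch_raises(self):
        design = _flat_sites(16)
        params = LatentCommunityParams(
            intercepts=np.zeros(2),
            B=np.zeros((4, 2)),
            G=np.zeros((5, 2)),
            L=np.zeros((2, 1)),
            rank=1,
        )
        with pytest.raises(ValueError):
            simulate_presence_absence(design, params, seed=0)


class TestReadCounts:
    def test_no_contamination_means_no_false_reads(self):
        cfg = SimulationConfig(
            n_beaches=4, n_levels=4, n_species=10, contamination_rate=0.0, seed=2
        )
        design = generate_design(cfg)
        pa = simulate_presence_absence(design, draw_params(cfg), seed=1)
        counts = simulate_read_counts(pa, cfg, design, seed=1)
        absent = ~pa.loc[design["composite_id"]].to_numpy().astype(bool)
        assert (counts.to_numpy()[absent] == 0).all()

    def test_degenerate_depth_row_sums(self):
        cfg = SimulationConfig(
            n_beaches=3,
            n_levels=4,
            n_species=12,
            depth_log_mean=float(np.log(10_000.0)),
            depth_log_sd=0.0,
            contamination_rate=0.0,
            low_depth_fraction=0.0,
            seed=3,
        )
        design = generate_design(cfg)
        pa = simulate_presence_absence(design, draw_params(cfg), seed=1)
        counts = simulate_read_counts(pa, cfg, design, seed=1)
        assert np.allclose(counts.sum(axis=1), 10_000, atol=cfg.n_species)

    def test_determinism(self, small_study):
        again = simulate_study(small_study.config)
        assert again.counts.equals(small_study.counts)
        assert again.presence.equals(small_study.presence)
        assert again.design.to_csv() == small_study.design.to_csv()


def test_round_trip_filters_recover_truth(small_study):
    """The planted noise (contamination below 0.03%, low-depth samples,
    contaminant OTUs) is exactly removed by the stated filters."""
    pa = preprocess_pipeline(
        small_study.counts, small_study.taxonomy, small_study.design["composite_id"],
        min_occupancy=5,
    )
    truth = small_study.presence.loc[pa.matrix.index, pa.matrix.columns]
    assert (truth.to_numpy() == pa.matrix.to_numpy()).all()
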