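"""End-to-end orchestration: simulate or ingest tables, preprocess,
select covariates, fit the dissimilarity and joint models, partition the
explained variation, and write a machine-readable report.

Every stage reads plain CSV tables with header rows (samples as rows)
and writes its outputs under the configured directory; no stage mutates
its inputs on disk. The report JSON collects the headline statistics of
each stage — sample/OTU tallies, GDM deviances and coefficient sums, the
joint model's log-likelihood and pseudo-R^2, and the median assembly-
process shares — plus stage wall-clock timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import gdm as gdm_mod
from . import jsdm as jsdm_mod
from . import partition as part_mod
from . import preprocess as prep
from . import simulate as sim

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "output_dir",
    "counts_csv",
    "taxonomy_csv",
    "sites_csv",
    "simulate",
    "min_rel",
    "min_reads",
    "min_occupancy",
    "abundance_scope",
    "merge_mode",
    "r_max",
    "vif_max",
    "gdm_splines",
    "jsdm",
    "partition_method",
    "quantreg_degree",
    "n_boot",
    "seed",
}


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Either the three input CSV paths or a ``simulate`` block (passed to
    :class:`~metasandy.simulate.SimulationConfig`) must be given.
    """

    output_dir: str = "metasandy_out"
    counts_csv: str | None = None
    taxonomy_csv: str | None = None
    sites_csv: str | None = None
    simulate: dict | None = None
    min_rel: float = 0.0003
    min_reads: int = 3000
    min_occupancy: int = 10
    abundance_scope: str = "sample"
    merge_mode: str = "sum"
    r_max: float = 0.7
    vif_max: float = 2.0
    gdm_splines: int = 3
    jsdm: dict = field(default_factory=dict)
    partition_method: str = "shapley"
    quantreg_degree: int = 2
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _stage(report, name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report["timings_s"][name] = round(dt, 3)
            if exc is not None:
                log.error("stage %s failed after %.1fs: %s", name, dt, exc)
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)

    return _Timer()


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the full workflow and return the report dictionary."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()}, "timings_s": {}}

    with _stage(report, "ingest"):
        if config.simulate is not None:
            sim_cfg = sim.SimulationConfig(**{**config.simulate, "seed": config.seed})
            study = sim.simulate_study(sim_cfg)
            design, counts, taxonomy = study.design, study.counts, study.taxonomy
            design.to_csv(out / "sites.csv")
            counts.to_csv(out / "counts.csv")
            taxonomy.to_csv(out / "taxonomy.csv", index=False)
            (out / "truth.json").write_text(study.params.to_json())
        else:
            if not (config.counts_csv and config.taxonomy_csv and config.sites_csv):
                raise ValueError("need counts_csv, taxonomy_csv and sites_csv (or simulate)")
            counts = pd.read_csv(config.counts_csv, index_col=0)
            taxonomy = pd.read_csv(config.taxonomy_csv)
            design = pd.read_csv(config.sites_csv, index_col=0)
        report["n_physical_samples"] = int(counts.shape[0])
        report["n_input_otus"] = int(counts.shape[1])

    with _stage(report, "preprocess"):
        pa = prep.preprocess_pipeline(
            counts,
            taxonomy,
            design["composite_id"],
            min_rel=config.min_rel,
            min_reads=config.min_reads,
            min_occupancy=config.min_occupancy,
            abundance_scope=config.abundance_scope,
            merge_mode=config.merge_mode,
        )
        pa.matrix.to_csv(out / "community_matrix.csv")
        report["n_composite_samples"] = pa.n_samples
        report["n_retained_otus"] = pa.n_otus
        report["group_tally"] = {str(k): int(v) for k, v in pa.group_tally().items()}

    with _stage(report, "select_covariates"):
        sites = sim.composite_design(design).loc[pa.matrix.index]
        env_raw = sites[[c for c in sim.ENV_COVARIATES if c in sites.columns]]
        env_std, _ = cov.standardise(env_raw)
        env_sel, sel_report = cov.select_covariates(
            env_std, r_max=config.r_max, vif_max=config.vif_max
        )
        (out / "selection_report.json").write_text(json.dumps(sel_report.to_dict(), indent=2))
        report["covariates_retained"] = sel_report.retained
        report["max_vif"] = max(sel_report.final_vifs.values())
        geo = cov.geo_distance_matrix(sites["lon"].to_numpy(), sites["lat"].to_numpy())

    with _stage(report, "fit_gdm"):
        d = gdm_mod.jaccard_matrix(pa.matrix)
        gfit = gdm_mod.fit_gdm(d, env_raw[env_sel.columns], geo=geo, K=config.gdm_splines)
        curves, importance = gdm_mod.gdm_transform_and_importance(gfit)
        curves.to_csv(out / "gdm_curves.csv", index=False)
        report["gdm"] = {
            "null_deviance": gfit.null_deviance,
            "model_deviance": gfit.model_deviance,
            "pct_deviance_explained": gfit.pct_deviance_explained,
            "intercept": gfit.intercept,
            "coefficient_sums": {k: float(v) for k, v in importance.items()},
        }

    with _stage(report, "fit_jsdm"):
        spec = jsdm_mod.JSDMSpec(seed=config.seed + 100, **config.jsdm)
        S_design = jsdm_mod.trend_surface(sites["lon"].to_numpy(), sites["lat"].to_numpy())
        jfit = jsdm_mod.fit_jsdm(pa.matrix, env_sel, S_design, spec)
        r2 = jsdm_mod.pseudo_r2(jfit, pa.matrix)
        coef_table = jsdm_mod.wald_significance(jfit)
        coef_table.to_csv(out / "jsdm_coefficients.csv", index=False)
        assoc = jsdm_mod.association_matrix(jfit, groups=pa.groups)
        assoc.to_csv(out / "association_matrix.csv")
        report["jsdm"] = {
            "log_likelihood": jfit.log_likelihood,
            "pseudo_r2_mcfadden": r2["mcfadden"],
            "pseudo_r2_nagelkerke": r2["nagelkerke"],
            "rank": jfit.L.shape[1],
        }

    with _stage(report, "partition"):
        grid = part_mod.component_loglik_grid(pa.matrix, env_sel, S_design, spec)
        richness = pa.matrix.sum(axis=1).to_numpy()
        pres = part_mod.partition_r2(grid, method=config.partition_method, richness=richness)
        pres.per_site.to_csv(out / "partition_sites.csv")
        pres.per_species.to_csv(out / "partition_species.csv")
        med = pres.per_site[["share_E", "share_S", "share_C"]].median()
        report["partition"] = {
            "median_share_environment": float(med["share_E"]),
            "median_share_space": float(med["share_S"]),
            "median_share_biotic": float(med["share_C"]),
        }

    with _stage(report, "internal_structure"):
        env_dist = cov.distinctiveness(features=env_sel.to_numpy())
        spa_dist = cov.distinctiveness(distance_matrix=geo)
        predictors = pd.DataFrame(
            {
                "env_distinctiveness": env_dist,
                "spatial_distinctiveness": spa_dist,
                "richness": (richness - richness.mean()) / richness.std(ddof=0),
            },
            index=pa.matrix.index,
        )
        for c in env_sel.columns:
            predictors[c] = env_sel[c].to_numpy()
        regressions = part_mod.internal_structure_analysis(
            pres,
            predictors,
            degree=config.quantreg_degree,
            n_boot=config.n_boot,
            seed=config.seed + 200,
        )
        regressions.to_csv(out / "regressions.csv", index=False)
        report["n_significant_regressions"] = int(regressions["significant"].sum())

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    summary = _summarise(report)
    (out / "summary.txt").write_text(summary)
    log.info("pipeline complete; outputs in %s", out)
    return report


def _summarise(report: dict) -> str:
    g = report["gdm"]
    j = report["jsdm"]
    p = report["partition"]
    lines = [
        "metasandy pipeline summary",
        "==========================",
        f"physical samples: {report['n_physical_samples']}; "
        f"composites: {report['n_composite_samples']}; retained OTUs: {report['n_retained_otus']}",
        f"GDM: {g['pct_deviance_explained']:.1f}% deviance explained "
        f"(null {g['null_deviance']:.1f}, model {g['model_deviance']:.1f}, intercept {g['intercept']:.2f})",
        "GDM predictor importance (sum of spline coefficients):",
    ]
    for k, v in g["coefficient_sums"].items():
        lines.append(f"  {k}: {v:.2f}")
    lines += [
        f"JSDM: log-likelihood {j['log_likelihood']:.2f}, "
        f"McFadden R2 {j['pseudo_r2_mcfadden']:.2f}, Nagelkerke R2 {j['pseudo_r2_nagelkerke']:.2f}",
        f"median assembly-process shares: environment {p['median_share_environment']:.2f}, "
        f"space {p['median_share_space']:.2f}, biotic {p['median_share_biotic']:.2f}",
    ]
    return "\n".join(lines) + "\n"
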