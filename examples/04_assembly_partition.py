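"""Internal structure: which assembly process drives which site?

Fits all 8 subset models over {environment, space, biotic covariance},
allocates each site's explained variation with Shapley values, and
regresses the per-site partial R^2 of each process on environmental
distinctiveness with median quantile regression.
"""

import pandas as pd

from metasandy import (
    JSDMSpec,
    SimulationConfig,
    component_loglik_grid,
    composite_design,
    distinctiveness,
    internal_structure_analysis,
    partition_r2,
    simulate_study,
    standardise,
    trend_surface,
)
from metasandy.simulate import ENV_COVARIATES

# environment-dominated world: strong species sorting, no dispersal
# limitation, no residual co-occurrence; short-range environmental
# fields keep space and environment decoupled
cfg = SimulationConfig(
    n_beaches=24, n_levels=8, n_species=20,
    effect_scale=1.5, spatial_scale=0.0, loading_scale=0.0, rank=2,
    env_range_km=30.0, seed=100,
)
study = simulate_study(cfg)
sites = composite_design(study.design)
X, _ = standardise(sites[ENV_COVARIATES])
S_design = trend_surface(sites["lon"].to_numpy(), sites["lat"].to_numpy())

spec = JSDMSpec(mc_samples=50, rank=2, iterations=300, seed=100, mc_samples_report=2000)
grid = component_loglik_grid(study.presence, X, S_design, spec)
result = partition_r2(grid, richness=study.presence.sum(axis=1).to_numpy())

medians = result.per_site[["share_E", "share_S", "share_C"]].median()
print("median share of explained variation per site:")
print(f"  environment {medians['share_E']:.2f}  space {medians['share_S']:.2f}  "
      f"biotic {medians['share_C']:.2f}")
print("(simulated sorting dominates, as planted)")

env_dist = distinctiveness(features=X.to_numpy())
predictors = pd.DataFrame({"env_distinctiveness": env_dist}, index=sites.index)
table = internal_structure_analysis(result, predictors, degree=1, n_boot=200, seed=2)
row = table[(table.component == "E")].iloc[0]
print(f"\nmedian regression of the environmental partial R2 on environmental")
print(f"distinctiveness: slope {row.beta_1:+.3f} (bootstrap p = {row.p_beta_1:.3f})")
print("a positive slope means sorting strengthens at environmentally unusual sites")
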