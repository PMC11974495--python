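# Methods

This note documents the models, the numerical choices and the synthetic
data the test suite relies on, in enough detail to judge what passing
tests do and do not demonstrate.

## Community matrix preprocessing

The filter chain is fixed: per-sample low-abundance zeroing → low-depth
sample removal → replicate merging → taxonomy/occupancy filtering.
Thresholds follow common metabarcoding practice and are all strict where
they are stated as strict: an entry is zeroed when it is *below* 0.03% of
its sample's reads (an entry at exactly 0.03% survives), a sample is
dropped when its total is *below* 3000 reads, and identity bins are
(97, 100] species, (95, 97] genus, (90, 95] family, (85, 90] order, with
85% itself unassigned and excluded.

Two readings of the 0.03% rule exist: per-sample zeroing (our default —
the artefact it targets, tag jumping, is a per-sample event) and
whole-OTU removal; `abundance_filter_scope="table"` provides the second.
Replicates are merged by summing read counts (`merge_mode="union"` gives
the same binary matrix). Negative controls are logged but never
subtracted, matching the situation where controls contain no target
taxa.

## Covariate selection and distinctiveness

Selection is correlation pruning (drop one member of each pair with
|r| > 0.7, the member with the larger mean absolute correlation to the
rest) followed by stepwise VIF elimination until max VIF < 2. A VIF
threshold below 1 is impossible (VIF = 1/(1−R²) ≥ 1), so 2 is the
default and the threshold is configurable.

Distinctiveness has no canonical formula; we use the simplest statistic
matching its verbal description: a site's mean distance to all other
sites — Euclidean on the standardised retained covariates for
environmental distinctiveness, great-circle km for spatial — z-scored
across sites. `method="centroid"` (distance to the covariate centroid)
is the obvious alternative and is provided. Distinctiveness is computed
on the retained, standardised covariate set.

## Generalised dissimilarity model

Monotone I-splines are built as right partial sums of a degree-2
B-spline partition of unity (degree 1 when only one spline is
requested); K = 3 puts the interior knot at the median, i.e. knots at
the 0/50/100 percentiles of the observed values. Each basis function is
exactly 0 at the predictor minimum and 1 at the maximum, so a
predictor's coefficient sum equals its total partial ecological
distance. Geographic distance gets its own basis evaluated on the
pairwise distance itself rather than on a difference of transforms.

The deviance (with the 0·ln 0 ≡ 0 convention; predictions clipped to
[1e−9, 1−1e−9] inside logarithms only) is minimised with L-BFGS-B under
non-negativity bounds using the analytic gradient; the null deviance
comes from the intercept-only model fitted the same way. The fit was
checked against a dense two-stage grid search on a 6-site problem and
recovers noiseless simulated models to within 5% on coefficient sums.
Site pairs are weighted uniformly. Out-of-range covariates at prediction
time are clamped to the training range with a warning.

## Joint species distribution model

The multivariate probit with low-rank residual covariance
Σ = LLᵀ + I is fitted by maximising a simulation consistent
approximation of the marginal likelihood: M Monte-Carlo draws of the
rank-r latent vector, drawn once and reused across iterations (common
random numbers), make the objective a smooth deterministic function.
M = 100 during optimisation and 10 000 for the reported final
log-likelihood are the defaults; on a 10-site toy the likelihood changes
by < 0.1% when M doubles at 10⁴. The optimiser is Adam
(lr 0.05 default) with a reduce-on-plateau scheduler: after 10
non-improving iterations the learning rate is multiplied by 0.9;
500 iterations by default. The latent rank defaults to ⌈S/2⌉.

The trend surface uses z-scored coordinates with columns
(x, y, x², y², xy); linear terms are included since a "second-order
polynomial" without them cannot represent a plane. On an exactly
linear coastline the x and y columns coincide; the fit is unaffected
(the likelihood depends on the column span) and standard errors fall
back to the pseudo-inverse with a warning.

Standard errors are a profile approximation: per-species probit
observed information on the marginal scale Φ(μ_j/c_j),
c_j = √(1+‖L_j‖²), ignoring uncertainty in L and cross-species
coupling. On pure-noise communities this yields Wald type-I error
within [0.03, 0.07] at α = 0.05 (checked over 20 seeds). No
multiple-testing correction is applied; stars are * < 0.05, ** < 0.01,
*** < 0.001.

Pseudo-R² is McFadden (1 − logL/logL₀ against the exact intercept-only
model) as the headline, with Nagelkerke (site-normalised) also
reported; the two differ substantially for community data and which one
a given analysis reports should be stated explicitly. The association
matrix masks off-diagonal correlations inside the [2.5%, 97.5%]
quantile band of the off-diagonal values and orders rows by
higher-taxon group.

## Variation partitioning and internal structure

All 2³ subset models over {environment E, space S, biotic covariance C}
are fitted with the same spec and seed; dropping C removes the latent
loadings entirely, dropping E or S removes that design block, and the
empty model is the exact independent-Bernoulli fit. Per-site (and
per-OTU, via the exact marginal Φ(μ/c)) McFadden R² defines the payoff
of each subset, and each process' partial R² is its Shapley value.
Shapley allocation is exact by construction — efficiency (partials sum
to the full-model R²), symmetry and additivity are asserted to 1e−9 on
every run; `method="unique"` (full minus leave-one-out) is provided as
the conservative alternative. Shares are |partial| normalised to sum 1;
a site with all-zero partials is flagged and excluded from regressions.

The internal-structure regressions are median (τ = 0.5) quantile
regressions solved exactly as linear programmes (HiGHS), with p-values
from a seeded case-resampling bootstrap (1000 resamples by default) and
a degree-2 polynomial design by default because the relationships of
interest are visibly curved; degree 1 is available. The regressed
quantity defaults to the per-site **partial R²** of each process — the
individual sample R² values — with the normalised share as an option.
This matters: a share is a ratio, and because the latent covariance
absorbs environment-induced co-occurrence (any covariance of rank ≤ the
fitted latent rank is representable by LLᵀ), the non-focal components'
explained variation grows together with the focal one at distinctive
sites, which can flatten or even invert a genuinely planted gradient in
share space while the partial-R² gradient remains robust.

## Synthetic data

The generator reproduces the study geometry: 24 beaches along a 650 km
coastline parameterised as a straight segment from (3.5°E, 51.5°N) to
(8.5°E, 55°N), with irregular (sorted-uniform) beach spacing and pinned
endpoints, 3 transects × 8 tidal levels per beach (576 physical
samples, 192 composites), and six covariates: distance from low tide
runs 100 → 0 equidistantly within each transect; grain size (300 ± 80
μm), spring tide range (2.5 ± 0.8 m), beach slope (3 ± 1.5°), salinity
(30 ± 1.5) and annual temperature (10 ± 0.7 °C) are beach-level
Gaussian-process draws along the coast with exponential covariance
(range 100 km by default), mimicking the space/environment confounding
of real coastlines while staying controllable.

Communities are drawn from the probit model itself (the generative twin
of the fitted model), so parameter-recovery tests are well-posed.
Read counts emulate the noise the filters target: present OTUs get
log-normal relative abundances floored at twice the abundance threshold
(a genuine occurrence never falls to the filter), depth is log-normal
(median 20 000 reads, σ = 0.6 on the log scale) with ~2% of samples
forced below 3000 reads, absent OTUs receive cross-talk reads with
probability 1% at a relative abundance strictly below 0.03%, and
non-target OTUs (non-meiofauna or < 85% identity) add ~2% of each
sample's reads. By construction the filter chain removes this noise
exactly, which is what the round-trip test asserts — it shows the
filters implement their stated rules, not that real contamination obeys
them. Sequence-level artefacts (chimeras, PCR bias, index hopping
above threshold) are not modelled.

Simulated taxonomy draws higher-taxon labels from the observed
composition of a 127-OTU sandy-beach meiofauna community (Nematoda 42,
Copepoda 21, … singletons), so group-sorted outputs look realistic.

## Problem sizes

Test and reproduction runs use deliberately scaled problem sizes chosen
to exercise every code path at full design geometry: the acceptance
script simulates the complete 24 × 3 × 8 design with a 60-OTU community
(fitted rank 10); parameter-recovery uses 200 sites × 30 species ×
6 covariates at rank 5; regime-recovery uses the full geometry with 20
species and 3 replicate studies pooled per regime, since a single ~190
site realisation gives the median regression little power. Regime
simulations use a 30 km environmental range (reducing space/environment
confounding so each planted mechanism is identifiable) and a moderate
spatial effect scale (0.8 versus 1.5 for the other mechanisms) because
the trend surface has few effective degrees of freedom on a near-linear
coast and saturates per-site R² early.

## Known limitations

- Monte-Carlo maximum likelihood with fixed draws is a simulated
  likelihood: with small M the latent covariance is mildly biased
  towards the draws; recovery tests quantify the practical effect.
- Standard errors ignore uncertainty in L; intervals for species with
  large loadings are somewhat anti-conservative.
- Per-site McFadden R² uses the global-prevalence null; sites with
  unusual composition have a larger null deficit, inflating every
  component's R² there.
- The biotic-association component is residual co-occurrence: missing
  covariates are indistinguishable from interactions, in the model as
  in the field.
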