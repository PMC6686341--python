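# Methods

This note documents the models, rules and numerical choices behind the
package, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Fire-context classification

Leks are classified against mapped fire perimeters (polygons with a fire
year) and an unburned-island mask (30 m raster of unburned patches inside
perimeters). Distances are planar Euclidean distances from the lek point
to polygon edges — vector, not raster cell-walks — so the 50 m rule does
not depend on grid resolution. Categories, in precedence order:

| category | rule |
|---|---|
| unburned island | inside an island, or < 50 m from an island edge or a perimeter edge (either side) |
| fire perimeter | inside a perimeter interior |
| small buffer | 50 m – 1.5 km outside the nearest perimeter |
| large buffer | 1.5 – 6.4 km outside (control: ~80 % of nests fall within 6.4 km of a lek) |
| outside | > 6.4 km; excluded from analysis |

Boundary conventions are not pinned down by the verbal definitions, so
they are fixed here as documented constants: "< 50 m" strict; the small
buffer closed at 50 m and open at 1.5 km; the large buffer closed at both
ends. A lek < 50 m outside a perimeter but far from any island is
classified *unburned island* — that is what the edge-proximity rule says
verbatim; users probing its sensitivity can reclassify with a different
`island_near_m`. When several perimeters are equally relevant (all
containing, or tied in distance), the earliest fire year supplies
`burn_year`, on the grounds that the earliest disturbance set the habitat
state.

## Lek inclusion filters

A lek enters the trend analysis only if it (a) lies in one of the four
categories, (b) was surveyed ≥ 6 years, (c) has ≥ 2 counts before and ≥ 2
at/after its fire year, and (d) is not already extirpated before the fire.
Criterion (d) is interpreted as "the two most recent prefire surveys are
not both zero"; an alternative reading ("any two consecutive prefire
zeros") is available via `zero_rule="any_consecutive"`. Exclusions report
the first failing criterion in (a)–(d) order.

The count in the fire year itself is treated as *postfire*
(`fire_year_is_post=True`); the sources are silent on this and the switch
is exposed.

## Before/after Poisson trend model

Per lek, counts Y follow a Poisson GLM with log link:
E(ln Y) = β₀ + β₁X₁ + β₂X₂ + β₃X₁X₂, with X₁ the survey year and X₂ the
after-fire indicator, so the prefire trend is β₁ and the postfire trend
β₁ + β₃ (units: log males per year). Fitting is by iteratively reweighted
least squares:

- X₁ is centered at the fire year internally for conditioning; slopes are
  invariant to this shift (verified to 1e-10), only β₀/β₂ change;
- start β = (ln(ȳ + 0.5), 0, 0, 0); Fisher-scoring steps with working
  weights μ; step-halving (≤ 30 halvings) whenever a step would increase
  the deviance, so the deviance is non-increasing across accepted
  iterations;
- convergence when the relative deviance change is < 1e-10, up to 50
  iterations; standard errors from the inverse observed information.

The IRLS path is self-contained; tests cross-check it against an
established GLM implementation to 1e-6 on random series and against a
coarse-to-fine grid search of the Poisson likelihood on a toy series.
Leks whose postfire counts are all zero have no finite postfire-slope MLE
(the likelihood increases as the slope → −∞); they are returned with a
NaN `post_slope`, `post_unbounded=True` and a warning, and excluded from
the comparison and averaging stages rather than silently dropped. How such
extirpated leks entered the original per-category comparisons is unknown;
the sentinel policy is one defensible reading.

No overdispersion correction is applied (negative-binomial and
state-space trend models are out of scope), and counts are taken at face
value without a detection-probability correction.

## Category comparison

Within each category the per-lek prefire slopes are compared with the
postfire slopes. Each vector is screened with Shapiro–Wilk at α = 0.05; if
both pass, a **two-sample Welch t test** is used, otherwise a two-sided
Wilcoxon rank-sum test (reported statistic: the Mann–Whitney U of the pre
sample). The two-sample (not paired) choice is deliberate: with n pre and
n post slopes the Welch–Satterthwaite df is non-integer (e.g. 8.30 at
n = 9), which identifies the two-sample convention used in the original
analysis; a paired t is available as an option. Sign convention:
statistic > 0 ⇔ mean(pre) > mean(post). Two degenerate constant samples
return statistic 0, p = 1, flagged. No multiple-testing correction is
applied across the four categories.

## Postfire habitat composition

For a lek burned in year T, a cell counts as burned if its most recent
fire year lies in [T − 17, T] (inclusive). The 17-year lookback reflects
that sagebrush recovery takes 35–120 years, so a 17-year-old burn is still
unsuitable; burned area is therefore treated as uniformly unsuitable with
no recovery curve.

- **Vegetation height**: 0.5 m height classes are mapped to midpoints
  (0.25 m for 0–0.5 m, …); the open-ended "> 3 m" class is assigned
  3.25 m (a documented constant; only the first-bin midpoint is given by
  the sources). Burned cells and unsuitable types (forest, juniper) are
  0 m. The per-disc covariate is the mean over unburned sagebrush cells,
  0 if the disc has none.
- **Cheatgrass**: the 250 m cover raster is nearest-neighbor resampled to
  the 30 m grid (preserving observed values). Burned cells below 2,000 m
  are unsuitable regardless of observed cover (burns invite invasion);
  burned cells at or above 2,000 m are suitable (cells at exactly 2,000 m
  follow the at-or-above branch); unburned cells are unsuitable iff
  observed cover > 8 %. The covariate is the unsuitable fraction of disc
  cells.
- **Elevation**: mean over all disc cells. Synthetic rasters contain no
  nodata inside discs, so the question of nodata handling in disc means
  does not arise.

Discs of 0.8, 6.4 and 18 km use cell-center membership; the discretized
area is within 1 % of πr² at 6.4 km on 30 m cells, and the rounded areas
at the three radii are 2, 129 and 1,018 km². A disc extending beyond the
raster is an error — callers must pad extents by the largest radius.

## Multimodel inference

Postfire slopes are regressed on the nine standardized covariates
(mean 0, SD 1, sample SD) by OLS (QR-based solve). The candidate set
assigns each of the three habitat variables one of {absent, 0.8, 6.4,
18 km} and excludes the intercept-only model: 4³ − 1 = 63 models. An
unconstrained all-subsets set over nine predictors (511 models) would be
inconsistent with a 63-model set and is available behind a flag only.

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with Gaussian ML variance RSS/n and
k counting intercept, slopes and the residual variance (k = #terms + 2).
Models with n ≤ k + 1 are skipped with a warning. Akaike weights are
w_i ∝ exp(−Δ_i/2); they sum to 1 and are invariant to AICc shifts.

Averaging is **full** by default: a model omitting a term contributes 0
with zero within-model variance, shrinking weakly supported terms toward
zero; **conditional** averaging (renormalized over models containing the
term) is the option. The unconditional SE follows the classic
Burnham–Anderson combination SE = Σ w_i √(var_i + (β_i − β̄)²); the
revised (Δ-adjusted) variant is not the default. 95 % CIs are β̄ ± 1.96·SE
(normal quantile, matching the symmetric CI structure of the reference
results) and p-values use the normal approximation. Significance =
CI excludes zero.

Collinearity screening computes the Spearman matrix (rank transform with
average ranks for ties) and VIF_j = 1/(1 − R²_j) from regressing each
predictor on the others; perfectly collinear predictors report +inf.
Retention requires pairwise |r| < 0.5 and VIF ≤ 3; drops are greedy
(highest VIF first) and every removal is reported with its reason.

## Synthetic landscape generator

The generator emulates the study system — a sagebrush steppe with a
multi-decade fire record — at configurable scale:

- **Fires** are blobs made by thresholding spatially smoothed noise minus
  a radial ramp around random ignition points; overlapping fires keep the
  most recent burn year per cell (mosaic semantics of operational
  perimeter databases). Fire sizes are log-uniform over a configurable
  range with a 4.05 km² floor (the usual mapping threshold of 405 ha).
- **Unburned islands** are the highest-scoring cells of a finer smooth
  field inside each perimeter, thresholded at an exact count, so the
  requested island fraction is achieved to within ±2 points. Per-fire
  fractions are drawn as range-scaled Beta(1.2, 10) over (0.02, 0.78),
  giving a mean near 10 % and a median near 8 % of perimeter area — the
  spread reported for the study region. A reburn erases older islands.
  The burn-year raster covers the full perimeter interior (islands
  included), mirroring perimeter-database semantics; the island mask is a
  separate layer.
- **Elevation** is a large-scale smooth field plus a gentle gradient,
  rescaled exactly onto 1,120–2,750 m. **Vegetation** is a sagebrush
  matrix (~80 %) with coherent grass/forest/juniper patches; height
  classes 1–7 come from another smooth field. **Cheatgrass** cover (0–100
  %, 250 m grid) declines logistically with elevation.
- **Counts** are Poisson draws from the log-linear trend model with
  per-category true parameters: burned leks crash after fire
  (β₃ ≈ −0.20 with a −0.7 level shift), small-buffer leks dip (−0.06),
  island and control leks stay roughly stable (−0.01 / 0). The true
  postfire trend change also tilts mildly with the lek's elevation and
  local cheatgrass cover (±0.03 per SD), so the inference stage has a
  genuine habitat signal. Baseline abundance is ~33 males (β₀ = 3.5 ±
  0.25). Leks are surveyed 1984–2017 with 80 % yearly probability; fire
  years span the 1984–2014 record, so some leks legitimately fail the
  inclusion filters, as in real monitoring data.
- Smooth fields with long correlation lengths are generated on a
  decimated grid and bilinearly upsampled — indistinguishable for this
  purpose and much faster; all randomness flows from one integer seed
  through a single generator, so equal seeds give bit-identical rasters.

What the generator does **not** emulate: physical fire spread, burn
severity, sagebrush recovery over decades, geographic (lat/lon)
coordinates, observation error in lek counts, and spatial correlation
between lek placement and fire risk. Passing tests therefore demonstrate
the correctness and calibration of the estimators under the stated
generating model, not the ecological conclusions themselves on real data.

## Problem sizes

The default end-to-end landscape is 60 × 60 km at 30 m (the real study
area is ~47,000 km²; this is a deliberately scaled-down replicate that
preserves all rates and thresholds), with 24 fires and 8 leks per
category; the bundled fixture is 15 × 15 km with reduced radii for
second-scale runs. Calibration simulations use 1,000 leks (CI coverage),
10,000 replicates (comparison type-I error) and 500 replicates of n = 32
(model-averaging sign recovery, with effect magnitudes 0.39/−0.47/0.27
and residual SD 0.83 chosen to match published coefficient and SE
magnitudes).

## Known limitations

- The 63-model constrained candidate set is a reconstruction of the
  published model count; the screening thresholds and the candidate-set
  structure are as documented above.
- Leks extirpated after fire (all-zero postfire counts) are excluded from
  comparisons and averaging; any downstream summary is conditional on
  non-extirpation.
- The pipeline assumes one planar metric CRS for all inputs and raises on
  grid mismatches rather than reprojecting, since silent reprojection
  could flip 50 m-scale classifications.
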