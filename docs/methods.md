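# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the verification studies implemented in
`krillspot`, including the design decisions taken where more than one
reasonable construction exists.

## Survey-record standardization

Raw net-haul tables (one row per haul × species × stage × sex) pass
through three steps.

**Inclusion filters.** Daylight hauls from 1993 onwards in April–September
are retained. Hauls whose sampling depth sits too far off the bottom are
excluded: a gap over 30 m where the bottom is shallower than 100 m, over
50 m for bottoms of 100–250 m. Hauls over bottoms deeper than 250 m are
always kept, because the nets sample to a 250-m maximum regardless of
bottom depth; whether such hauls should also face a disparity rule is
genuinely ambiguous, and we keep them. Records with missing depths are
rejected with a warning, never silently retained. Both filters are
idempotent.

**Counts to biomass.** Counts are divided by their subsample fraction,
adult (S4) counts multiplied by a daylight net-avoidance factor, converted
to dry weight with per-(species, stage, sex) coefficients, divided by the
filtered volume (mg/m³) and multiplied by the sampling depth (mg/m²).
Every haul emits exactly three observations — *E. pacifica* adults,
*T. spinifera* adults, pooled larvae (eggs + s1 + s2 of all species) —
including zeros, which the Tweedie model requires. Adults of non-focal
species are excluded from all groups and logged. The avoidance factor
defaults to 1.0 with a startup warning: no literature value is bundled,
and inventing one would silently bias every downstream number. Dry-weight
coefficients are likewise user-supplied; the synthetic generator uses
fixed documented toy values that only need to round-trip. When the flow
meter failed, volume can fall back to mouth_area × wire_out × cos(tow
angle) from configuration. Oblique and vertical hauls are treated
identically. Stage-group boundaries: eggs/nauplii < 3 mm; zoea < 5 mm
(s1); 5–10 mm juveniles (s2); ≥ 10 mm adults (S4) split by sex, with
unknown-sex adults priced at the male/female coefficient mean.

**Ecosections.** Points are labelled by first-match point-in-polygon over
an ordered polygon list (boundary points go to the first listed polygon —
a documented tie-break), with the continental-slope band split into north
and south bioregions at a configured line. Points outside all polygons are
labelled `outside` and drop out of regional summaries only.

## The spatiotemporal Tweedie GLMM

For biomass `y_i` at location `s_i`, year `t_i`, month `m_i`:

    y_i ~ Tweedie(mu_i, phi, p),  1 < p < 2
    log mu_i = X_i beta + A(s_i) u_{m_i}

### Tweedie density

The compound Poisson–gamma parameterisation (λ = μ^(2−p)/(φ(2−p)),
α = (2−p)/(p−1), γ = φ(p−1)μ^(p−1)) gives the exact zero mass
P(Y=0) = e^(−λ) and a positive part evaluated by the Dunn–Smyth series.
Terms are summed in log space around the maximising index
j_max = y^(2−p)/(φ(2−p)); for moderate j_max (≤ 2000) the full range is
enumerated vectorised over observations, for large j_max (the p → 1,
small-φ corner the optimiser may visit) a window of half-width
≈ 9.5 √j_max around j_max is summed per observation, widened until the
edge terms fall 37 log-units below the peak (relative truncation error
< 1e-10 — well below the 1e-16 floating-point floor at the reported
tolerance). Linear predictors extreme enough to under- or overflow μ
return a log density of −∞ for positive y, which the optimisers treat as
a rejected step. Only p ∈ (1, 2) is supported; other Tweedie branches are
out of scope. Random variates are drawn by explicit Poisson–gamma
composition (a Gamma(Nα, γ) draw given N > 0), which doubles as the
simulation oracle for the series.

### SPDE random fields

Each month carries a Gaussian Markov random field on a triangulation:
interior knots are seeded k-means centres of the observation locations
(thinned to a minimum spacing `cutoff_km`, default 10 km; default
n_knots = 200), surrounded by a rectangular ring of boundary nodes offset
outwards (default 0.15 × the data diagonal) to dampen boundary variance
inflation, and triangulated with Delaunay. The synthetic domain is a
convex rectangle, so an unconstrained triangulation suffices; barrier or
coastline-constrained meshes are out of scope. Piecewise-linear finite
elements give the lumped mass matrix C (diagonal; row sums of element
areas / 3) and stiffness matrix G (G is symmetric with zero row sums —
both properties are tested), and the Matérn (ν = 1, α = 2) precision is

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G).

`range_km` is the distance at which Matérn correlation falls to ≈ 0.13
(κ = √8/range) and `sigma` the marginal SD (τ = 1/(2√π κ σ)); both are
verified by simulation (correlation at the range within [0.10, 0.16],
SD within 10%). Months couple through a Kronecker product of the
unit-marginal-variance AR1 precision with Q; the six monthly fields are
shared across years (year enters the mean as a factor), so there is no
year boundary for the AR1 chain to cross. Observations interpolate the
field bilinearly (barycentric weights; rows of A sum to 1 and reproduce
affine functions exactly).

Matrices are assembled sparse; factorizations are dense Cholesky, which
at the latent dimensions used here (n_u = 6 × n_knots ≤ ~1500) is faster
and simpler than sparse supernodal factorization and has no extra
dependency. GMRF draws solve Lᵀx = z.

### Likelihood and optimisation

The joint negative log density is

    sum_i -log f(y_i | mu_i, phi, p) + 1/2 u'Qu - 1/2 log|Q| + (n_u/2) log 2pi.

Only the μ-dependent exponential-family part enters the inner problem;
its Hessian in η = log μ, ((2−p)μ^(2−p) + (p−1)yμ^(1−p))/φ, is strictly
positive for p ∈ (1,2), so the inner objective is convex and a damped
Newton iteration with Armijo halving converges globally (tolerance 1e-8
on the gradient, 100-iteration cap with a hard error). log|Q| uses the
Kronecker identity n_k·log|Q_AR1| + n_time·log|Q_space|.

`laplace_marginal_nll` implements the textbook form — inner mode over u
at fixed β, plus ½ log|H| with H = Q + AᵀWA — and is verified against an
independent dense implementation (scipy trust-region inner optimiser,
numpy log-determinants) to 1e-8 on 8-node meshes, and against the
closed-form linear-mixed-model marginal likelihood in the Gaussian-family
analogue, where the Laplace approximation is exact.

`fit()` profiles β into the inner Newton solve (joint step over (β, u),
Laplace log-determinant over the u block), so the outer problem is
5-dimensional: (log range, log σ, atanh ρ, log φ, logit(p−1)). The outer
search is L-BFGS-B with finite-difference gradients, box bounds on the
transformed scale, and warm-started inner modes; refits with identical
inputs are bit-identical. With `reml=True` the log-determinant of the
fixed-effect Schur complement joins the Laplace term (the restricted
likelihood). REML is the estimator used for variance-parameter studies
because plain ML shows the classic downward bias in range and σ when the
fixed effects absorb broad-scale field structure; AIC comparisons across
different fixed-effect structures use plain ML fits, since restricted
likelihoods are not comparable between mean models. AIC counts
df = (number of fixed effects) + 5; random effects are not counted, and
no claim is made that this df convention matches any particular software.

Splines are fixed-rank unpenalised thin-plate regression splines: cubic
radial basis |x − t_j|³ at k quantile knots with the two polynomial
null-space constraints absorbed by a QR basis, yielding k−1 design
columns (one linear) per term, centred over the training data. Basis
dimensions follow the standard formula set (month k=6; log depth k=3;
distance to coast k=4; distance to 1000-m isobath k=3; slope k=4; SST
k=3; log chlorophyll k=3; larval models add log1p adult-biomass splines
with k=4). No smoothing penalty is estimated — k is fixed by design, and
a penalty would add an unstated layer. The month spline is non-cyclic.
Covariates are transformed (log depth and chlorophyll, log1p adult
biomass), centred and scaled; the constants are stored so prediction
reproduces the training design bit-exactly. Fixed-effect covariances come
from the β Schur complement of the joint Hessian at the optimum.

Conditional-effect curves hold all other covariates at their
biomass-weighted means (weights = observed group biomass per haul,
falling back to unweighted means with a warning if all biomass is zero),
the month at the group's peak predicted month, the year factor at its
average effect, and the field at its mean (zero); intervals (50% and 95%)
use fixed-effect uncertainty only, by the delta method on the log scale.
σ_ε intervals use a finite-difference Hessian of the outer objective and
the delta method on log σ (so the interval never crosses zero).

## Prediction, masking, ratios

Grid predictions per month use all fixed and random effects,
μ = exp(Xβ + A_grid u_month), with the year factor at its average effect
(the monthly maps pool years; the survey's year coverage makes any single
year arbitrary). (Bioregion, month) strata with no observations are
masked — the emulated survey has no April effort in the north — and
masked cells never reach any downstream table; masking is idempotent.
Cells whose standardized covariates fall outside the training knot range
are predicted but listed as extrapolations. The E:T ratio surface is
EP/TS per cell-month with log10 for mapping; zero-denominator cells are
dropped with a count. Season averages are per-cell means over valid
months (ratio-of-season-means for the season ratio map, a documented
choice where average-of-ratios would also be defensible). Regional
monthly means are unweighted over valid cells with cell counts reported;
empty region-months are missing, not zero.

## Hotspots

Neighbour weights are symmetric binary distance-band matrices on cell
centroids (default d = 10 km, taken from configuration; Moran's I — with
expectation and normality variance — is reported as the diagnostic that
justifies d, but no automatic selection is attempted). The default local
statistic is Gi with self excluded, standardized with leave-one-out mean
and SD:

    Z_i = [sum_j w_ij x_j - xbar_(i) W_i] /
          { s_(i) sqrt(((n-1) sum_j w_ij^2 - W_i^2)/(n-2)) }

with the Gi* (self-included) variant behind a flag, since reference
implementations differ. Both match brute-force double-loop references to
1e-12. Constant fields have no defined Z and return all-missing with a
warning.

Percentile thresholds (90th and 95th) are computed on the Z-scores pooled
across the six months per group (type-7 linear-interpolation quantiles;
ties at the threshold flagged inclusively), so that month-to-month
comparisons share one scale. Persistence is the count of flagged months
per cell (0–6; 6 = persistent); masked months count as unflagged and such
cells are annotated. The persistence threshold defaults to the 95th
percentile with the 90th available — the two conventions coexist in the
source material and the discrepancy is surfaced in every run manifest.
Total-adult hotspots are computed from the summed adult prediction
surface with its own pooled percentiles. Regional summaries report total
(score ≥ 1) and persistent (score = 6) hotspot areas as 3 km² × cell
counts — areas are multiples of 3 km² by that accounting convention even
though grid cells are 3 km × 3 km — plus the peak-Z month/value and the
month of largest flagged area, per ecosection and coast-wide.

## Synthetic data

`make_domain` tiles a rectangle (default 300 × 198 km; the height is 198
rather than 200 so 3-km cells tile exactly) into five ecosection polygons
(shelf north/south, slope north/south, offshore) with the north/south
bioregion split at mid-height. `make_covariates` builds depth as a smooth
shelf-to-slope sigmoid (20–1500 m) with a sinuous shelf break, slope as
its finite-difference gradient magnitude, distances to the coast (x = 0
edge) and to the 1000-m isobath from the depth model itself, SST warming
through the season and southwards with a month-shifting mesoscale
anomaly, and chlorophyll as a May-peaking seasonal curve times a coastal
enrichment with a drifting bloom patch, normalised so the monthly spatial
means reproduce the configured seasonal curve exactly. The month-specific
spatial anomalies matter: perfectly separable (month + static space)
dynamic covariates are absorbed by the month spline and the monthly
fields, which no real SST/chlorophyll field would allow.

`simulate_survey` emulates the survey conditions: 1,609 rule-conforming
hauls by default across 1993–2019, month-uneven (April lightest) and
shelf-heavy effort, no April hauls in the northern bioregion, lognormal
filtered volumes, sampling depth near the bottom capped at 250 m. Biomass
for the two adult groups is drawn from the model family itself (monthly
AR1 Matérn fields simulated on a survey mesh, spline-shaped covariate
effects, year effects, Tweedie noise); larval μ couples to the simulated
adult μ surfaces through the same log(x+1) link the larval model uses,
with a stronger coefficient on *T. spinifera* than *E. pacifica*. Default
adult observation scale (intercept e^4 mg/m², p = 1.6, φ = 15) yields
~40% empty hauls. Each haul's biomass is decomposed back into the raw
count table (inverting the standardization chain through the toy
coefficients, subsample fractions and avoidance factor), so
ingest(simulated table) reproduces the generator's mg/m² to 1e-8 —
decomposed counts are real-valued, which the ingest chain accepts.
Planted depth-disparity violators, night hauls and off-season hauls are
appended beyond the valid-haul count with flags, so the filters must
remove exactly them. Everything regenerates bit-identically from its
seed, and the truth (field and Tweedie parameters, effects, seeds) is
serialized with each dataset.

### Verification study designs

The **recovery study** (20 seeded replicates) measures pure estimation
error: n = 1200 observations over 6 months × 4 years at truth range 30 km,
σ = 1, ρ = 0.6, p = 1.5, φ = 1.2, with a quadratic log-depth effect and
intercept 1.0 (≈ 10% zeros). Its domain is 150 × 120 km so that the
80-knot analysis mesh has ~range/2 knot spacing — coarser meshes cannot
resolve the field and push the likelihood onto a small-range/large-σ
ridge — and effort is spatially uniform, the cleanest design for
identification. The latent field is simulated on the same mesh used for
fitting, so the study isolates estimation consistency from
mesh-refinement error; the full survey emulation simulates on its own
mesh instead. Fits use REML (see above). With this design each parameter
lands within 25% (ρ within ±0.15) in at least 80% of replicates.

The **model-selection study** uses the same design with effects on depth,
SST and chlorophyll (0.6 and 0.5 per SD for the dynamic covariates —
sized so the full-vs-depth AIC margin is decisive rather than marginal)
and compares null / depth-only / full ML fits: AIC orders
full < depth-only < null in ≥ 90% of replicates.

What passing these studies does **not** show: the generator shares the
model family, mesh discretization and covariate set with the estimator,
so real-data issues — misspecified covariance, coastline barriers,
preservation and species-identification errors, vessel effects,
oblique-vs-vertical haul bias — are untouched. The studies verify the
machinery, not the ecology.

## Problem sizes and runtime choices

The test suite runs the recovery and selection studies at their design
sizes (20 replicates each; an 80-knot mesh, i.e. n_u = 720 latent
values), Monte-Carlo oracles at 4×10⁵–10⁶ draws, and GMRF calibration on
a 24 × 24 regular mesh with 800 draws. `scripts/acceptance.py` runs the
same studies scaled down (8 recovery and 5 selection replicates) plus a
full-size (1,609-haul) survey round trip and an end-to-end demonstration
fit on an 80-knot mesh; these sizes are the package's chosen
demonstration scale. Dense Cholesky factorization bounds the per-fit
cost at roughly (6·n_knots)³; 200-knot production meshes remain
practical, and the latent dimension — not the number of observations —
dominates.

## Known limitations

* Outer-gradient evaluation is finite-difference; there is no automatic
  differentiation, so very high-dimensional fixed-effect outer problems
  are avoided by profiling β.
* Penalized smoothness selection, anisotropic or barrier fields,
  non-Tweedie families and spatially varying coefficients are out of
  scope by design.
* Conditional-effect intervals ignore random-effect and hyperparameter
  uncertainty (fixed-effect covariance only).
* The AIC df convention (fixed effects + 5) is documented, not claimed to
  match other software's accounting.
* At grid-prediction time the larval model substitutes predicted adult
  surfaces for the observed co-located adult biomass used at fitting
  time; the source convention is unstated and this choice is ours.
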