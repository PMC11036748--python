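# Methods

`cortisel` implements a glucocorticoid-integrated habitat-selection pipeline
for GPS-collared ungulates, with a synthetic-study generator that makes
every stage testable against a known truth. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
validation studies do and do not establish.

## The selection model

The core is an integrated step-selection analysis (iSSA). A *movement bout*
is the GPS subset in the 20 h preceding one fecal sample's deposition — in
elk, circulating glucocorticoids are metabolized into fecal metabolites
(FGMs) over roughly that window, so the sample integrates the hormone state
over exactly those fixes, and restricting the bout to that window keeps the
inference directed from hormones to subsequent selection rather than the
reverse.

Within a bout, each observed step (a consecutive fix pair with a defined
turn angle; a bout needs ≥ 3 fixes) is matched with K available steps drawn
from movement kernels fitted to the observed steps: gamma for step length
(location fixed at 0), von Mises for turn angle. The conditional logistic
likelihood compares the used step against its K available steps within each
stratum:

    log L(β) = Σ_strata [ βᵀx_used − log Σ_j exp(βᵀx_j) ]

with design columns

    dist_end                        distance to forest/shrubland cover at the
                                    step end point, in units of 100 m
    dist_end × fgm_z                hormone interaction
    dist_end × fgm_z × period      period = 0 pre-calving, 1 post
    dist_end × fgm_z × days        days since calving (0 for pre bouts)

`fgm_z` is the FGM concentration standardized to mean 0, sample SD (ddof=1)
1 across the accepted samples — the same convention as R's `scale()` — so a
"unit increase" in the hormone coefficient is one population SD. Distance is
measured in 100-m units purely to keep coefficients O(1); "200 m from
cover" is `dist_end = 2`.

Two estimation routes are implemented and must agree:

- **clogit** — Newton iteration on the conditional likelihood with analytic
  gradient (Σ x_used − E[x]) and observed information (Σ within-stratum
  covariance of x). The likelihood is concave; convergence is declared at
  max |score| < 1e-6, and ‖β‖ > 50 is flagged as separation
  (`converged=False`).
- **poisson_trick** — the equivalent Poisson log-linear model with one free
  intercept per stratum. Given β the intercepts have the closed form
  α_s = −log Σ_j exp(βᵀx_j) (each stratum's fitted total equals its observed
  total of 1), so the fit is block-coordinate IRLS: profile the intercepts,
  take a Newton step on the slopes using the intercept-profiled information
  I_ββ − I_βα I_αα⁻¹ I_αβ. This is the standard device for making stratified
  models tractable at many strata, and its fixed point coincides with clogit
  (enforced to 1e-5 in the tests; observed agreement ~1e-14).

Covariates that are constant within every stratum cannot enter a matched
likelihood; they are dropped with a NaN coefficient (R's `clogit`
behaviour), leaving other coefficients untouched. Genuinely collinear
columns raise an error naming the offenders.

Movement-correction covariates (log step length, cosine turn angle) are
available (`MOVEMENT_TERMS`) but **off by default**: the substantive model
here is the four habitat × hormone terms. Random slopes are provided only as
an L2-penalized per-individual-deviation variant (`fit_ssf_mixed`) behind a
separate entry point; the package's inferential surface is the fixed-effects
fit, since the mixed conditional model is only weakly identifiable at the
sample sizes this pipeline targets (~70 bouts).

Kernels are fitted per individual when that individual contributes ≥ 50 used
steps, else pooled. Zero-length steps are floored at 1 m before gamma
fitting.

## The synthetic generator

`simulate_dataset` emulates the study conditions end-to-end: 13 collared
female elk over two seasons (May–August 2019/2020), 30-min fixes, ~6 fecal
samples per individual-year with a 20% DNA identification rate, calving
between May 20 and June 25, and a 5-day post-calving hiding phase.

**Landscape.** A 120×120 grid of 50-m cells: cropland matrix (the dense
forage source) with ~8 circular forest/shrubland patches of 150–500 m
radius. `dist_cover` is the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`), zero on cover cells; point lookups
are bilinear.

**Hormones.** Concentration = population mean + individual intercept +
within-individual noise, truncated positive by rejection. Defaults (mean
1900, between-SD 500, within-SD 665 µg·g⁻¹) were solved once from the
printed population quantile range: pooled SD = √(500² + 665²) ≈ 832 and
1900 ∓ 0.8416 × 832 ≈ 1200 / 2600 µg·g⁻¹ at the 0.2/0.8 quantiles. The
between/within split is not identified by that range; 500/665 gives a
realistic intraclass correlation of ~0.36.

**Movement.** A redistribution-kernel process: at each step, M candidate
steps are drawn from the gamma/von Mises kernel (gamma shape 2, scale 150 m
per 30-min step; von Mises κ = 0.5 — elk-scale defaults) and one is chosen
with probability ∝ exp(β_eff · dist_end), where

    β_eff = β_dist + β_df·z + β_dfp·z·period + β_dfd·z·days.

The generating β defaults are the effect sizes the pipeline is designed to
resolve: exp(β) = 0.90, 1.44, 0.80, 1.01. The hormone state z(t) is
piecewise constant and equals each sample's standardized concentration
during the 20 h before its deposition (zero otherwise), so refitting the
bout model has an exact truth.

The discrete candidate choice approximates the continuous selection density
with O(1/M) error. **M = 500 by default**: at M = 50 the discretization
produces measurable attenuation of refitted coefficients (up to ~1 SE at
desk scale), which is a numerical artifact of the generator, not a property
of the model; M = 500 pushes it well below estimation noise. This is a
fidelity knob, not a study condition.

**Calving.** During the hiding window (calving date + 5 days) candidate step
lengths are multiplied by the suppression factor (default 0.2) and
candidates are weighted toward the calving site by exp(−2 · d_site/100 m),
reproducing the revisit-plus-slow-movement signature mothers of hidden
calves show. Bout-level recovery studies (`simulate_bout`,
`simulate_issa_study`) disable the hiding layer so the fitted model matches
the generating process exactly; the full `simulate_dataset` keeps it, as
real data would.

What the generator does **not** emulate: GPS fix loss and location error,
herd sociality, weather-driven FGM degradation, spatially heterogeneous
forage quality within a class, and hormone autocorrelation between samples.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to those field
complications.

## Calving-date detection

Per-fix features: revisit count within a 300-m buffer (a revisit is a
maximal time-contiguous run of fixes inside the circle centred on the focal
fix; the defining visit counts, so counts ≥ 1), mean step length and net
displacement in a centred 24-h window, and hour of day. The feature list is
a design choice (revisit frequency and movement slowing are the signal; the
protocol we follow does not prescribe features).

Training labels mark fixes inside [calving date, +5 d] of observed events,
classes are balanced by seeded down-sampling without replacement, and the
default classifier is a 100-tree random forest behind a pluggable
`fit`/`predict_prob` contract.

The detection threshold is the mean probability assigned to in-event fixes
— but estimated **leave-one-event-out**: each observed event is scored by a
classifier trained on the other events. In-sample (or even per-row
out-of-bag) probabilities on event fixes are overfit toward 1 because
within-event fixes are strongly autocorrelated, and an overfit threshold is
unattainable on genuinely held-out tracks.

Detection scans a 5-day rolling window advancing fix-by-fix (ties broken by
the earliest start). The protocol is repeated 100 times — the repeats differ
only in down-sampling and classifier seeds — per-fix probabilities are
averaged across repeats, and the best window exceeding the threshold is
returned; the estimated calving date is the window's first date, and the
across-repeat spread of per-repeat best dates is reported as a precision
statistic. If no window exceeds the threshold the track yields no event.
Probabilities are averaged per fix before windowing (the alternative,
averaging per window, is equivalent for fixed windows but ill-defined where
window supports differ).

## Sample assignment and the screening ledger

Samples without DNA identity are scored against their suspected individual:
the scorer predicts correct-identification over 500 seeded iterations and
the sample is accepted when the mean reaches the 0.77 accuracy threshold
(boundary closed). Failures get one rescue pass over candidate individuals —
any other elk with ≥ 1 fix within 20 m of the sample up to 2 d before
collection, both boundaries closed — evaluated in descending order of
qualifying fix count, first acceptance winning (ties within a fix-count
group resolved by highest mean accuracy). Per-(sample, candidate) seeds are
derived by a stable hash, so screening is order-independent. The bundled
`ProximityScorer` (logistic in near-fix fraction and recency, optionally
calibrated on DNA-identified samples) is a minimal stand-in for a
telemetry-based identity model; the interface accepts any replacement.

Every stage lands in a `ScreeningLedger` whose identities are enforced
exactly (collected = DNA + scored; accepted = DNA + scored − failed +
recovered; discarded = failed − recovered; retained ≤ accepted).

## RSS and UHC

Log relative selection strength is the coefficient contrast
log-RSS(x1, x2) = β̂ᵀ(x1 − x2); it is antisymmetric and zero at x1 = x2.
Curves sweep the hormone axis over the 0.2–0.8 population quantile range,
comparing a location 200 m from cover (dist = 2) with a location in cover
(dist = 0), by calving period (days fixed at 0) and by calf age 0/30/60 days
(period fixed post). Uncertainty is a **coefficient (parametric) bootstrap**:
draws from MVN(β̂, vcov) with percentile 2.5/97.5 ribbons — the bootstrap
target is the sampling distribution of the linear contrast, and at 10⁵ draws
the percentile CI converges to the analytic normal CI. A non-PSD vcov is
repaired by eigenvalue clipping with a warning.

Used-habitat calibration (UHC) splits the data **by bout** (50/50 by
default) to respect stratum dependence, refits on the training half, and
for each of n_sims coefficient draws samples one predicted-used step per
held-out stratum with weights exp(βᵀx) (Gumbel-max sampling). Covariate
densities are Gaussian KDEs with Silverman bandwidth on a fixed 512-point
grid, renormalized to integrate to 1 on the grid (trapezoid); the envelope
is the pointwise 2.5–97.5% band across simulations and coverage is the
fraction of grid points where the observed used-density lies inside it.
Covariates omitted from a model can still be evaluated — that is how a
wrongly omitted interaction is caught.

## Pre/post-calving hormone model

Standardized FGM ~ period + year (two-level factor) with a random intercept
per individual. Two engines:

- `likelihood`: REML via `statsmodels.MixedLM`, Wald 95% intervals; when
  the random-intercept variance is estimated at the boundary (0) and the
  mixed fit yields no usable information matrix, the model collapses to —
  and is refitted as — ordinary least squares;
- `mcmc`: a conjugate Gibbs sampler (slopes N(0,1) prior, intercept N(0,10),
  variances InvGamma(2,1) — weakly informative on the standardized scale),
  4 chains × 10,000 iterations with 5,000 warmup, posterior medians and
  quantile intervals.

The two agree in sign and overlap in interval on well-conditioned data;
exact numerical agreement with any particular sampler is not a goal.
Samples with no calving record for their individual-year are dropped from
this model with a log entry.

## Validation studies and sizes

All sizes below were chosen as the smallest designs that resolve the
questions; they are what `tests/test_acceptance.py` and
`scripts/acceptance.py` run.

- **Coefficient recovery**: 100 replicates of 13 individuals × 6 bouts
  (~78 bouts, ~3,100 strata) at K = 40; each monitored 95% CI must cover its
  generating value in 90–99 replicates (observed 93/97/98 at the
  development seed).
- **Estimation equivalence**: clogit vs an independently coded brute-force
  conditional likelihood (Nelder-Mead) on 10-strata toys, and vs the Poisson
  route, both to 1e-5.
- **Kernel recovery**: gamma/von Mises MLEs within 10% at n = 2,000.
- **Ratio sensitivity**: K ∈ {1, 30, 40, 100}; the max over coefficients of
  |β̂(30) − β̂(100)|/SE(100) stays below 0.5, and SE(K=1) > SE(K=40).
- **Calving detection**: 11 training + 10 hidden events at suppression 0.15;
  median |date error| ≤ 2 d among detections (observed 0–1 d, 9–10/10
  detected).
- **UHC**: the self-consistent model keeps ≥ 90% of grid points in the
  envelope; omitting dist × FGM degrades the omitted covariate's coverage
  (observed ~0.95+ vs ~0.5–0.7).
- **Hormone GLM null coverage**: 100 null replicates (26 individual-years,
  ~78 samples); the period interval covers 0 in ≥ 90.

## Known limitations

- The identity scorer is a proximity heuristic, not a validated telemetry
  classifier; its 0.77 threshold is meaningful only relative to a scorer of
  that accuracy.
- The penalized random-slopes variant does not estimate variance components;
  it shrinks with a fixed penalty.
- UHC envelope coverage treats test strata as independent when sampling
  predicted-used points; strongly autocorrelated tracks make the observed
  density clumpier than the envelope assumes, so coverage on small test
  sets is conservative to interpret near the 0.90 line.
- The Gibbs sampler assumes the conjugate Gaussian model; it is not a
  general-purpose MCMC engine.
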