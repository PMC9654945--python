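# Methods

## Primary growth models

All four models are implemented in their explicit, canonical forms
(see README for the equations). Two numerical points matter:

* **Direction.** Sensor responses decline during spoilage, so the
  package allows `Nmax < N0` rather than forcing callers to negate
  their data. The Logistic, Huang and Baranyi forms are already
  direction-symmetric: with `Nmax < N0` they run monotonically from
  `N0` down to `Nmax`. The Zwietering Modified Gompertz is not — with
  a signed `(Nmax − N0)` in its slope factor a decreasing
  parameterisation time-reverses the curve. We therefore use
  `|Nmax − N0|` in the slope factor, which is identical to the
  classical form for increasing curves and gives the intended mirror
  image for decreasing ones. The constant usually printed as 2.718 is
  Euler's *e*.
* **Overflow.** Terms like `e^{4λ}` or `e^{μmax·t}` overflow double
  precision well inside the legal parameter box (λ up to the last
  sampling time, t up to 10⁶ h in the asymptote checks). Huang's lag
  transfer and Baranyi's adjustment function are evaluated through
  `logaddexp`/`log1p`/`expm1`, and `log(e^x + c)` switches to
  `x + log1p(c·e^{−x})` for large `x`.

`shelf_life_time` inverts the fitted curve at a threshold (default
5 Log CFU/mL, the safety limit used for freshly squeezed juice) by
Brent root-finding on the monotone curve, with an expanding upper
bracket. A threshold already met at t = 0 returns 0; one outside the
band swept by the curve returns `None`.

## Fitting

`GrowthCurveFitter` minimises the residual sum of squares with
`scipy.optimize.least_squares` (trust-region reflective, bounds) from
multiple starts: one data-driven guess (`n0` ← first observation,
`nmax` ← last, `μmax` ← max finite-difference slope / |range|, `λ` ←
time of steepest slope − 1/μmax, clamped ≥ 0) plus Latin-hypercube
samples over the bounds, 32 starts by default. Bounds: `n0`, `nmax`
within the observed range widened by 50 % of the range on each side;
`μmax ∈ [10⁻⁴, 1] h⁻¹`; `λ ∈ [0, max t]`. Everything is seeded, so
fits are bit-reproducible; in practice the restart design converges to
the same optimum for any seed on the reference series.

Fit quality uses the degrees-of-freedom adjusted R² and RMSE (both
divide by `n − p`, `p = 4`). Note that the adjusted R² is smaller than
the plain `1 − SSE/SST` whenever SSE > 0; reference tables in the
literature sometimes mix the two conventions, so comparisons should
state which is used. Replicated data are fitted on **per-time means**,
not pooled replicates: the calibration RMSEs reported for sensor-based
growth curves (≈ 0.37 response units) match mean-level scatter, not
the ~2–3× larger replicate-level scatter. Train/test evaluation
(`fit_with_validation`) fits the training means and re-scores the
*same* trained curve on the testing means — no refit — since the
reported validation statistics accompany a single set of (λ, μmax).

A caution from using a thorough optimiser: on convex-decay-shaped
series (e.g. an E-nose channel that drops fastest at the start) the
global Baranyi optimum can sit at the lag bound with a substantially
lower SSE than the textbook-shaped local optimum a single-start fit
finds. Published parameter tables produced by single-start software
may therefore be unreachable *from above*: this package will report
the better-fitting optimum.

`fit_all` fits all four models and sorts by adjusted R² (ties: lower
RMSE, then the conventional model order), returning partial results
with error records if a model fails.

## Channel screening

ANOVA and Duncan's multiple range test are computed from per-group
summary statistics: `SS_between = Σ nᵢ(mᵢ − m̄)²` and `SS_within =
Σ (nᵢ−1)sdᵢ²` reconstruct the raw-data sums of squares exactly, so
published mean ± sd tables can be re-analysed without replicates.
Duncan's critical range for a stretch of k adjacent (sorted) means is
`q*(α_k, k, df)·√(MSE/n_h)` with the protection level
`α_k = 1 − (1−α)^{k−1}`, studentized-range quantiles from scipy and
the harmonic mean `n_h` for unequal group sizes. Letters are assigned
to the maximal non-significant stretches, so the letter display is
interval-consistent. Be aware that letter groupings recomputed from
*rounded* summary tables can differ from the grouping the original
raw-data software printed — the raw MSE is not recoverable from
rounded SDs — so letter counts should be compared with that caveat.

Pearson tables use two-sided t-tests with stars at p < 0.05 (`*`) and
p < 0.01 (`**`). The E-nose loadings analysis is a centered (not
variance-scaled) PCA of the time × channel mean matrix, the customary
view of which sensors dominate the array's raw response. Channel
ranking orders by Duncan letter count, then |r| with the plate-count
series, then |PC1 loading|.

## Fusion

E-nose responses span ~0.7–16 instrument units while taste channels
live on their own scale, so the fused PCA z-standardises each channel
of the time × channel mean matrix first (a deliberate choice; an
unscaled PCA would be dominated by the widest-range channel).
Component signs are oriented so every retained score series correlates
negatively with time — spoilage pushes the composite down — which
makes the downstream negation reproducible. The number of retained
components k is the smallest with cumulative explained variance ≥ 0.90
(default). The composite score is the variance-fraction-weighted sum
of the retained scores, weights *not* renormalised; its negation is
the growth-like series handed to the model fitters. Negation, not
reciprocals: scores cross zero mid-storage, so an actual inverse would
explode, while the negated series is a bounded sigmoid-like curve that
all four models fit well.

## Synthetic study generator

`make_fixture(seed)` reproduces the design: 15 sampling times (0–168 h
every 12 h), 20 replicates per time (15 train / 5 test by replicate),
one plate-count channel and 19 sensor channels. The latent truth is
the Baranyi plate-count curve (N0 = 3.996, Nmax = 5.337 Log CFU/mL,
μmax = 0.064 h⁻¹, λ = 97.85 h — slow growth with a long lag at 4 °C);
counts add Gaussian replicate noise (sd 0.1 Log CFU/mL, matching
plate-count RMSEs of ≈ 0.10).

Sensor channels are affine in the latent count. E-nose slopes and
intercepts are anchored to the observed 0 h and 168 h responses and
replicate noise to typical reported SDs; taste-channel slopes and
noise are set so the per-time-mean correlation with the count matches
the published correlation pattern (sweetness ≈ +0.77, umami ≈ −0.58,
richness ≈ +0.64, bitterness ≈ 0, …).

Real mean trajectories deviate from the kinetic curve far more than
replicate averaging explains (published sensor-vs-count correlations
are |r| ≈ 0.79–0.94 where pure replicate noise would give ≈ 0.99), so
the fixture also injects **session drift**: three smooth time profiles
(sine/cosine harmonics, orthogonalised against the latent trend so
drift does not mimic growth), shared by all replicates of a sampling
time, with per-channel random loadings. Drift magnitudes are budgeted
per channel so the mean-level correlation with the count hits its
target (85 % of the non-signal variance is shared drift, 15 % stays
iid), and the relative amplitudes of the three profiles decline like
the variance split seen in fused sensor PCAs. Under this structure
the fused PCA retains ~3–5 components at the 0.90 threshold, versus
exactly 1 on a noiseless fixture.

What the generator does **not** emulate: non-Gaussian and
heteroscedastic replicate noise, replicate-level covariance between
channels, sensor saturation/nonlinearity, and temperature excursions.
Passing tests on the fixture show the pipeline's statistics and
optimisation behave correctly under the design's dimensions and noise
scales, not that any particular instrument will achieve the same
correlations. All randomness flows from a single integer seed through
per-channel `SeedSequence` sub-streams, so datasets are
bit-reproducible and channel-local.

## Pipeline

`run_pipeline` executes: summarise → screen E-nose channels
(ANOVA/Duncan letter counts, Pearson vs counts, loadings) → select the
taste channel by |r| with counts → fit all four models to each of the
four sources (count means, selected E-nose channel means, selected
taste channel means, negated fused composite, each with the count
means as the correlation reference) → shelf life from the count fits.
Shelf life is reported only for the plate-count source: sensor units
have no calibrated mapping to CFU in this design, so inverting a
sensor curve at "5" would be meaningless. Reports are JSON
(canonical), CSV model tables, and markdown; reruns with the same
config and seed are byte-identical apart from the timestamp.

## Problem sizes and tolerances in the test suite

The suite regenerates all data programmatically: the full fixture
(15 × 20 × 20), 200 replicate panels for the parameter-recovery check
(median relative error of μmax ≈ 4 % < 10 %, λ ≈ 1 % < 15 % when
fitting per-time means), a 20⁴-point exhaustive grid as an optimiser
oracle on 8-point series, and 50 random ANOVA instances checked
against `scipy.stats.f_oneway` to 10⁻¹⁰. Noiseless recovery asserts
parameter agreement to 10⁻⁵ relative; curve-evaluation oracles are
frozen from high-precision symbolic evaluation (≥ 12 significant
digits).
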