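# Methods

## Cosinor model and conventions

All rhythm fitting uses the single-component cosinor with a fixed 24-h
period: `y(t) = M + A·cos(ω(t − φ)) + ε`, `ω = 2π/24`.  Linearizing gives
`y = β₀ + β₁cos ωt + β₂sin ωt`, solved by ordinary least squares, with
`M = β₀`, `A = √(β₁² + β₂²)` and `φ = atan2(β₂, β₁)/ω mod 24`.  The sign
convention is chosen so that φ is the clock time of the fitted peak: a
larger φ means a later peak.  When `A = 0` exactly the acrophase is
undefined; it is reported as 0 and flagged (`phase_defined=False`).
Rhythmicity per series is the F-test of `β₁ = β₂ = 0` (2 numerator df,
`n − 3` denominator df).  Two residual variances coexist deliberately: the
MLE `rss/n` feeds BIC (which requires the maximized likelihood), while the
F-test uses the unbiased `rss/(n − 3)`.  A series whose total sum of
squares is at round-off level is treated as exactly constant (F = 0,
p = 1) to avoid 0/0 in the variance ratio.

Period estimation is out of scope throughout; 24 h is fixed.

## Four-model BIC classification

Per gene, four Gaussian regressions are fit to the pooled young + old
observations: group intercepts only ("neither", 2 regression parameters),
young cosine/sine + old intercept ("young_only", 4), the mirror
("old_only", 4), and fully group-specific intercepts and cosine/sine terms
("both", 6).  Each model has a single shared residual variance, so its BIC
parameter count is the regression count plus one; `BIC = k·ln n − 2·ℓ̂`
with `n` the total observations (112 under the default design).  Weights
are Schwarz weights computed after subtracting the minimum BIC (numerically
stable); they sum to 1 and are invariant to adding a constant to all BICs.
Classification requires one weight to strictly exceed 0.75 (a threshold
must exceed 0.5, otherwise two models could pass simultaneously); genes
with no dominant model are "unclassified" rather than forced into a class.

Design choices made where the design was genuinely open: the variance is
pooled across groups within each model (the minimal Gaussian reading of a
shared-noise least-squares comparison), and no fifth "same rhythm in both
groups" model is included — the model space is exactly the four classes
above.

## Joint differential fit

Differences in MESOR, amplitude and phase between groups are estimated by
the joint nonlinear model
`y = (k + k₁G) + (α + α₁G)·cos(ω(t − φ − φ₁G))`, `G ∈ {0, 1}`.  Because
this full-interaction model is a bijective reparameterization of two
independent per-group linear cosinor fits, its global optimum is known in
closed form; the Levenberg–Marquardt solver (analytic Jacobian) is started
there and is, in effect, a verification step.  A fit is flagged
non-converged when the optimizer fails or the joint RSS exceeds the sum of
the two separate fits' RSS beyond tolerance; flagged genes keep their row
with NaN p-values and are excluded from downstream BH families — never
silently reported as a zero effect.

Wald tests use `SE² = diag(σ̂²(JᵀJ)⁻¹)` with `σ̂² = rss/(n − 6)` and a t
reference with `n − 6` df (slightly better calibrated than the normal at
n = 112; verified by the type-I simulations).  Phase differences are
wrapped to (−12, 12] with +12 at the boundary; positive φ₁ = the old group
peaks later (delay).  In the zero-residual limit (noise-free data) the SEs
vanish; a difference below round-off is then reported with p = 1 and any
real difference with p = 0, which makes the identical-groups null exact by
construction.

BH adjustment (via statsmodels) is run separately per statistic family
across genes: per-group rhythmicity (young, old), ΔMESOR, Δamplitude, and
Δphase.  The Δphase family includes only genes rhythmic in both groups —
a phase difference is meaningless when one group does not oscillate.  The
gate is the weighted-BIC "both" call by default; a per-group
rhythmicity-q gate (`q < 0.05` in both groups) is available as
`PipelineConfig(phase_gate="qvalue")` because the two readings are both
defensible and the choice materially affects which genes are tested.

## Subset filters and log₂ FC screens

The seven enrichment-input subsets are pure conjunctions over report
columns: (1)/(2) rhythmic `q < 0.05` in both groups AND MESOR-difference
`q < 0.05` AND sign of the difference; (3)/(4) the same with the phase
difference; (5)/(6) weighted BIC > 0.75 for the young-only / old-only
model; (7) weighted BIC > 0.75 for "both".  All inequalities are strict,
including the 0.75 boundary.

The paper-style effect-size screens operate on genes rhythmic in both
groups by the BIC call with a difference `q < 0.05`:
`|log₂FC| > 0.25` for MESOR and `> 0.1` for amplitude, strict.  Because
the input scale is log₁₀(1 + count), no fold-change is defined by the data
themselves; the package's convention is
`log2fc_mesor = (M_old − M_young)/log₁₀2` (the MESOR difference
re-expressed in log₂ units of 1 + count) and
`log2fc_amplitude = log₂(A_old/A_young)` (undefined, NaN, when either
amplitude is 0).  This is a convention, not an attribution; it is applied
uniformly and tested at its boundaries.

## Heatmap normalization

Three rounds per gene: (1) subtract each donor's mean within each age
group — this removes additive per-serum baselines exactly, which is also
asserted as an invariance test; (2) average replicates within each
group × timepoint; (3) Z-score each gene's trace across timepoints within
each group, using the sample (ddof = 1) standard deviation.  Genes
constant within a group would divide by zero; they are emitted as all-zero
rows and flagged instead of NaN.  A missing group × timepoint cell is an
error naming the cell.  The normalization is for display only and feeds no
statistics.

## Wearable chain

Activity streams are summed into calendar-minute bins (epochs labelled by
minute start); heart-rate and RR-interval streams are averaged per minute,
since summing rates is meaningless.  Minutes without data are absent, not
zero-filled (no imputation).  Times are hours since midnight of the first
measurement day per subject, so the 24-h cosinor acrophase is a clock
time.  Group comparisons: MESOR and amplitude by the exact two-sided
Wilcoxon rank-sum test (scipy's exact null distribution; midranks + normal
approximation with a `tied` flag in the measure-zero event of ties), phase
by the two-sample Kuiper test.

The Kuiper statistic `V = D⁺ + D⁻` is computed over the pooled support and
is exactly invariant to common rotations of both samples, which the test
suite checks.  Its p-value resamples group labels of the pooled values
without replacement (permutation) by default, `p = (1 + #{V* ≥ V})/(1 +
nboots)` with nboots = 10000, so p is never 0 and is reproducible from the
required seed; with-replacement resampling is available behind
`method="bootstrap"` since either reading of a "bootstrapped" circular
test is defensible.

## Synthetic data generator

The expression generator emulates the two-group serum-entrainment
time-course: 2 groups × 4 donors × 14 timepoints (32–58 h every 2 h),
values on the log₁₀(1 + count) scale.  Signal = group-specific cosinor +
per-donor additive intercept (drawn once per donor, N(0, 0.1²)) + i.i.d.
Gaussian noise.  Class sizes are `floor(frac × n_genes)` with the
remainder assigned to "neither" — deterministic and testable.  Defaults:
MESOR ~ U(2, 4), amplitude ~ U(0.5, 1.0), acrophase ~ U(0, 24),
noise SD 0.2 — an amplitude-to-noise ratio of 2.5–5, the regime where a
14 × 4 design detects rhythms reliably; these were chosen once as
plausible for normalized bulk RNA-seq log signals.  Injected
between-group effects (ΔM = +0.5, ΔA = −0.25, Δφ = +2 h by default) are
assigned round-robin over the "both"-class genes across the active
effects, giving every effect a deterministic quarter share.  Randomness is
split by `numpy.random.SeedSequence.spawn` into three independent streams
(gene parameters, donor offsets, noise), so regeneration is bit-identical
per seed.

The wearable generator produces truncated-at-zero cosine streams
(`max(0, M + A·cos(ω(t − φ_group − jitter)) + ε)`) with group-level
acrophases (default scenario: young 16 h, old 14 h — a 2-h advance in the
old group), optional per-subject phase jitter, and integer-second
timestamps so minute binning is exact.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: count-level sampling noise and its
mean–variance relationship, library-size normalization artifacts,
non-sinusoidal waveforms, damping of oscillations over the time course,
transients from the synchronization itself, gene–gene correlation, and
wearable non-wear gaps or activity bout structure.  Results on real data
depend on the adequacy of the cosinor shape and the Gaussian noise
approximation on the log scale.

## Problem sizes

The validation suite runs at sizes chosen to make each property
measurable with tight Monte-Carlo error while keeping the whole suite
fast: 1000 random series for the least-squares oracle, 400 genes for
classification accuracy, 2000 null genes for type-I calibration (99%
binomial band around 0.05 is ±0.0126), 500 replicates × 999 resamples for
Kuiper null uniformity, and 200 replicates for Wald coverage.

## Known limitations

- Replicates are treated as independent observations; there is no
  per-donor random effect in the inference (donor baselines are removed
  only in the heatmap normalization).  With few donors, a strong shared
  donor effect inflates MESOR-difference significance.
- The phase Wald test degrades when either group's amplitude approaches 0
  (the phase is then unidentified); gating the phase family on
  rhythmic-in-both mitigates but does not remove this.
- The exact Wilcoxon path requires no ties and group sizes where the exact
  null is computable; ties switch to the midrank normal approximation.
- The Kuiper p-value is a resampling estimate; with nboots = 10000 its
  granularity is ~1e-4.
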