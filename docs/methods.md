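# Methods

This note documents the models implemented by `threatdyn`, their
assumptions, the choices made where the design space was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Paradigm generator

`generate_timeline` produces a randomized countdown session: by default
3 scans of 478 volumes (TR 1.25 s), each presenting 6 trials of each of the
four conditions (certain/uncertain × threat/safety) in random order.

* **Certain epochs** last exactly 18.75 s (a 30-integer countdown at
  0.625-s display intervals).
* **Uncertain epochs** are drawn on the TR grid within [8.75, 30.00] s.
  The distribution is near-uniform over the grid with a constrained
  adjustment — random entries are nudged one grid step at a time — that
  forces the mean to exactly 18.75 s. The constraint is enforced **per
  scan**, which both fixes the session mean and guarantees that every
  scan's schedule fits its 597.5 s deterministically; the first three
  uncertain trials of a session are the fixed demonstration epochs
  (8.75, 15.00, 28.75 s).
* **Reinforcers** co-onset at epoch offset (shock 0.1 s, photograph 1.8 s,
  audio 0.8 s on threat trials; a 1.8-s benign compound on safety trials),
  followed by a 3.2-s white-noise mask. Co-onset is the simplest schedule
  consistent with an epoch that "culminates" in reinforcer delivery.
* **Inter-trial interval**: the mask plus a jittered gap on the TR grid.
  The jitter budget is whatever scan time remains after the fixed events
  (≈25 s per scan at the defaults), allocated one TR at a time to random
  trial gaps with a per-gap cap of 4 TRs. Rating prompts are supported as
  optional events but disabled by default; their schedule in the original
  paradigm is not public.
* Conventions: seconds from scan start, volumes indexed from 0, half-open
  intervals `[onset, onset + duration)`.

## HRF and design matrices

The canonical HRF is the standard double-gamma difference (peak delay 6 s,
undershoot delay 16 s, unit dispersions, 6:1 peak:undershoot ratio, 32-s
support), sampled on a microtime grid of TR/20 = 0.0625 s and normalized to
unit integral so a unit boxcar convolves to a plateau of height ≈1 and
fitted amplitudes read in neural-signal units. Event indicators are
rasterized on the microtime grid (onset "impulses" are a single microtime
sample of unit area), convolved by FFT, and sampled at volume midpoints,
matching slice-time correction to the TR center. Task columns span scans;
Legendre polynomials of orders 0–4 per scan serve as the high-pass/drift
basis (included as columns rather than pre-filtering, preserving
degrees-of-freedom bookkeeping).

Model-specific reference conditions (omitted columns, recorded in
`reference_record`): the certain-safety boxcar; the certain-safety
Sustained regressor (its Onset and Phasic columns are retained); and the
second certain-safety block. Contrast helpers treat weights on reference
columns as zero, so a reference-vs-itself contrast is exactly 0.

Convolved blocks tile each epoch with 6.25-s rectangles, truncating the
final block at epoch offset. Truncated blocks are kept, which is the only
tiling rule that yields the full 2–5 block range over 8.75–30.00-s epochs
(ceil(8.75/6.25) = 2, ceil(30/6.25) = 5).

### Collinearity diagnostics

`compute_vif` reports VIF_j = 1/(1 − R²_j), regressing each column on the
others after projecting out the drift basis, then averages within each
condition's components and across conditions. By default the diagnostic set
is the anticipation regressors of the four conditions: the reinforcer,
mask, and rating regressors are modeled to absorb stimulus-evoked variance
but are regressors of no interest, and treating them as part of the
collinearity summary roughly doubles the mean (they are strongly coupled to
the epoch-offset regressors by design — every epoch ends in a reinforcer
followed by a mask). With the default set, the mean condition-wise VIF over
200 generated sessions is ≈1.52 for the OSP model and ≈1.35 for the
Convolved Blocks model; `include_events=True` restores the all-columns
diagnostic. VIF is scale-invariant, so task columns are left unnormalized
(their amplitude carries duration information).

## Synthetic BOLD

The forward model is the analysis model run forwards: a `NeuralScenario`
assigns onset/sustained/phasic amplitudes (or an arbitrary piecewise
within-epoch envelope) per condition, the microtime neural series is
convolved with the same HRF and sampled on the same grid as the design
builders, then per-scan Legendre drift and stationary AR(1) noise are
added. Because simulator and design share one rasterize/convolve/sample
code path, fitting the generating design to noiseless data recovers the
amplitudes to numerical precision — the key invariant behind the
parameter-recovery tests.

Noise is AR(1) with white innovations rather than ARMA(1,1): at
single-series scale the MA component is weakly identified and adds an
unidentifiable knob; the AR coefficient is configurable (default 0.4).
Amplitudes are in arbitrary BOLD units — no attempt is made to calibrate
percent signal change. The generator does **not** emulate motion,
physiological noise, spatial autocorrelation, or scanner drift families
beyond low-order polynomials, so passing tests demonstrate the estimators'
correctness and the paradigm's identifiability, not robustness to real
artifact structure.

Group data draw subject amplitudes around a scenario mean with a
between-subject SD; the default study-conditions used by the acceptance
suite are n = 50 subjects, amplitudes 0.5, innovation SD 1, AR(1) 0.4 —
chosen to mimic single-ROI effect-to-noise ratios where a within-subject
effect is detectable but individual fits are noisy.

The signature simulator draws a voxel pattern u ~ N(0, 1) carrying a latent
per-condition × block distress course and sets decoder weights
w = u/‖u‖², so w·u = 1 and zero-noise decoding reproduces the latent
course exactly (up to float summation order). With per-voxel noise of fixed
SD, ‖w‖ ∝ n_voxels^(−1/2), so decoded responses converge on the latent
course as the pattern grows — the behavior expected of a trained
multivariate decoder.

## First-level estimation

`FirstLevelGLM.fit()` is a Cochrane–Orcutt-style prewhitened GLS: OLS on
the censored design, lag-1 autocorrelation of the residuals (computed only
across volume pairs adjacent within a scan), one prewhitening pass
(`row_t − φ·row_{t−1}`; the first usable row of each contiguous run scaled
by √(1−φ²)), and OLS on the whitened system. This approximates the
REML-ARMA(1,1) convention of standard fMRI tools with one fewer nuisance
parameter. Censored volumes are deleted (not interpolated); whitening never
couples rows across scan boundaries or censoring gaps; fits with more than
50% of volumes censored are refused. Standardized coefficients are
β_j·sd(X_j)/sd(y) — the convention is selectable via `bold_sd` since the
original convention is not printed.

## Group statistics

* **Repeated-measures GLM**: any number of within-subject factors, each
  effect tested against its own effect-by-subject error term. Effects are
  computed from orthonormal contrast scores (Helmert-based; Kronecker
  products across factors; uniform averaging over uninvolved factors).
  Sphericity: Greenhouse–Geisser ε from the contrast-score covariance,
  converted to Huynh–Feldt ε = (nqε_GG − 2)/(q(n − 1 − qε_GG)), capped at
  1 and exactly 1 for single-df effects; degenerate zero-variance scores
  get ε = 1. Partial η² = SS_effect/(SS_effect + SS_error). Verified to
  1e-8 against an independent cell-means sums-of-squares oracle and against
  pingouin for two-factor tables.
* **Trends**: linear (−1, 0, 1) and quadratic (1, −2, 1) contrasts over
  blocks 1–3, evaluated as one-sample t-tests of per-subject contrast
  scores (F = t²). Integer weights are used as-is; F and p are invariant to
  contrast scaling.
* **FDR**: Benjamini–Hochberg step-up via statsmodels over the supplied
  in-mask family, each contrast corrected separately; conjunctions are
  voxelwise AND of rejection masks.
* **Bayes factor**: JZS one-sample/paired BF10 with a Cauchy(0, r) prior on
  the standardized effect, r = √2/2 by default (the conventional default;
  configurable, since the original prior scale is unprinted), computed by
  adaptive quadrature over the induced inverse-gamma mixing density.
  Integration failures raise rather than clamp. Bands: ≤0.10 strong null,
  ≤1/3 moderate, ≤1 weak, >1 favors the alternative.
* **Effect-size bands** for d_z: the printed anchors are nil (≤0.10,
  boundary inclusive) and small (0.20); intermediate band edges are placed
  midway between the standard small/medium/large benchmarks (0.35, 0.65).
* **Power**: minimum detectable d_z by root-finding on the noncentral-t
  power function; a normal-approximation fallback covers noncentrality
  values where the scipy noncentral t loses accuracy.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale by design: 200 generated
sessions for the collinearity averages; 100 seeded replicates × 50
subjects for parameter recovery and dynamics emulation; 100 replicates ×
50 subjects × 100 voxels for signature fidelity. Seeds are fixed in the
suite (replicate index conventions chosen before the suites were run).
"Exact" algebraic identities are asserted at 1e-8–1e-12 to absorb
floating-point summation-order residue. Rank deficiency is detected from
the least-squares rank and reported with the offending column names;
zero-variance inputs to t-tests and effect sizes raise rather than return
infinities.

## Known limitations

The package deliberately excludes everything upstream of first-level
modeling (acquisition, motion/physio nuisance estimation, normalization,
smoothing) and the training of multivoxel signatures; published weight maps
can be supplied as external files but all shipped tests run on synthetic
weights. Headline group findings from real countdown data (regional
equivalence of extended-amygdala subdivisions, V-shaped distress dynamics)
depend on restricted participant data and are represented here only as
qualitative patterns that the pipeline reproduces under the documented
synthetic study conditions.
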