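# Methods

## Signal models and units

Two forward models describe the per-voxel DWI magnitude signal as a function
of diffusion weighting `b` (s/mm²):

- monoexponential: `SI(b) = SI₀ · exp(−b·ADC)`;
- biexponential (IVIM): `SI(b) = SI₀ · [(1−f_p)·exp(−b·D) + f_p·exp(−b·D*)]`
  with the vascular pseudo-diffusion compartment `(f_p, D*)` and the tissue
  compartment `(1−f_p, D)`, constrained to `0 ≤ D ≤ D*` and `0 ≤ f_p ≤ 1`.

All diffusivities are carried internally in mm²/s; the conventional
`×10⁻³ mm²/s` display scale is applied only when rendering report tables.
This avoids silent scale errors between `D` (~10⁻³) and `D*` (~10⁻²).
Signals are kept in linear space throughout, because magnitude-MRI noise is
additive (approximately, at high SNR) in linear, not log, space; logarithms
appear only inside initialization and test oracles.

For any two measurements the monoexponential model has the exact solution
`ADC = ln(SI₁/SI₂)/(b₂−b₁)` (the chord slope of the log-signal). Because the
log-signal of a perfused voxel is strictly convex in `b`, this chord slope
decreases whenever both endpoints of the interval move right, and every chord
exceeds `D`. That single convexity fact is what drives the whole
scheme-sensitivity phenomenology: low-b ADCs (schemes over b ≤ 250) are
systematically higher than high-b ADCs, and all ADCs exceed `D`. Note that
the ordering is only a partial order: interval pairs that are not ordered
componentwise (e.g. (50,100) vs (0,250)) are not comparable in general, and
for strongly perfused voxels with fast pseudo-diffusion their ADCs can cross.

## Scheme registry

The acquisition is b = 0, 50, 100, 250, 800 s/mm². The registry defines 13
monoexponential combinations `B0`–`B12` (every variant explored: the full
set, high-b-only, low-b-only, and intermediate pairs) plus `B0_biexp`, the
biexponential fit on all five b values. `B0`–`B5` carry a clinical-relevance
flag (they all include b = 800 and are the combinations used in practice).
A mono scheme needs ≥ 2 b values; a biexponential fit needs ≥ 4 — with four
unknowns, fewer points cannot constrain the model, and a 3-point request is
a precondition error rather than a degenerate fit.

## Fitting

Both fitters minimize squared residuals in linear signal space with
Levenberg–Marquardt, matching the approach used for this kind of per-voxel
analysis; the mono fit uses MINPACK LM directly (`scipy.optimize.least_squares`,
no bounds needed), the IVIM fit uses lmfit's MINPACK backend, whose
MPFIT-style parameter transformation enforces bounds. The ordering
constraint `D ≤ D*` is imposed by optimizing the non-negative gap `D*−D`.
Bounds are `D ∈ [0, 5×10⁻³]`, `D*−D ∈ [0, 0.5]` mm²/s, `f_p ∈ [0, 1]` —
wide enough to contain all reported malignant-lesion values (D up to
1.6×10⁻³, D* up to 72×10⁻³, f_p up to 0.55) with generous margin.

Initialization:

- mono: log-linear regression on the positive signals (exact for noiseless
  data, so LM converges in essentially one step; for two points the result
  reproduces the closed-form chord to ~1e−15 relative).
- IVIM: a *segmented* start. `D` comes from a log-linear fit over
  b ≥ 250 s/mm² (the perfusion compartment has decayed by ~95 % at b = 250
  for typical D*), `f_p` from one minus the ratio of the back-extrapolated
  high-b intercept to the measured b = 0 signal, and `D*` is seeded at 10·D.
  If either segment lacks points, a documented default start
  (D = 1×10⁻³, D* = 1×10⁻², f_p = 0.1) is used and flagged. A fixed
  user-supplied start is also supported for reproducing pathological cases.

`SI₀` is fitted freely by default; `pin_si0=True` pins it to the measured
lowest-b signal (both behaviours are exposed because either convention is
defensible and they differ under noise).

Convergence flags: optimizer failure ⇒ `converged=False` with best-effort
parameters retained. A solution pinned at an *upper* bound (D at 5×10⁻³,
gap at 0.5, f_p at 1) is treated as degenerate and flagged non-converged;
`f_p = 0` and `D* = D` are legitimate single-compartment limits and remain
converged — otherwise a perfusion-free voxel could never produce a valid
IVIM fit. Pathological voxels (all-zero or negative signal) never raise
during map computation; they yield `converged=False` and fall to QC.

Tolerances: `xtol`/`ftol` at 1e−13/1e−14 — tight enough that noiseless
round-trips recover generating parameters to ≤ 1e−6 (mono) and ≤ 1e−4
(biexp) relative error, the recovery contract asserted in the tests.

## Goodness of fit and QC

Each voxel fit reports `r²` (squared Pearson correlation between measured
and fitted signals over the scheme's b values) and `χ²` (summed squared
residuals of signals normalized by the measured lowest-b amplitude, making
the thresholds scale-free). When the measured signal has zero variance `r²`
is undefined (reported as NaN) and the voxel is excluded by QC. A voxel
passes QC iff the fit converged, `r²` is defined and ≥ `r2_min`, and
`χ² ≤ chi2_max`. QC is applied independently per model, so a voxel can pass
the mono fit and fail the biexponential one.

Default thresholds are `r2_min = 0.50`, `chi2_max = 0.20`. The intent of the
filter is to reject *noise-dominated* voxels — whose flat magnitude signal
decorrelates from any decay model — while retaining voxels that are merely
model-misspecified: a monoexponential fit of a strongly perfused voxel has
intrinsically depressed r² (down to ~0.4 noiseless at f_p ≈ 0.5) even though
its ADC is exactly the quantity this analysis studies. At these defaults a
phantom cohort at SNR 50 keeps ~99 % of mono fits and ~100 % of biexponential
fits, while signal-free voxels are rejected. Stricter settings (e.g. 0.98 /
0.05) isolate near-perfect fits only and are exercised in the tests; both
values are configurable and recorded in the map sidecars and logs.

## The phantom

The generator emulates the study conditions end to end: a
(36, 36, 9)-voxel grid containing 24 non-overlapping spherical lesions of
radius 2 voxels (~33 voxels each, comparable to a ~100 mm² ROI at typical
DWI resolution), background modelled as perfusion-free tissue with
D = 1.8×10⁻³ mm²/s (normal-parenchyma-like), SI₀ = 1000 a.u., and the
five-b acquisition. Per-lesion IVIM parameters are drawn uniformly from the
reported malignant-lesion ranges — D ∈ [0.2, 1.6]×10⁻³ mm²/s,
D* ∈ [4.3, 72.1]×10⁻³ mm²/s, f_p ∈ [0.05, 0.55] — emulating inter-patient
spread; a fixed parameter set (e.g. the cohort medians D = 0.84×10⁻³,
D* = 11.9×10⁻³, f_p = 0.16) can be supplied instead for calibration studies.
Diffusion is isotropic: the three orthogonal acquisition directions are
modelled as already trace-averaged, since the analysis consumes a single
signal per b value.

Noise is Rician by default — the magnitude of the clean signal plus complex
Gaussian noise, `sqrt((s+n₁)² + n₂²)` with `σ = SI₀/SNR` defined at b = 0 —
because the emulated data are magnitude EPI images; additive Gaussian and
noise-free variants exist for analytic tests (e.g. the Rayleigh mean
`σ·sqrt(π/2)` of noise-only voxels, and σ-calibration against SNR). Lesion
SNR is a free parameter defaulting to 50, a realistic value for lesion ROIs
at 1.5 T; recovery error scales with it, and the stochastic tests state
their SNR explicitly rather than hiding it. Geometry (slice thickness, gaps,
physical ROI areas) is not simulated: no computation downstream depends on
it, and ROIs are voxel sets.

Determinism: the `PhantomSpec` seed feeds two independent substreams (geometry /
parameter draws, and noise), so identical specs yield bit-identical
datasets; `add_noise` is itself deterministic under a fixed seed.

What the phantom does *not* emulate — EPI distortion, motion, partial
volume, fat saturation residues, coil inhomogeneity, rater variability in
ROI placement — bounds what passing tests show: they validate the
*estimators and statistics* under known ground truth and realistic noise,
not robustness to acquisition artefacts. One visible consequence: on this
well-specified phantom nearly all voxels admit a satisfactory biexponential
fit, whereas real lesion data show substantially lower biexponential
acceptance rates.

## Cohort statistics

Each lesion is reduced to the median (plus mean, SD, range) of each
parameter map over its QC-passing voxels; cohort analysis operates on the
per-lesion medians. Scheme pairs are compared by:

- percent deviation `dev(a, b) = 100·(a−b)/b`, which satisfies the exact
  reciprocal identity `(1 + dev(a,b)/100)(1 + dev(b,a)/100) = 1`;
- the two-sided Wilcoxon signed-rank test — exact null distribution for
  n ≤ 25 (midranks under ties), normal approximation above, zero differences
  dropped; if all pairs are tied the test carries no evidence and p = 1 by
  convention;
- tie-corrected Spearman rank correlation against the biexponential `D`.

"Deviation of median values" between two schemes is ambiguous: deviations of
group medians and group medians of per-lesion deviations differ at the
percent level. Both are implemented (`method="group_median"`, the default,
for which reciprocity is exact, and `method="per_lesion"`), and neither is
asserted to be canonical. No multiple-testing correction is applied by
default (the conventional 5 % level is used as-is); a Holm step-down helper
is available but off by default. The report tables are pure functions of
the summaries: re-running on saved maps reproduces them bit-exactly.

## Problem sizes

The test suite and the acceptance script run the phantom at its default
size: 24 lesions × ~33 voxels ≈ 790 fitted voxels per scheme, 1000 voxels
for the stochastic calibration at cohort-median truth, and 1000 random
signal pairs for the closed-form oracle comparison. These sizes give
sampling error well below the asserted tolerances while keeping a full run
in the tens of seconds on one CPU.

## Known limitations

- `D*` is weakly identified with only five b values (two below 100 s/mm²):
  its per-voxel estimates have very heavy tails, and the upper fit bound is
  occasionally active under noise. This mirrors the instability reported for
  pseudo-diffusion parameters generally; per-lesion medians are the only
  robust summary offered.
- The Rician noise model assumes a single-coil magnitude reconstruction;
  modern multi-coil reconstructions have different (non-central chi) noise.
- QC thresholds are declared package defaults, not values inferred from any
  reference dataset; analyses sensitive to the exclusion rule should sweep
  them.
- The phantom's uniform parameter ranges produce a more perfused cohort
  (mean f_p ≈ 0.3) than a typical median lesion, so group-level ADC-vs-D
  deviations on the default phantom are larger than those reported for
  clinical cohorts; fixed-parameter phantoms at the cohort medians are the
  right tool for calibration against printed values.
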