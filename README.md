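# ivimfit

Voxel-wise quantitative analysis of diffusion-weighted MRI (DWI): apparent
diffusion coefficient (ADC) mapping under different b-value combinations,
biexponential intravoxel-incoherent-motion (IVIM) fitting, and the cohort
statistics needed to compare them — together with a synthetic DWI phantom so
the whole pipeline can be exercised and validated without patient data.

## The problem

The ADC is the decay rate of the DWI signal with diffusion weighting `b`
(s/mm²) under the monoexponential model

```
SI(b) = SI₀ · exp(−b · ADC)
```

In perfused tissue the ADC is not a pure diffusion measure: capillary
microcirculation ("pseudo-diffusion") adds a fast-decaying component that
dominates at low b values, so the ADC you compute depends strongly on *which*
b values enter the fit. The IVIM model separates the two compartments,

```
SI(b) = SI₀ · [(1 − f_p) · exp(−b·D) + f_p · exp(−b·D*)]
```

with tissue diffusion coefficient `D`, pseudo-diffusion coefficient `D*`
(roughly an order of magnitude larger), and perfusion fraction `f_p`. This
package quantifies how the b-value choice moves the ADC, and how
monoexponential ADCs relate to the biexponential `D`, for an acquisition at
b = 0, 50, 100, 250, 800 s/mm² with a built-in registry of 13 ADC calculation
variants (schemes `B0`–`B12`, all subsets of ≥ 2 of the acquired b values)
plus the full-acquisition biexponential scheme `B0_biexp`.

It is aimed at researchers in quantitative MRI who want a tested, scriptable
reference implementation of scheme-sensitivity analysis — fitters, QC,
ROI statistics and paired tests — plus a ground-truth phantom for method
validation.

## What is inside

- `ivimfit.models` — closed-form forward models and the exact two-point ADC
  (chord-slope) solution that serves as the analytic oracle for every
  two-b-value scheme.
- `ivimfit.estimators` — scikit-learn style estimators `MonoExponentialModel`
  and `IvimModel` (Levenberg–Marquardt least squares in linear signal space;
  the IVIM fit is bound-constrained with 0 ≤ D ≤ D*, 0 ≤ f_p ≤ 1 and uses a
  segmented high-b initialization). They expose `fit`/`predict`/`get_params`
  and compose with sklearn tooling.
- `ivimfit.phantom` — a 4-D digital phantom: spherical lesions with per-lesion
  IVIM parameters drawn from published malignant-breast-lesion ranges,
  perfusion-free background, Rician (magnitude) noise at a configurable SNR,
  NIfTI + `.bval` on-disk layout.
- `ivimfit.fitting` — voxel-wise map computation for any scheme selection,
  r²/χ² goodness of fit and QC exclusion, NIfTI maps with JSON provenance
  sidecars.
- `ivimfit.stats` — per-lesion summaries over QC-passing voxels, percent
  deviation matrices, Wilcoxon signed-rank paired tests (exact null for
  n ≤ 25), Spearman correlations, and report rendering (CSV/JSON/Markdown).
- `ivimfit.cli` — `ivimfit simulate | fit | report`.

## Worked example

```
$ ivimfit simulate --out ds --seed 1 --n-lesions 24 --snr 50
wrote dataset to ds: grid (36, 36, 9), 24 lesions, b=(0, 50, 100, 250, 800), noise=rician, seed=1, ...

$ ivimfit fit --dataset ds --out maps --schemes B0,B4,B7,B0_biexp
wrote 7 maps to maps, ...

$ ivimfit report --dataset ds --maps maps --out report
  scheme parameter  n_lesions      mean         sd    median      min        max         units
      B0       adc         24  1.484161   0.620655  1.406839 0.612741   3.060969 x10^-3 mm^2/s
      B4       adc         24  0.920008   0.347597  0.906503 0.376676   1.577021 x10^-3 mm^2/s
      B7       adc         24  5.939447   3.429204  5.539788 1.659624  12.541199 x10^-3 mm^2/s
B0_biexp         d         24  0.823305   0.376586  0.813610 0.245887   1.566595 x10^-3 mm^2/s
B0_biexp    d_star         24 76.593322 129.453034 39.006857 5.084548 496.263169 x10^-3 mm^2/s
B0_biexp        fp         24  0.300146   0.149609  0.302883 0.061675   0.531979      fraction
```

Reading the table: each row summarizes the 24 per-lesion medians of one
parameter map. The flow-sensitive low-b scheme `B7` (b = 0, 50) gives a far
higher "ADC" (median 5.54 × 10⁻³ mm²/s) than the flow-insensitive high-b
scheme `B4` (0.91), because at low b the perfusion compartment dominates the
decay; the all-b ADC (`B0`, 1.41) sits in between, and the biexponential
tissue coefficient `D` (0.81) is lower than every ADC. The large spread of
`d_star` reflects the well-known instability of pseudo-diffusion estimates
at this number of b values. The `report/` directory also contains the
pairwise percent-deviation matrix with Wilcoxon significance stars, the
Spearman correlation of each ADC against `D`, and per-lesion QC acceptance
rates.

The same analysis is available as a library:

```python
from ivimfit import PhantomSpec, generate_phantom, compute_maps

ds = generate_phantom(PhantomSpec(seed=1))
maps = compute_maps(ds)   # 13 ADC maps + D/D*/f_p/SI0 maps, QC applied
```

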