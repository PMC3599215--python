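"""Voxel-wise parameter-map computation with goodness-of-fit QC.

Every b-value combination scheme yields one apparent-diffusion-coefficient
(ADC) map from the monoexponential model; the full acquisition additionally
yields D, D* and fp maps from the biexponential IVIM model.  Each voxel is
fitted independently by Levenberg-Marquardt least squares (see
:mod:`ivimfit.estimators`); goodness of fit is summarized by the squared
Pearson correlation r^2 between measured and fitted signals and by the
summed squared residuals chi^2 of signals normalized to the lowest-b
amplitude.  Voxels with low r^2, high chi^2 or a non-converged fit are
excluded by the QC filter, independently per model: a voxel can pass the
mono fit and fail the biexponential one.

Default QC cut-offs are r^2 >= 0.50 and normalized chi^2 <= 0.20.  The
criteria are standard; the numeric values are this package's own declared
defaults, chosen so that noise-dominated voxels (whose flat magnitude signal
decorrelates from any decay model) are rejected while voxels that are merely
model-misspecified — monoexponential fits of strongly perfused tissue have
intrinsically depressed r^2 — are retained, giving near-total acceptance of
informative mono fits.  Both are configurable; strict settings such as
(0.98, 0.05) isolate only near-perfect fits.

Maps are fitted over the union of the dataset's lesion ROIs by default
(per-voxel analysis is only meaningful there); pass an explicit mask to fit
any other region, including the full grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__ as _pkg_version
from .errors import ConfigurationError
from .estimators import (
    IvimModel,
    MonoExponentialModel,
    r_squared_chi_squared,
    segmented_estimate,
)
from .models import IvimParams, MonoParams, VoxelSeries
from .schemes import BValueScheme, builtin_schemes, get_scheme  # noqa: F401

__all__ = [
    "FitResult",
    "QCThresholds",
    "ParameterMap",
    "fit_mono",
    "fit_biexp",
    "segmented_init",
    "goodness_of_fit",
    "qc_filter",
    "compute_maps",
    "write_maps",
    "builtin_schemes",
]


@dataclass(frozen=True)
class FitResult:
    """One voxel's fitted parameters plus goodness of fit."""

    params: object  # MonoParams or IvimParams
    r_squared: float  # nan when the measured signal has zero variance
    chi_squared: float  # normalized summed squared residuals
    converged: bool
    n_points: int


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion cut-offs applied to every voxel fit."""

    r2_min: float = 0.50
    chi2_max: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_min <= 1.0):
            raise ConfigurationError(f"r2_min must be in [0,1], got {self.r2_min}")
        if not self.chi2_max > 0:
            raise ConfigurationError(f"chi2_max must be > 0, got {self.chi2_max}")


@dataclass
class ParameterMap:
    """A fitted 3-D parameter map for one scheme.

    ``values`` is nan outside ``fit_mask``; ``qc_mask`` marks the subset of
    fitted voxels that passed QC.
    """

    scheme_id: str
    parameter: str  # adc | d | d_star | fp | si0
    values: np.ndarray
    qc_mask: np.ndarray
    fit_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.fit_mask is None:
            self.fit_mask = np.isfinite(self.values)


def _result_from_estimator(est, model_kind: str) -> FitResult:
    return FitResult(
        params=est.params_,
        r_squared=est.r_squared_,
        chi_squared=est.chi_squared_,
        converged=est.converged_,
        n_points=est.n_points_,
    )


def fit_mono(series: VoxelSeries, scheme: BValueScheme, pin_si0: bool = False) -> FitResult:
    """Fit the monoexponential model to one voxel under one scheme.

    The series must contain a signal for every b value of the scheme; extra
    acquired b values are ignored.  Pathological signal (all-zero/negative)
    yields ``converged=False`` rather than raising, so map computation never
    aborts mid-volume.
    """
    if scheme.model != "mono":
        raise ConfigurationError(f"scheme {scheme.id} is not a mono scheme")
    sub = series.subset(scheme.b_values)
    est = MonoExponentialModel(pin_si0=pin_si0).fit(
        np.asarray(sub.b_values), sub.signal
    )
    return _result_from_estimator(est, "mono")


def fit_biexp(series: VoxelSeries, scheme: BValueScheme, init="segmented",
              pin_si0: bool = False) -> FitResult:
    """Fit the biexponential IVIM model to one voxel (>= 4 distinct b values).

    ``init`` is ``"segmented"`` or a fixed :class:`~ivimfit.models.IvimParams`.
    Raises ``ValueError`` when the scheme has fewer than 4 points (precondition
    of the model); optimizer failure is reported via ``converged=False`` with
    best-effort parameters retained.
    """
    if scheme.model != "biexp":
        raise ConfigurationError(f"scheme {scheme.id} is not a biexp scheme")
    sub = series.subset(scheme.b_values)
    est = IvimModel(init=init, pin_si0=pin_si0).fit(
        np.asarray(sub.b_values), sub.signal
    )
    return _result_from_estimator(est, "biexp")


def segmented_init(series: VoxelSeries, b_threshold: float = 250.0):
    """Segmented starting estimate for the IVIM fit.

    Returns ``(IvimParams, fell_back)``; see
    :func:`ivimfit.estimators.segmented_estimate` for the procedure and the
    fallback default used when a segment has too few points.
    """
    return segmented_estimate(
        np.asarray(series.b_values), series.signal, b_threshold
    )


def goodness_of_fit(series: VoxelSeries, fitted: FitResult):
    """(r^2, normalized chi^2) of a fit re-evaluated against a series."""
    from .models import biexp_signal, mono_signal

    b = np.asarray(series.b_values)
    if isinstance(fitted.params, IvimParams):
        pred = biexp_signal(fitted.params, b)
    else:
        pred = mono_signal(fitted.params, b)
    ref = float(series.signal[np.argmin(b)])
    if ref <= 0:
        ref = float(np.max(series.signal, initial=0.0)) or None
    return r_squared_chi_squared(series.signal, pred, ref)


def qc_filter(map_fits, thresholds: QCThresholds):
    """Apply QC to a sequence of fits.

    A voxel passes iff its fit converged, r^2 is defined and >= ``r2_min``,
    and chi^2 <= ``chi2_max``.  Returns ``(mask, report)`` where ``mask`` is
    a boolean array over the input order and ``report`` counts exclusions by
    cause (a voxel is counted once, by the first failing criterion in the
    order above).
    """
    mask = np.zeros(len(map_fits), dtype=bool)
    report = {"n_total": len(map_fits), "n_not_converged": 0,
              "n_low_r2": 0, "n_high_chi2": 0}
    for i, f in enumerate(map_fits):
        if not f.converged:
            report["n_not_converged"] += 1
        elif not (np.isfinite(f.r_squared) and f.r_squared >= thresholds.r2_min):
            report["n_low_r2"] += 1
        elif not f.chi_squared <= thresholds.chi2_max:
            report["n_high_chi2"] += 1
        else:
            mask[i] = True
    report["n_pass"] = int(mask.sum())
    report["fraction_pass"] = (
        report["n_pass"] / report["n_total"] if report["n_total"] else float("nan")
    )
    return mask, report


def _check_scheme_bvalues(scheme: BValueScheme, acquired) -> np.ndarray:
    idx = []
    for b in scheme.b_values:
        matches = [i for i, ab in enumerate(acquired) if float(ab) == float(b)]
        if not matches:
            raise ConfigurationError(
                f"scheme {scheme.id} requests b={b:g} s/mm^2 which was not "
                f"acquired (acquisition: {tuple(acquired)})"
            )
        idx.append(matches[0])
    return np.asarray(idx)


def compute_maps(ds, schemes=None, thresholds: QCThresholds | None = None,
                 init="segmented", mask=None, pin_si0: bool = False):
    """Fit every requested scheme voxel-by-voxel and return parameter maps.

    Parameters
    ----------
    ds : PhantomDataset or compatible
        Needs ``signal`` (4-D), ``b_values`` and (for the default mask)
        ``roi_masks``.
    schemes : list of BValueScheme, optional
        Defaults to the full built-in registry (13 mono + B0_biexp).
    thresholds : QCThresholds, optional
    init : "segmented" or IvimParams
        Initialization strategy for the biexponential fits.
    mask : 3-D bool array, optional
        Voxels to fit; defaults to the union of the dataset's lesion ROIs.

    Returns
    -------
    list of ParameterMap
        One ``adc`` map per mono scheme and, per biexp scheme, one map for
        each of ``d``, ``d_star``, ``fp`` and ``si0`` (sharing one QC mask).
        Voxel order and masks are consistent across schemes.
    """
    schemes = list(builtin_schemes()) if schemes is None else list(schemes)
    thresholds = thresholds or QCThresholds()
    signal = np.asarray(ds.signal, dtype=float)
    acquired = tuple(float(b) for b in ds.b_values)
    if mask is None:
        roi_masks = getattr(ds, "roi_masks", None)
        if roi_masks:
            mask = np.zeros(signal.shape[:3], dtype=bool)
            for m in roi_masks:
                mask |= m
        else:
            mask = np.ones(signal.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    vox = signal[mask]  # (n_vox, n_b)

    maps: list[ParameterMap] = []
    for scheme in schemes:
        idx = _check_scheme_bvalues(scheme, acquired)
        b = np.asarray(scheme.b_values)
        sub = vox[:, idx]
        if scheme.model == "mono":
            est = MonoExponentialModel(pin_si0=pin_si0)
            fits = [
                _result_from_estimator(est.fit(b, sub[i]), "mono")
                for i in range(sub.shape[0])
            ]
            qc_flat, report = qc_filter(fits, thresholds)
            values = np.full(signal.shape[:3], np.nan)
            values[tuple(coords.T)] = [f.params.adc for f in fits]
            qc = np.zeros(signal.shape[:3], dtype=bool)
            qc[tuple(coords.T)] = qc_flat
            maps.append(ParameterMap(scheme.id, "adc", values, qc, mask.copy()))
        else:
            est = IvimModel(init=init, pin_si0=pin_si0)
            fits = [
                _result_from_estimator(est.fit(b, sub[i]), "biexp")
                for i in range(sub.shape[0])
            ]
            qc_flat, report = qc_filter(fits, thresholds)
            qc = np.zeros(signal.shape[:3], dtype=bool)
            qc[tuple(coords.T)] = qc_flat
            for pname in ("d", "d_star", "fp", "si0"):
                values = np.full(signal.shape[:3], np.nan)
                values[tuple(coords.T)] = [
                    getattr(f.params, pname) for f in fits
                ]
                maps.append(
                    ParameterMap(scheme.id, pname, values, qc.copy(), mask.copy())
                )
    return maps


def write_maps(maps, outdir, thresholds: QCThresholds | None = None,
               init="segmented", seed=None) -> Path:
    """Write each map as NIfTI plus a JSON sidecar with provenance
    (scheme, parameter, QC thresholds, init strategy, package version, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or QCThresholds()
    for m in maps:
        stem = f"{m.scheme_id}_{m.parameter}"
        nib.save(nib.Nifti1Image(m.values, np.eye(4)), outdir / f"{stem}.nii.gz")
        nib.save(
            nib.Nifti1Image(m.qc_mask.astype(np.uint8), np.eye(4)),
            outdir / f"{stem}_qc.nii.gz",
        )
        sidecar = {
            "scheme_id": m.scheme_id,
            "parameter": m.parameter,
            "qc_thresholds": {"r2_min": thresholds.r2_min,
                              "chi2_max": thresholds.chi2_max},
            "init": init if isinstance(init, str) else "fixed",
            "software": {"name": "ivimfit", "version": _pkg_version},
            "seed": seed,
            "units": "mm^2/s" if m.parameter in ("adc", "d", "d_star") else
                     ("dimensionless" if m.parameter == "fp" else "a.u."),
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return outdir


def read_maps(indir):
    """Load parameter maps written by :func:`write_maps` (registry order)."""
    indir = Path(indir)
    maps = []
    for sidecar in sorted(indir.glob("*.json")):
        meta = json.loads(sidecar.read_text())
        stem = sidecar.stem
        values = np.asarray(nib.load(indir / f"{stem}.nii.gz").get_fdata())
        qc = np.asarray(nib.load(indir / f"{stem}_qc.nii.gz").get_fdata()) > 0.5
        maps.append(
            ParameterMap(meta["scheme_id"], meta["parameter"], values, qc)
        )
    order = {s.id: i for i, s in enumerate(builtin_schemes())}
    maps.sort(key=lambda m: (order.get(m.scheme_id, 99), m.parameter))
    return maps
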