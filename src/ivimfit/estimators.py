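"""Scikit-learn style estimators for per-voxel signal-decay fitting.

Both estimators follow the sklearn regressor contract: hyperparameters in
``__init__`` (inspectable through ``get_params``/``set_params``), a
``fit(b, signal)`` method that stores fitted quantities in trailing-underscore
attributes, and ``predict(b)`` returning model signal amplitudes.  ``X`` is
the vector of diffusion weightings (s/mm^2, shape ``(n,)`` or ``(n, 1)``) and
``y`` the measured signal, so the estimators compose with sklearn pipelines
and model-selection utilities.

Fitting is Levenberg-Marquardt least squares in linear signal space: the
monoexponential fit uses MINPACK LM directly (no bounds are needed), the
biexponential fit uses lmfit's MINPACK backend, which handles the parameter
bounds 0 <= D <= D*, 0 <= fp <= 1 through the MPFIT-style bound
transformation.  Log-linear regression appears only inside initialization.

Pathological voxels (all-zero or negative signal) never raise during a map
computation; they produce a result with ``converged_ = False`` that the QC
stage excludes.
"""

from __future__ import annotations

import numpy as np
import lmfit
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .models import IvimParams, MonoParams

__all__ = ["MonoExponentialModel", "IvimModel", "r_squared_chi_squared"]

_LOG_FLOOR = 1e-12


def _as_b_signal(X, y):
    b = np.asarray(X, dtype=float)
    if b.ndim == 2 and b.shape[1] == 1:
        b = b[:, 0]
    if b.ndim != 1:
        raise ValueError(f"b must be 1-D (or a single column), got shape {b.shape}")
    s = np.asarray(y, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"signal shape {s.shape} does not match b shape {b.shape}")
    if np.any(b < 0):
        raise ValueError("b values must be non-negative")
    if len(np.unique(b)) != b.size:
        raise ValueError("b values must be distinct")
    return b, s


def r_squared_chi_squared(measured, predicted, normalize_by=None):
    """Goodness of fit: squared Pearson correlation and summed squared residuals.

    chi^2 is computed on signals normalized by ``normalize_by`` (typically the
    measured signal at the lowest b value) so that QC thresholds are
    scale-free; pass ``None`` to skip normalization.  A zero-variance measured
    signal makes r^2 undefined; ``nan`` is returned and the voxel is left to
    the QC stage to exclude.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    resid = measured - predicted
    if normalize_by is not None and normalize_by > 0:
        chi2 = float(np.sum((resid / normalize_by) ** 2))
    else:
        chi2 = float(np.sum(resid**2))
    sm = measured - measured.mean()
    sp = predicted - predicted.mean()
    denom = np.sqrt(np.sum(sm**2) * np.sum(sp**2))
    if denom == 0.0:
        return float("nan"), chi2
    r = float(np.sum(sm * sp) / denom)
    # guard tiny numerical overshoot of |r| past 1
    return min(r * r, 1.0), chi2


def _signal_reference(b, s):
    """Scale reference for normalized chi^2: measured signal at the lowest b."""
    ref = float(s[np.argmin(b)])
    if ref <= 0:
        ref = float(np.max(s, initial=0.0))
    return ref if ref > 0 else None


class MonoExponentialModel(RegressorMixin, BaseEstimator):
    """Monoexponential decay fit, ``SI(b) = SI0 * exp(-b * ADC)``.

    Parameters
    ----------
    pin_si0 : bool, default False
        If True, SI0 is pinned to the measured signal at the lowest acquired
        b value and only ADC is optimized; otherwise both are free.

    Attributes
    ----------
    si0_, adc_ : float
        Fitted amplitude (a.u.) and apparent diffusion coefficient (mm^2/s).
    params_ : MonoParams
    r_squared_ : float
        Squared Pearson correlation of measured vs fitted signal (nan if the
        measured signal has zero variance).
    chi_squared_ : float
        Summed squared residuals of signals normalized by the measured
        lowest-b amplitude (scale-free).
    converged_ : bool
    n_points_ : int
    """

    def __init__(self, pin_si0: bool = False):
        self.pin_si0 = pin_si0

    def fit(self, X, y):
        b, s = _as_b_signal(X, y)
        if b.size < 2:
            raise ValueError("monoexponential fit needs >= 2 b values")
        self.n_points_ = int(b.size)

        ok = s > 0
        if ok.sum() < 2:
            # noise-dominated voxel: no log-linear chord exists
            self.si0_ = max(float(np.mean(np.abs(s))), _LOG_FLOOR)
            self.adc_ = 0.0
            self.converged_ = False
            self._finalize(b, s)
            return self

        slope, icpt = np.polyfit(b[ok], np.log(s[ok]), 1)
        si0_init = float(np.exp(icpt))
        adc_init = float(-slope)

        if self.pin_si0:
            si0 = _signal_reference(b, s)

            def resid(p):
                return si0 * np.exp(-b * p[0]) - s

            sol = least_squares(resid, [adc_init], method="lm", xtol=1e-14, ftol=1e-14)
            self.si0_, self.adc_ = float(si0), float(sol.x[0])
        else:

            def resid(p):
                return p[0] * np.exp(-b * p[1]) - s

            sol = least_squares(
                resid, [si0_init, adc_init], method="lm", xtol=1e-14, ftol=1e-14
            )
            self.si0_, self.adc_ = float(sol.x[0]), float(sol.x[1])

        self.converged_ = bool(sol.success) and self.si0_ > 0
        if self.si0_ <= 0:
            self.si0_ = _LOG_FLOOR
        self._finalize(b, s)
        return self

    def _finalize(self, b, s):
        self.params_ = MonoParams(si0=self.si0_, adc=self.adc_)
        pred = self.si0_ * np.exp(-b * self.adc_)
        self.r_squared_, self.chi_squared_ = r_squared_chi_squared(
            s, pred, _signal_reference(b, s)
        )

    def predict(self, X):
        b = np.asarray(X, dtype=float)
        if b.ndim == 2 and b.shape[1] == 1:
            b = b[:, 0]
        return self.si0_ * np.exp(-b * self.adc_)


def segmented_estimate(b, s, b_threshold=250.0):
    """Segmented IVIM initialization.

    D is taken from a log-linear fit over the perfusion-free regime
    ``b >= b_threshold``; fp from one minus the ratio of the back-extrapolated
    high-b intercept to the measured lowest-b signal; D* is seeded at a fixed
    multiple (10x) of D.  All values are clipped into the fit bounds.

    Returns ``(params, fell_back)`` where ``fell_back`` flags that a segment
    had too few points and the documented default initialization
    (D=1e-3, D*=1e-2 mm^2/s, fp=0.1) was used instead.
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)
    hi = b >= b_threshold
    lo = ~hi
    s0 = float(s[np.argmin(b)])
    if s0 <= 0:
        s0 = max(float(np.max(s, initial=0.0)), _LOG_FLOOR)
    if hi.sum() < 2 or lo.sum() < 1:
        return IvimParams(si0=s0, d=1e-3, d_star=1e-2, fp=0.1), True

    slope, icpt = np.polyfit(b[hi], np.log(np.maximum(s[hi], _LOG_FLOOR)), 1)
    d0 = float(np.clip(-slope, 1e-6, 5e-3))
    fp0 = float(np.clip(1.0 - np.exp(icpt) / s0, 1e-4, 0.95))
    return IvimParams(si0=s0, d=d0, d_star=10.0 * d0, fp=fp0), False


class IvimModel(RegressorMixin, BaseEstimator):
    """Biexponential IVIM fit with bound constraints.

    Minimizes the full-model squared residuals over (SI0, D, D*, fp) with
    Levenberg-Marquardt, subject to ``0 <= D <= d_max``,
    ``D <= D* <= D + d_star_max`` and ``0 <= fp <= 1``.  The ordering
    constraint D <= D* is enforced by optimizing the non-negative gap
    ``D* - D``.  The bounds are wide enough to contain all parameter values
    reported for malignant breast lesions (D up to 1.6e-3, D* up to
    72e-3 mm^2/s, fp up to 0.55); unbounded IVIM fits are notoriously
    degenerate.

    Parameters
    ----------
    init : "segmented" or IvimParams, default "segmented"
        Starting point strategy.  "segmented" estimates D and fp from the
        high-b log-linear segment (see :func:`segmented_estimate`); a fixed
        IvimParams reproduces pathological cases deterministically.
    b_threshold : float, default 250.0
        Low/high-b split for the segmented initialization, s/mm^2 (the
        largest sub-maximal weighting of the emulated acquisition).
    d_max, d_star_max : float
        Upper bounds for D and for the gap D* - D, mm^2/s.
    pin_si0 : bool, default False
        Pin SI0 to the measured lowest-b signal instead of fitting it.

    Attributes
    ----------
    si0_, d_, d_star_, fp_ : float
    params_ : IvimParams
    r_squared_, chi_squared_ : float
        As in :class:`MonoExponentialModel`.
    converged_ : bool
        False when the optimizer fails or the solution is pinned at an upper
        bound (d = d_max, gap = d_star_max or fp = 1), which marks a
        degenerate fit; fp = 0 or D* = D are legitimate single-compartment
        limits and stay converged.
    init_fell_back_ : bool
        True when the segmented initialization lacked points and the default
        start was used.
    """

    def __init__(
        self,
        init="segmented",
        b_threshold: float = 250.0,
        d_max: float = 5e-3,
        d_star_max: float = 0.5,
        pin_si0: bool = False,
    ):
        self.init = init
        self.b_threshold = b_threshold
        self.d_max = d_max
        self.d_star_max = d_star_max
        self.pin_si0 = pin_si0

    def _initial(self, b, s):
        if isinstance(self.init, IvimParams):
            return self.init, False
        if self.init == "segmented":
            return segmented_estimate(b, s, self.b_threshold)
        raise ValueError(f"init must be 'segmented' or IvimParams, got {self.init!r}")

    def fit(self, X, y):
        b, s = _as_b_signal(X, y)
        if b.size < 4:
            raise ValueError(
                f"biexponential fit needs >= 4 distinct b values, got {b.size}"
            )
        self.n_points_ = int(b.size)
        start, self.init_fell_back_ = self._initial(b, s)

        if not np.any(s > 0):
            self.si0_, self.d_, self.d_star_, self.fp_ = _LOG_FLOOR, 1e-3, 1e-2, 0.0
            self.converged_ = False
            self._finalize(b, s)
            return self

        pars = lmfit.Parameters()
        pars.add("si0", value=max(start.si0, _LOG_FLOOR), min=0.0,
                 vary=not self.pin_si0)
        pars.add("d", value=float(np.clip(start.d, 0.0, self.d_max)),
                 min=0.0, max=self.d_max)
        pars.add("gap", value=float(np.clip(start.d_star - start.d, 1e-6,
                                            self.d_star_max)),
                 min=0.0, max=self.d_star_max)
        pars.add("d_star", expr="d + gap")
        pars.add("fp", value=float(np.clip(start.fp, 0.0, 1.0)), min=0.0, max=1.0)

        def resid(p):
            return (
                p["si0"]
                * ((1 - p["fp"]) * np.exp(-b * p["d"])
                   + p["fp"] * np.exp(-b * p["d_star"]))
                - s
            )

        out = lmfit.minimize(resid, pars, method="leastsq", xtol=1e-13, ftol=1e-13)
        v = out.params.valuesdict()
        self.si0_ = float(max(v["si0"], _LOG_FLOOR))
        self.d_ = float(v["d"])
        self.d_star_ = float(v["d_star"])
        self.fp_ = float(v["fp"])

        pinned_high = (
            self.d_ >= self.d_max * (1 - 1e-9)
            or v["gap"] >= self.d_star_max * (1 - 1e-9)
            or self.fp_ >= 1.0 - 1e-12
        )
        self.converged_ = bool(out.success) and not pinned_high
        self._finalize(b, s)
        return self

    def _finalize(self, b, s):
        self.params_ = IvimParams(
            si0=self.si0_, d=self.d_, d_star=self.d_star_, fp=self.fp_
        )
        pred = self.predict(b)
        self.r_squared_, self.chi_squared_ = r_squared_chi_squared(
            s, pred, _signal_reference(b, s)
        )

    def predict(self, X):
        b = np.asarray(X, dtype=float)
        if b.ndim == 2 and b.shape[1] == 1:
            b = b[:, 0]
        return self.si0_ * (
            (1 - self.fp_) * np.exp(-b * self.d_)
            + self.fp_ * np.exp(-b * self.d_star_)
        )
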