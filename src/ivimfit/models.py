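"""Closed-form diffusion signal models.

The monoexponential model describes the diffusion-weighted MRI signal of a
single water compartment,

    SI(b) = SI0 * exp(-b * ADC),

where ``b`` (s/mm^2) is the diffusion weighting and ADC (mm^2/s) the apparent
diffusion coefficient.  The intravoxel-incoherent-motion (IVIM) model adds a
vascular pseudo-diffusion compartment of volume fraction ``fp``,

    SI(b) = SI0 * [(1 - fp) * exp(-b * D) + fp * exp(-b * D*)],

with tissue diffusion coefficient D and pseudo-diffusion coefficient D*
(both mm^2/s, D <= D*).  All diffusivities are carried in mm^2/s internally;
the conventional 1e-3 mm^2/s display scale is applied only when rendering
reports.  Signals are kept in linear (not log) space because magnitude-MRI
noise is additive there.

This module is pure computation: the functions here are the phantom's
generative core and the fitters' objective functions and closed-form oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MonoParams",
    "IvimParams",
    "VoxelSeries",
    "mono_signal",
    "biexp_signal",
    "two_point_adc",
]


@dataclass(frozen=True)
class MonoParams:
    """Parameters of the monoexponential decay.

    Attributes
    ----------
    si0 : float
        Unweighted (b=0) signal amplitude, arbitrary units; must be > 0.
    adc : float
        Apparent diffusion coefficient, mm^2/s.  May be negative for
        noise-dominated voxels; such voxels are flagged downstream by QC.
    """

    si0: float
    adc: float

    def __post_init__(self) -> None:
        if not (self.si0 > 0):
            raise ValueError(f"si0 must be positive, got {self.si0}")
        if not math.isfinite(self.adc):
            raise ValueError(f"adc must be finite, got {self.adc}")


@dataclass(frozen=True)
class IvimParams:
    """Parameters of the biexponential (IVIM) decay.

    Attributes
    ----------
    si0 : float
        Unweighted signal amplitude, arbitrary units; must be > 0.
    d : float
        Tissue diffusion coefficient, mm^2/s; 0 <= d <= d_star.
    d_star : float
        Pseudo-diffusion coefficient of the vascular compartment, mm^2/s.
    fp : float
        Perfusion (vascular volume) fraction, dimensionless in [0, 1].
    """

    si0: float
    d: float
    d_star: float
    fp: float

    def __post_init__(self) -> None:
        if not (self.si0 > 0):
            raise ValueError(f"si0 must be positive, got {self.si0}")
        if not (0.0 <= self.d <= self.d_star):
            raise ValueError(
                f"require 0 <= d <= d_star, got d={self.d}, d_star={self.d_star}"
            )
        if not (0.0 <= self.fp <= 1.0):
            raise ValueError(f"fp must lie in [0, 1], got {self.fp}")


@dataclass(frozen=True)
class VoxelSeries:
    """Measured signal of one voxel across the acquired b values."""

    b_values: tuple[float, ...]
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        if sig.ndim != 1 or sig.size != len(self.b_values):
            raise ValueError(
                f"signal length {sig.size} does not match "
                f"{len(self.b_values)} b values"
            )

    def subset(self, b_values) -> "VoxelSeries":
        """Restrict the series to the given b values (all must be acquired)."""
        idx = []
        for b in b_values:
            try:
                idx.append(self.b_values.index(float(b)))
            except ValueError:
                raise ValueError(
                    f"b={b} s/mm^2 was not acquired (available: {self.b_values})"
                ) from None
        return VoxelSeries(tuple(self.b_values[i] for i in idx), self.signal[idx])


def mono_signal(params: MonoParams, b):
    """Monoexponential signal SI0 * exp(-b * ADC).

    ``b`` may be a scalar or array of non-negative diffusion weightings
    (s/mm^2); the result has the same shape.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b values must be non-negative")
    out = params.si0 * np.exp(-b * params.adc)
    return out if out.ndim else float(out)


def biexp_signal(params: IvimParams, b):
    """Biexponential IVIM signal.

    Evaluates ``SI0 * [(1-fp) exp(-b D) + fp exp(-b D*)]``.  Reduces exactly
    to :func:`mono_signal` with ``adc=d`` when ``fp == 0`` or ``d_star == d``.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b values must be non-negative")
    out = params.si0 * (
        (1.0 - params.fp) * np.exp(-b * params.d)
        + params.fp * np.exp(-b * params.d_star)
    )
    return out if out.ndim else float(out)


def two_point_adc(si_a: float, b_a: float, si_b: float, b_b: float) -> float:
    """Exact ADC through two signal measurements.

    Solves the monoexponential model through the points ``(b_a, si_a)`` and
    ``(b_b, si_b)``:  ``ADC = ln(si_a / si_b) / (b_b - b_a)``.  This is the
    closed-form chord slope used as the analytic oracle for every two-b-value
    scheme.

    Raises
    ------
    ValueError
        If a signal is non-positive (noise-corrupted voxel) or the b values
        are not strictly ordered ``b_b > b_a``.
    """
    if si_a <= 0 or si_b <= 0:
        raise ValueError(
            f"signals must be positive for a log-ratio ADC, got ({si_a}, {si_b})"
        )
    if not b_b > b_a:
        raise ValueError(f"require b_b > b_a, got b_a={b_a}, b_b={b_b}")
    return math.log(si_a / si_b) / (b_b - b_a)
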