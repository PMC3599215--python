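"""Registry of b-value combination schemes.

The study acquisition uses b = 0, 50, 100, 250, 800 s/mm^2.  Thirteen
monoexponential combinations B0..B12 are defined over subsets of these,
plus the full-acquisition biexponential scheme ``B0_biexp``.  B0..B5 are
the combinations with current clinical relevance (they all include the
highest weighting b=800); B6..B12 probe the perfusion-sensitive low-b
regime.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["BValueScheme", "STUDY_BVALUES", "builtin_schemes", "get_scheme"]

#: Acquired diffusion weightings of the emulated protocol, s/mm^2.
STUDY_BVALUES: tuple[float, ...] = (0.0, 50.0, 100.0, 250.0, 800.0)


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings defining one calculation variant.

    Attributes
    ----------
    id : str
        Short label, e.g. ``"B4"`` or ``"B0_biexp"``.
    b_values : tuple of float
        Strictly increasing, non-negative weightings in s/mm^2.  At least 2
        for the mono model, at least 4 for the biexponential model.
    model : str
        ``"mono"`` or ``"biexp"``.
    clinical : bool
        Whether the combination is flagged as clinically relevant (B0-B5).
    """

    id: str
    b_values: tuple[float, ...]
    model: str = "mono"
    clinical: bool = False

    def __post_init__(self) -> None:
        bv = tuple(float(b) for b in self.b_values)
        object.__setattr__(self, "b_values", bv)
        if self.model not in ("mono", "biexp"):
            raise ValueError(f"model must be 'mono' or 'biexp', got {self.model!r}")
        if any(b < 0 for b in bv):
            raise ValueError(f"b values must be non-negative: {bv}")
        if any(b2 <= b1 for b1, b2 in zip(bv, bv[1:])):
            raise ValueError(f"b values must be strictly increasing: {bv}")
        n_min = 2 if self.model == "mono" else 4
        if len(bv) < n_min:
            raise ValueError(
                f"{self.model} scheme needs >= {n_min} b values, got {len(bv)}"
            )


_TABLE = [
    ("B0", (0, 50, 100, 250, 800), "mono", True),
    ("B1", (0, 800), "mono", True),
    ("B2", (50, 800), "mono", True),
    ("B3", (50, 100, 250, 800), "mono", True),
    ("B4", (100, 250, 800), "mono", True),
    ("B5", (100, 800), "mono", True),
    ("B6", (250, 800), "mono", False),
    ("B7", (0, 50), "mono", False),
    ("B8", (0, 100), "mono", False),
    ("B9", (0, 250), "mono", False),
    ("B10", (50, 100), "mono", False),
    ("B11", (50, 250), "mono", False),
    ("B12", (100, 250), "mono", False),
    ("B0_biexp", (0, 50, 100, 250, 800), "biexp", False),
]


def builtin_schemes() -> list[BValueScheme]:
    """The 13 monoexponential combinations B0-B12 plus B0_biexp.

    Returned in registry order (B0..B12, then B0_biexp), which is also the
    deterministic row/column order used by the cohort report.
    """
    return [BValueScheme(i, b, m, c) for i, b, m, c in _TABLE]


def get_scheme(scheme_id: str) -> BValueScheme:
    """Look up a built-in scheme by its label.

    Raises :class:`~ivimfit.errors.ConfigurationError` for unknown labels.
    """
    for s in builtin_schemes():
        if s.id == scheme_id:
            return s
    raise ConfigurationError(
        f"unknown scheme {scheme_id!r}; known: {[s.id for s in builtin_schemes()]}"
    )
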