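"""Synthetic 4-D diffusion-weighted phantom with known ground truth.

The generator emulates the study acquisition the rest of the pipeline is
built for: a magnitude DWI stack at b = 0, 50, 100, 250 and 800 s/mm^2 (one
3-D volume per weighting, trace-averaged over directions, i.e. isotropic
diffusion) containing a cohort of spherical lesions whose voxels decay
biexponentially with per-lesion IVIM parameters drawn from the ranges
reported for malignant breast lesions: D in [0.2, 1.6]e-3 mm^2/s, D* in
[4.3, 72.1]e-3 mm^2/s, fp in [0.05, 0.55].  The default cohort size is 24
lesions.  Background tissue is a perfusion-free compartment with
D = 1.8e-3 mm^2/s, in the range reported for normal breast parenchyma.

Noise is Rician by default (magnitude reconstruction of complex Gaussian
noise), with sigma = si0 / snr defined at b = 0; Gaussian and noise-free
variants exist for analytic tests.  Identical spec + seed yields a
bit-identical dataset.

On disk a dataset is a directory of uncompressed-or-gzipped NIfTI volumes
(4-D signal, per-lesion 3-D masks, per-parameter truth maps), an FSL-style
whitespace-separated ``dwi.bval`` sidecar, and a ``meta.json`` with seed and
noise provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, ParseError
from .models import IvimParams
from .schemes import STUDY_BVALUES

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "add_noise",
    "write_dataset",
    "read_dataset",
]

#: Per-lesion uniform sampling ranges bracketing the reported cohort spread.
DEFAULT_D_RANGE = (0.2e-3, 1.6e-3)
DEFAULT_D_STAR_RANGE = (4.3e-3, 72.1e-3)
DEFAULT_FP_RANGE = (0.05, 0.55)

#: Perfusion-free background tissue (normal-parenchyma-like diffusivity).
DEFAULT_BACKGROUND = IvimParams(si0=1000.0, d=1.8e-3, d_star=1.8e-3, fp=0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic dataset.

    ``lesion_params`` may be None (per-lesion parameters drawn uniformly from
    the ``*_range`` fields), a single :class:`IvimParams` applied to every
    lesion, or a sequence of one :class:`IvimParams` per lesion.
    ``lesion_centers`` may be None (non-overlapping centers placed by a
    seeded sampler) or explicit voxel coordinates, which are then validated
    for overlap and grid containment.
    """

    grid_shape: tuple[int, int, int] = (36, 36, 9)
    n_lesions: int = 24
    lesion_radius: float = 2.0
    lesion_centers: tuple | None = None
    lesion_params: object = None
    d_range: tuple[float, float] = DEFAULT_D_RANGE
    d_star_range: tuple[float, float] = DEFAULT_D_STAR_RANGE
    fp_range: tuple[float, float] = DEFAULT_FP_RANGE
    background: IvimParams = DEFAULT_BACKGROUND
    si0: float = 1000.0
    b_values: tuple[float, ...] = STUDY_BVALUES
    snr: float = 50.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive ints: {self.grid_shape}")
        if self.n_lesions < 0:
            raise ConfigurationError("n_lesions must be >= 0")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ConfigurationError(
                f"noise_model must be rician|gaussian|none, got {self.noise_model!r}"
            )
        if self.noise_model != "none" and not self.snr > 0:
            raise ConfigurationError("snr must be > 0 when noise is enabled")
        if self.si0 <= 0:
            raise ConfigurationError("si0 must be positive")
        bv = tuple(float(b) for b in self.b_values)
        object.__setattr__(self, "b_values", bv)
        if any(b2 <= b1 for b1, b2 in zip(bv, bv[1:])) or any(b < 0 for b in bv):
            raise ConfigurationError(f"b_values must be non-negative increasing: {bv}")


@dataclass
class PhantomDataset:
    """A generated (or loaded) 4-D DWI dataset with ground truth."""

    signal: np.ndarray  # (nx, ny, nz, n_b)
    b_values: tuple[float, ...]
    roi_masks: list[np.ndarray]  # per-lesion boolean (nx, ny, nz)
    truth: dict[str, np.ndarray]  # parameter name -> (nx, ny, nz) map
    seed: int
    snr: float | None = None
    noise_model: str = "none"
    lesion_params: list[IvimParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ParseError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != len(self.b_values):
            raise ParseError(
                f"b-value table length {len(self.b_values)} does not match "
                f"signal's 4th dimension {self.signal.shape[3]}"
            )
        for i, m in enumerate(self.roi_masks):
            if m.shape != self.signal.shape[:3]:
                raise ParseError(f"mask {i} shape {m.shape} mismatches signal grid")
            if not m.any():
                raise ParseError(f"lesion mask {i} is empty")

    @property
    def roi_union(self) -> np.ndarray:
        out = np.zeros(self.signal.shape[:3], dtype=bool)
        for m in self.roi_masks:
            out |= m
        return out


def add_noise(signal, snr, noise_model, seed, si0_ref=None):
    """Apply magnitude-MRI noise to a clean signal array.

    For ``rician`` the output is ``sqrt((s + n1)^2 + n2^2)`` with n1, n2
    independent zero-mean Gaussians of sigma = ``si0_ref / snr``; for
    ``gaussian`` it is ``s + n1``; ``none`` returns a copy.  ``si0_ref``
    defaults to the array maximum (the unweighted amplitude in a phantom).
    Deterministic under a fixed seed; noise is drawn independently per voxel
    and per b value.
    """
    signal = np.asarray(signal, dtype=float)
    if noise_model == "none":
        return signal.copy()
    if noise_model not in ("rician", "gaussian"):
        raise ConfigurationError(f"unknown noise_model {noise_model!r}")
    if not snr > 0:
        raise ConfigurationError("snr must be > 0")
    if si0_ref is None:
        si0_ref = float(np.max(signal))
    sigma = float(si0_ref) / float(snr)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    if noise_model == "gaussian":
        return signal + n1
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator):
    """Non-overlapping lesion centers, rejection-sampled or user-supplied."""
    r = spec.lesion_radius
    lo = int(np.ceil(r))
    if spec.lesion_centers is not None:
        centers = [tuple(float(c) for c in ctr) for ctr in spec.lesion_centers]
        if len(centers) != spec.n_lesions:
            raise ConfigurationError(
                f"{len(centers)} centers given for {spec.n_lesions} lesions"
            )
    else:
        centers = []
        for _ in range(10000):
            if len(centers) == spec.n_lesions:
                break
            cand = tuple(
                rng.uniform(lo, n - 1 - lo) if n - 1 - lo > lo else (n - 1) / 2.0
                for n in spec.grid_shape
            )
            if all(
                sum((a - b) ** 2 for a, b in zip(cand, c)) > (2 * r + 1) ** 2
                for c in centers
            ):
                centers.append(cand)
        if len(centers) < spec.n_lesions:
            raise ConfigurationError(
                f"could not place {spec.n_lesions} non-overlapping lesions of "
                f"radius {r} in grid {spec.grid_shape}"
            )
    # containment + overlap validation (also covers user-supplied centers)
    for i, c in enumerate(centers):
        if any(x - r < -0.5 or x + r > n - 0.5 for x, n in zip(c, spec.grid_shape)):
            raise ConfigurationError(f"lesion {i} at {c} extends outside the grid")
        for j in range(i):
            if sum((a - b) ** 2 for a, b in zip(c, centers[j])) <= (2 * r) ** 2:
                raise ConfigurationError(f"lesions {j} and {i} overlap")
    return centers


def _lesion_param_list(spec: PhantomSpec, rng: np.random.Generator):
    if spec.lesion_params is None:
        out = []
        for _ in range(spec.n_lesions):
            d = rng.uniform(*spec.d_range)
            d_star = rng.uniform(*spec.d_star_range)
            fp = rng.uniform(*spec.fp_range)
            out.append(IvimParams(si0=spec.si0, d=d, d_star=d_star, fp=fp))
        return out
    if isinstance(spec.lesion_params, IvimParams):
        return [spec.lesion_params] * spec.n_lesions
    params = list(spec.lesion_params)
    if len(params) != spec.n_lesions:
        raise ConfigurationError(
            f"{len(params)} lesion_params given for {spec.n_lesions} lesions"
        )
    return params


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate a 4-D DWI dataset whose noiseless signal is exactly the
    biexponential forward model of the per-voxel truth maps."""
    ss = np.random.SeedSequence([int(spec.seed), 0x1D1])
    rng = np.random.default_rng(ss)
    centers = _place_lesions(spec, rng)
    lesion_params = _lesion_param_list(spec, rng)

    nx, ny, nz = spec.grid_shape
    bg = spec.background
    truth = {
        "si0": np.full(spec.grid_shape, bg.si0),
        "d": np.full(spec.grid_shape, bg.d),
        "d_star": np.full(spec.grid_shape, bg.d_star),
        "fp": np.full(spec.grid_shape, bg.fp),
    }
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    roi_masks = []
    for c, p in zip(centers, lesion_params):
        mask = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2 <= (
            spec.lesion_radius**2
        )
        roi_masks.append(mask)
        truth["si0"][mask] = p.si0
        truth["d"][mask] = p.d
        truth["d_star"][mask] = p.d_star
        truth["fp"][mask] = p.fp

    b = np.asarray(spec.b_values)
    clean = truth["si0"][..., None] * (
        (1 - truth["fp"])[..., None] * np.exp(-b * truth["d"][..., None])
        + truth["fp"][..., None] * np.exp(-b * truth["d_star"][..., None])
    )
    noisy = add_noise(
        clean, spec.snr, spec.noise_model, seed=np.random.SeedSequence(
            [int(spec.seed), 0x201]
        ), si0_ref=spec.si0,
    )
    return PhantomDataset(
        signal=noisy,
        b_values=spec.b_values,
        roi_masks=roi_masks,
        truth=truth,
        seed=spec.seed,
        snr=spec.snr if spec.noise_model != "none" else None,
        noise_model=spec.noise_model,
        lesion_params=lesion_params,
    )


# ---------------------------------------------------------------------------
# dataset directory layout


def _nifti(arr) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4))


def write_dataset(ds: PhantomDataset, path) -> Path:
    """Write a dataset directory: 4-D NIfTI signal, .bval sidecar, per-lesion
    masks, per-parameter truth maps, and a JSON provenance record."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(ds.signal), path / "dwi.nii.gz")
    (path / "dwi.bval").write_text(
        " ".join(f"{b:g}" for b in ds.b_values) + "\n"
    )
    for i, m in enumerate(ds.roi_masks):
        img = nib.Nifti1Image(m.astype(np.uint8), np.eye(4))
        nib.save(img, path / f"mask_lesion{i:02d}.nii.gz")
    for name, arr in ds.truth.items():
        nib.save(_nifti(arr), path / f"truth_{name}.nii.gz")
    meta = {
        "seed": int(ds.seed),
        "snr": ds.snr,
        "noise_model": ds.noise_model,
        "n_lesions": len(ds.roi_masks),
        "b_values": list(ds.b_values),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_dataset(path) -> PhantomDataset:
    """Load a dataset directory written by :func:`write_dataset`.

    Raises :class:`~ivimfit.errors.ParseError` naming the offending component
    on malformed input (missing files, b-table/volume mismatch, bad masks).
    """
    path = Path(path)
    dwi_path = path / "dwi.nii.gz"
    if not dwi_path.exists():
        raise ParseError(f"signal volume missing: {dwi_path}")
    signal = np.asarray(nib.load(dwi_path).get_fdata(), dtype=float)

    bval_path = path / "dwi.bval"
    if not bval_path.exists():
        raise ParseError(f"b-value sidecar missing: {bval_path}")
    try:
        b_values = tuple(float(x) for x in bval_path.read_text().split())
    except ValueError as e:
        raise ParseError(f"b-value sidecar {bval_path} is not numeric: {e}") from e

    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ParseError(f"provenance record missing: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"provenance record {meta_path} is invalid JSON: {e}") from e

    masks = []
    for i in range(int(meta.get("n_lesions", 0))):
        mp = path / f"mask_lesion{i:02d}.nii.gz"
        if not mp.exists():
            raise ParseError(f"lesion mask missing: {mp}")
        masks.append(np.asarray(nib.load(mp).get_fdata()) > 0.5)

    truth = {}
    for name in ("si0", "d", "d_star", "fp"):
        tp = path / f"truth_{name}.nii.gz"
        if tp.exists():
            truth[name] = np.asarray(nib.load(tp).get_fdata(), dtype=float)

    return PhantomDataset(
        signal=signal,
        b_values=b_values,
        roi_masks=masks,
        truth=truth,
        seed=int(meta.get("seed", 0)),
        snr=meta.get("snr"),
        noise_model=meta.get("noise_model", "none"),
    )
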