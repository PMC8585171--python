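"""Synthetic inputs with known ground truth.

Three generators cover everything the downstream stages consume:

* :func:`generate_phantom` — two-phase bone/marrow HU volumes standing in
  for scanned 5 x 5 x 5 mm^3 trabecular ROI cubes, with exact ground-truth
  masks (plate lattices, rod lattices, random voxel fields, solid cubes);
* :func:`generate_curve` — bilinear elastic-plastic stress-strain records
  with optional Gaussian noise;
* :func:`generate_paired_dataset` — tidy microstructure/mechanics tables
  with a known linear relation, for regression-recovery checks.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .volume import BinaryVolume, ImageVolume, REGION_LABELS

__all__ = [
    "PhantomSpec",
    "CurveSpec",
    "PairedDatasetSpec",
    "generate_phantom",
    "generate_curve",
    "generate_paired_dataset",
    "LEVELS",
    "SIDES",
]

ARCHITECTURES = ("plate_lattice", "rod_lattice", "homogeneous", "solid")
LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7")
SIDES = ("left", "right")


@dataclass
class PhantomSpec:
    """Parameters of a two-phase trabecular phantom.

    ``element_thickness`` is the plate (or rod) thickness in mm;
    ``target_bvtv`` the desired bone volume fraction.  Plates are normal
    to ``normal_axis`` (default z, the loading axis); rods run along it.
    Default HU values (2000 bone / 0 marrow) make midpoint thresholding
    unambiguous.  Optional ``blur_sigma`` applies a Gaussian point-spread
    after noise to mimic partial-volume blur.
    """

    shape_voxels: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 0.078125  # mm/voxel -> 64 voxels = 5 mm cube
    architecture: str = "plate_lattice"
    target_bvtv: float = 0.25
    element_thickness: float = 0.390625  # mm = 5 voxels at default spacing
    bone_hu: float = 2000.0
    marrow_hu: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    normal_axis: int = 0  # numpy axis index (0 = z)
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.shape_voxels = tuple(int(v) for v in self.shape_voxels)
        if len(self.shape_voxels) != 3 or any(s <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be a positive integer triple")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {ARCHITECTURES}, "
                f"got {self.architecture!r}")
        if not (0.0 < self.target_bvtv <= 1.0):
            raise ValueError("target_bvtv must lie in (0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.element_thickness < self.voxel_size:
            raise ValueError("element_thickness must be >= voxel_size")
        if self.bone_hu <= self.marrow_hu:
            raise ValueError("bone_hu must exceed marrow_hu")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.normal_axis not in (0, 1, 2):
            raise ValueError("normal_axis must be 0, 1 or 2")


@dataclass
class CurveSpec:
    """Bilinear stress-strain law: slope E up to the yield strain, then
    hardening slope H; iid Gaussian stress noise on top."""

    tissue_modulus: float = 100.0  # MPa
    yield_strain: float = 0.008
    hardening_modulus: float = 5.0  # MPa
    max_strain: float = 0.03
    n_points: int = 200
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.yield_strain < self.max_strain):
            raise ValueError("need 0 < yield_strain < max_strain")
        if self.hardening_modulus >= self.tissue_modulus:
            raise ValueError("hardening_modulus must be < tissue_modulus")
        if self.tissue_modulus <= 0:
            raise ValueError("tissue_modulus must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PairedDatasetSpec:
    """Linear microstructure -> mechanics relation with Gaussian noise."""

    n_samples: int = 144
    slope: float = 299.667
    intercept: float = -76.9
    predictor_range: Tuple[float, float] = (0.1, 0.5)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        lo, hi = self.predictor_range
        if not hi > lo:
            raise ValueError("predictor_range must be nondegenerate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _slab_indicator(n: int, t_vox: int, fraction: float) -> np.ndarray:
    """1-D indicator of evenly spaced slabs of thickness ``t_vox`` whose
    occupied fraction approximates ``fraction`` (quantized to whole
    slabs).  Raises on overlap (spacing < thickness)."""
    count = max(1, int(round(n * fraction / t_vox)))
    if count * t_vox > n:
        raise ValueError(
            f"infeasible bvtv/thickness combination: {count} slab(s) of "
            f"{t_vox} voxels exceed the {n}-voxel extent (slab spacing "
            "would fall below the slab thickness)")
    starts = np.floor(np.arange(count) * n / count).astype(int)
    if count > 1 and np.min(np.diff(starts)) < t_vox:
        raise ValueError(
            "infeasible bvtv/thickness combination: slab spacing below "
            "slab thickness")
    idx = np.zeros(n, dtype=bool)
    for s in starts:
        idx[s:s + t_vox] = True
    return idx


def _phantom_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.shape_voxels
    t_vox = max(1, int(round(spec.element_thickness / spec.voxel_size)))
    if spec.architecture == "solid":
        return np.ones(shape, dtype=bool)
    if spec.architecture == "homogeneous":
        # spatially uncorrelated voxel occupancy at the target fraction
        return rng.random(shape) < spec.target_bvtv
    if spec.architecture == "plate_lattice":
        idx = _slab_indicator(shape[spec.normal_axis], t_vox,
                              spec.target_bvtv)
        expand = [None, None, None]
        expand[spec.normal_axis] = slice(None)
        return np.broadcast_to(idx[tuple(expand)], shape).copy()
    # rod_lattice: square-section rods along normal_axis
    frac_1d = float(np.sqrt(spec.target_bvtv))
    axes = [a for a in range(3) if a != spec.normal_axis]
    in_rod = np.ones(shape, dtype=bool)
    for a in axes:
        idx = _slab_indicator(shape[a], t_vox, frac_1d)
        expand = [None, None, None]
        expand[a] = slice(None)
        in_rod &= np.broadcast_to(idx[tuple(expand)], shape)
    return in_rod


def generate_phantom(spec: PhantomSpec) -> Tuple[ImageVolume, BinaryVolume]:
    """Generate an HU phantom plus its ground-truth bone mask.

    The noiseless volume binarized at the HU midpoint reproduces the
    ground-truth mask exactly.  For lattices the achieved BV/TV sits
    within one thickness/period quantum of ``target_bvtv``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _phantom_mask(spec, rng)
    hu = np.where(mask, spec.bone_hu, spec.marrow_hu).astype(np.float64)
    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=mask.shape)
    if spec.blur_sigma > 0:
        from scipy import ndimage
        hu = ndimage.gaussian_filter(hu, spec.blur_sigma)
    meta = {"architecture": spec.architecture, "seed": spec.seed,
            "target_bvtv": spec.target_bvtv}
    vol = ImageVolume(hu, spec.voxel_size, meta)
    truth = BinaryVolume(mask, spec.voxel_size, dict(meta))
    return vol, truth


def bilinear_stress(strain: np.ndarray, modulus: float, yield_strain: float,
                    hardening_modulus: float) -> np.ndarray:
    """Noise-free bilinear law: E*eps below the yield strain, then
    sigma_y + H*(eps - eps_y)."""
    strain = np.asarray(strain, dtype=float)
    sigma_y = modulus * yield_strain
    return np.where(strain <= yield_strain, modulus * strain,
                    sigma_y + hardening_modulus * (strain - yield_strain))


def generate_curve(spec: CurveSpec):
    """Sample the bilinear law on a uniform strain grid, plus noise.

    The yield strain is always included as a grid point so the noiseless
    curve is exactly piecewise linear with its single breakpoint on the
    grid.
    """
    from .curves import StressStrainCurve

    strain = np.linspace(0.0, spec.max_strain, spec.n_points)
    # snap the nearest grid point onto the breakpoint
    k = int(np.argmin(np.abs(strain - spec.yield_strain)))
    if 0 < k < spec.n_points - 1:
        strain[k] = spec.yield_strain
    stress = bilinear_stress(strain, spec.tissue_modulus, spec.yield_strain,
                             spec.hardening_modulus)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)
    return StressStrainCurve(strain=strain, stress=stress)


def generate_paired_dataset(spec: PairedDatasetSpec) -> pd.DataFrame:
    """Tidy (x, y) table with region/level/side labels cycling over the
    SA/SP/IA/IP x C2-C7 x left/right design."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.predictor_range
    x = np.linspace(lo, hi, spec.n_samples)
    rng.shuffle(x)
    y = spec.slope * x + spec.intercept
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    idx = np.arange(spec.n_samples)
    regions = np.array(REGION_LABELS)[idx % 4]
    levels = np.array(LEVELS)[(idx // 4) % 6]
    sides = np.array(SIDES)[(idx // 24) % 2]
    return pd.DataFrame({
        "region": regions, "level": levels, "side": sides,
        "x": x, "y": y,
    })
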