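"""Trabecular microstructure parameters from binarized ROI volumes.

Implements the seven standard histomorphometric indices for a cubic ROI:

========  ======  ====================================================
BV/TV     --      bone volume / total volume
Tb.N      1/mm    trabecular number, (BV/TV) / Tb.Th
Tb.Th     mm      mean trabecular thickness (sphere fitting)
Tb.Sp     mm      mean trabecular separation (sphere fitting, marrow)
BS/BV     1/mm    bone surface / bone volume (triangulated isosurface)
Tb.Pf     1/mm    trabecular pattern factor (dilation convexity index)
BMD       mg/cc   mean calibrated mineral density over the bone phase
========  ======  ====================================================

Thickness follows the Hildebrand-Rueegsegger definition: the local
thickness at a point is the diameter of the largest sphere that fits in
the phase and contains the point; Tb.Th / Tb.Sp are the volume-weighted
means over bone / marrow.  Tb.Pf is Hahn's convexity index
(S1 - S2)/(V1 - V2) across a one-voxel dilation: convex, poorly
connected structures score positive, concave well-connected lattices
low or negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import BinaryVolume, ImageVolume, RegionOfInterest

__all__ = [
    "BmdCalibration",
    "MorphometryResult",
    "EmptyPhaseError",
    "binarize",
    "otsu_threshold",
    "bone_volume_fraction",
    "surface_area",
    "surface_and_bsbv",
    "local_thickness",
    "thickness_map",
    "trabecular_number",
    "trabecular_pattern_factor",
    "bmd_from_hu",
    "analyze_roi",
]


class EmptyPhaseError(ValueError):
    """Raised when a parameter is undefined because the requested phase
    (bone or marrow) contains no voxels."""


@dataclass
class BmdCalibration:
    """Linear HU -> bone mineral density conversion: BMD = slope*HU + intercept.

    Scanner calibrations are fitted against hydroxyapatite rod phantoms;
    the coefficients must be supplied (there is no universal default).
    """

    slope: float  # (mg/cc) per HU
    intercept: float = 0.0  # mg/cc

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


@dataclass
class MorphometryResult:
    """Microstructure indices for one ROI (NaN where undefined)."""

    bvtv: float
    tb_n: float
    tb_th: float
    tb_sp: float
    bs_bv: float
    tb_pf: float
    bmd: float
    label: str = ""
    level: str = ""
    side: str = ""
    theta: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "label": self.label, "level": self.level, "side": self.side,
            "theta": self.theta, "bvtv": self.bvtv, "tb_n": self.tb_n,
            "tb_th": self.tb_th, "tb_sp": self.tb_sp, "bs_bv": self.bs_bv,
            "tb_pf": self.tb_pf, "bmd": self.bmd,
        }


def binarize(volume: ImageVolume, threshold: float) -> BinaryVolume:
    """Global threshold: bone where HU >= threshold.

    A fully empty or fully solid result is legal (morphometry degenerates
    there) and only triggers a warning.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = volume.voxels >= threshold
    n_fg = int(mask.sum())
    if n_fg == 0 or n_fg == mask.size:
        warnings.warn(
            f"binarize: mask is all-{'foreground' if n_fg else 'background'};"
            " morphometry will be degenerate", stacklevel=2)
    return BinaryVolume(mask, volume.spacing,
                        {**volume.meta, "threshold": float(threshold)})


def otsu_threshold(volume: ImageVolume) -> float:
    """Otsu's automatic threshold on the HU histogram (explicit opt-in)."""
    from skimage.filters import threshold_otsu
    return float(threshold_otsu(volume.voxels))


def bone_volume_fraction(mask: BinaryVolume) -> float:
    """BV/TV: foreground voxels over total voxels."""
    return float(np.count_nonzero(mask.mask)) / mask.mask.size


def surface_area(mask: BinaryVolume, smooth_sigma: float = 1.0) -> float:
    """Bone surface in mm^2 from a triangulated 0.5-level isosurface.

    The mask is zero-padded (so boundary faces are closed) and lightly
    Gaussian-smoothed before marching cubes; the smoothing suppresses the
    staircase overestimate of binary isosurfaces (about +8% on a digital
    sphere) at the cost of slightly rounding sharp edges.  ``smooth_sigma``
    is in voxels; 0 disables it.
    """
    if not mask.mask.any():
        raise EmptyPhaseError("surface area undefined for an empty mask")
    field = np.pad(mask.mask, 2).astype(np.float32)
    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.5, spacing=(mask.spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def surface_and_bsbv(mask: BinaryVolume,
                     smooth_sigma: float = 1.0) -> Tuple[float, float]:
    """Bone surface (mm^2) and the specific surface BS/BV (1/mm)."""
    surf = surface_area(mask, smooth_sigma)
    bv = np.count_nonzero(mask.mask) * mask.voxel_volume
    return surf, surf / bv


def thickness_map(mask: BinaryVolume, phase: str = "foreground",
                  max_radii: int = 128) -> np.ndarray:
    """Local-thickness map (mm) of the selected phase by sphere fitting.

    For each phase voxel the map holds the diameter of the largest
    inscribed sphere containing it.  Implemented via the Euclidean
    distance transform: every voxel is a candidate sphere centre with
    radius equal to its distance to the phase boundary; radii are swept
    in descending order and each sphere stamps its diameter onto the
    voxels it covers.  Distances between voxel centres overestimate the
    true half-thickness by half a voxel, so diameters are reported as
    ``2 r - spacing``.  The ROI border counts as a phase interface
    (spheres may not extend outside the analysed cube), which keeps
    boundary-touching structures from inflating the map.  Radii are
    binned to at most ``max_radii`` distinct values (a sub-voxel
    quantization) to bound the sweep cost.
    """
    if phase not in ("foreground", "background"):
        raise ValueError("phase must be 'foreground' or 'background'")
    phase_mask = mask.mask if phase == "foreground" else ~mask.mask
    if not phase_mask.any():
        raise EmptyPhaseError(f"{phase} phase is empty")
    h = mask.spacing
    dt = ndimage.distance_transform_edt(
        np.pad(phase_mask, 1), sampling=h)[1:-1, 1:-1, 1:-1]
    radii = np.unique(dt[phase_mask])
    radii = radii[radii > 0][::-1]
    if radii.size > max_radii:
        # keep the quantization deterministic: evenly strided subsample
        radii = radii[np.unique(
            np.linspace(0, radii.size - 1, max_radii).astype(int))]
    thick = np.zeros(mask.shape)
    todo = phase_mask.copy()
    eps = 1e-9 * h
    for r in radii:
        if not todo.any():
            break
        centers = dt >= r - eps
        # voxels within r - h/2 of some centre lie inside that sphere
        cover_r = r - 0.5 * h
        if cover_r <= 0:
            covered = centers
        else:
            dist_to_center = ndimage.distance_transform_edt(
                ~centers, sampling=h)
            covered = dist_to_center <= cover_r + eps
        hit = covered & todo
        thick[hit] = max(2.0 * r - h, h)
        todo &= ~hit
    # isolated voxels whose sphere degenerates below one voxel
    thick[todo] = h
    thick[~phase_mask] = 0.0
    return thick


def local_thickness(mask: BinaryVolume, phase: str = "foreground") -> float:
    """Volume-weighted mean thickness (mm): Tb.Th for the foreground,
    Tb.Sp for the background."""
    tm = thickness_map(mask, phase)
    phase_mask = mask.mask if phase == "foreground" else ~mask.mask
    return float(tm[phase_mask].mean())


def trabecular_number(bvtv: float, tb_th: float) -> float:
    """Tb.N = (BV/TV) / Tb.Th, the model-independent plate-density
    estimate (intersections per mm along a probe line)."""
    if tb_th <= 0:
        raise ValueError("tb_th must be positive")
    return bvtv / tb_th


def trabecular_pattern_factor(mask: BinaryVolume, smooth_sigma: float = 1.0,
                              connectivity: int = 1) -> float:
    """Tb.Pf = (S1 - S2) / (V1 - V2) across a single-voxel dilation.

    S and V are isosurface area and bone volume before (1) and after (2)
    dilating the mask by one voxel (6-connected by default).  Dilation
    fills concavities: in well-connected lattices the surface shrinks
    relative to the volume gain, driving Tb.Pf low or negative; isolated
    convex bodies stay positive.
    """
    if not mask.mask.any():
        raise EmptyPhaseError("Tb.Pf undefined for an empty mask")
    struct = ndimage.generate_binary_structure(3, connectivity)
    dilated = BinaryVolume(ndimage.binary_dilation(mask.mask, struct),
                           mask.spacing)
    v1 = np.count_nonzero(mask.mask) * mask.voxel_volume
    v2 = np.count_nonzero(dilated.mask) * mask.voxel_volume
    if v2 == v1:
        raise EmptyPhaseError(
            "Tb.Pf undefined: dilation does not change the mask "
            "(mask fills the grid)")
    s1 = surface_area(mask, smooth_sigma)
    s2 = surface_area(dilated, smooth_sigma)
    return (s1 - s2) / (v1 - v2)


def bmd_from_hu(volume: ImageVolume, mask: BinaryVolume,
                cal: BmdCalibration) -> float:
    """Mean calibrated density (mg/cc) over the masked bone voxels."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.mask.any():
        raise EmptyPhaseError("BMD undefined for an empty mask")
    return float(cal(volume.voxels[mask.mask]).mean())


def analyze_roi(volume: ImageVolume, roi: RegionOfInterest, threshold: float,
                cal: Optional[BmdCalibration] = None,
                smooth_sigma: float = 1.0) -> MorphometryResult:
    """Crop an ROI, binarize it and compute the full parameter set.

    Degenerate sub-results (empty phase, grid-filling mask) are recorded
    as NaN rather than aborting the batch; a missing calibration leaves
    BMD as NaN.
    """
    sub = volume.crop(roi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = binarize(sub, threshold)
    bvtv = bone_volume_fraction(mask)

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except EmptyPhaseError:
            return float("nan")

    tb_th = _try(local_thickness, mask, "foreground")
    tb_sp = _try(local_thickness, mask, "background")
    if np.isfinite(tb_th) and tb_th > 0:
        tb_n = trabecular_number(bvtv, tb_th)
    else:
        tb_n = float("nan")
    try:
        _, bs_bv = surface_and_bsbv(mask, smooth_sigma)
    except EmptyPhaseError:
        bs_bv = float("nan")
    tb_pf = _try(trabecular_pattern_factor, mask, smooth_sigma)
    bmd = _try(bmd_from_hu, sub, mask, cal) if cal is not None else float("nan")
    return MorphometryResult(
        bvtv=bvtv, tb_n=tb_n, tb_th=tb_th, tb_sp=tb_sp, bs_bv=bs_bv,
        tb_pf=tb_pf, bmd=bmd, label=roi.label, level=roi.level,
        side=roi.side, theta=roi.theta)
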