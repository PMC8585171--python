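"""Core image containers shared across the pipeline.

A micro-CT scan is represented as a 3-D grid of Hounsfield-unit (HU)
values with isotropic voxel spacing; analysis units are labeled cubic
regions of interest (ROIs) cut from it.  Axis convention is ``(z, y, x)``
with the compression (gravity) axis along ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryVolume",
    "RegionOfInterest",
    "REGION_LABELS",
]

#: Quadrants of an articular process: superior/inferior x anterior/posterior.
REGION_LABELS = ("SA", "SP", "IA", "IP")


@dataclass
class ImageVolume:
    """A 3-D HU-valued image with isotropic voxel spacing in mm."""

    voxels: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    def crop(self, roi: "RegionOfInterest") -> "ImageVolume":
        """Extract the half-open box ``[origin, origin + size)``."""
        roi.check_inside(self.shape)
        sl = roi.slices
        return ImageVolume(self.voxels[sl].copy(), self.spacing,
                           {**self.meta, "roi": roi.label})


@dataclass
class BinaryVolume:
    """A boolean bone mask (True = bone) with voxel spacing in mm."""

    mask: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 3-D array")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing) ** 3

    def complement(self) -> "BinaryVolume":
        return BinaryVolume(~self.mask, self.spacing, dict(self.meta))

    def crop(self, roi: "RegionOfInterest") -> "BinaryVolume":
        roi.check_inside(self.shape)
        return BinaryVolume(self.mask[roi.slices].copy(), self.spacing,
                            {**self.meta, "roi": roi.label})


@dataclass
class RegionOfInterest:
    """A labeled cubic ROI with the facet-plane angle theta.

    ``theta`` (degrees) is the angle between gravity and the shear force
    acting on the facet; it enters the allowable-stress correction
    ``[sigma] = sigma_yield / cos(theta)``.  Cervical facets sit at
    roughly 45 degrees, the default.
    """

    label: str
    origin_voxel: Tuple[int, int, int]
    size_voxel: Tuple[int, int, int]
    theta: float = 45.0
    level: str = "C4"
    side: str = "right"

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(
                f"label must be one of {REGION_LABELS}, got {self.label!r}")
        if not (0.0 <= self.theta < 90.0):
            raise ValueError(f"theta must lie in [0, 90), got {self.theta}")
        self.origin_voxel = tuple(int(v) for v in self.origin_voxel)
        self.size_voxel = tuple(int(v) for v in self.size_voxel)
        if any(s <= 0 for s in self.size_voxel):
            raise ValueError("size_voxel components must be positive")
        if any(o < 0 for o in self.origin_voxel):
            raise ValueError("origin_voxel components must be non-negative")

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(o, o + s)
                     for o, s in zip(self.origin_voxel, self.size_voxel))

    def check_inside(self, parent_shape: Tuple[int, int, int]) -> None:
        for o, s, n in zip(self.origin_voxel, self.size_voxel, parent_shape):
            if o + s > n:
                raise ValueError(
                    f"ROI {self.label}: box [{o}, {o + s}) exceeds parent "
                    f"extent {n}")
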