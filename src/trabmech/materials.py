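"""Material mapping for voxel micro-FE models.

Each element inherits its material from the gray value (GV, in HU) of
its source voxel through the calibrated power law

    density   = 0.00097 * GV          [g/cc per HU]
    E-modulus = 19.04 * density^1.64  [MPa]
    nu        = 0.3

The HU -> g/cc -> MPa unit convention is the common micro-CT bone
calibration; both scale factors are configurable.  A bilinear tissue
constitutive law (elastic up to a sign-dependent yield strain, then a
reduced hardening slope) is provided for the optional elastoplastic
solve; its default transition strains are 0.8% in compression and 0.48%
in tension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .microfe import VoxelMesh
    from .volume import ImageVolume

__all__ = [
    "DENSITY_PER_GV",
    "MODULUS_COEFF",
    "MODULUS_EXPONENT",
    "POISSON_RATIO",
    "MaterialField",
    "MaterialMapping",
    "BilinearTissueLaw",
    "map_materials",
]

#: density (g/cc) per unit gray value (HU)
DENSITY_PER_GV = 0.00097
#: E (MPa) = MODULUS_COEFF * density^MODULUS_EXPONENT
MODULUS_COEFF = 19.04
MODULUS_EXPONENT = 1.64
POISSON_RATIO = 0.3


@dataclass
class MaterialMapping:
    """The gray-value -> density -> modulus calibration, configurable."""

    density_per_gv: float = DENSITY_PER_GV
    modulus_coeff: float = MODULUS_COEFF
    modulus_exponent: float = MODULUS_EXPONENT
    poisson_ratio: float = POISSON_RATIO
    density_floor: float = 0.0  # g/cc, clamp for negative HU

    def __post_init__(self) -> None:
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.density_floor < 0:
            raise ValueError("density_floor must be >= 0")

    def density(self, gv: np.ndarray) -> np.ndarray:
        """Apparent density (g/cc) from gray value (HU)."""
        return self.density_per_gv * np.asarray(gv, dtype=float)

    def modulus(self, density: np.ndarray) -> np.ndarray:
        """Tissue modulus (MPa) from density (g/cc)."""
        return self.modulus_coeff * np.asarray(density, float) ** self.modulus_exponent


@dataclass
class MaterialField:
    """Per-element density (g/cc) and modulus (MPa), global Poisson ratio."""

    density: np.ndarray
    modulus: np.ndarray
    poisson_ratio: float = POISSON_RATIO

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.modulus = np.asarray(self.modulus, dtype=float)
        if self.density.shape != self.modulus.shape:
            raise ValueError("density and modulus must have equal length")
        if np.any(self.density < 0) or np.any(self.modulus < 0):
            raise ValueError("density and modulus must be non-negative")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")

    @classmethod
    def homogeneous(cls, n_elements: int, modulus: float,
                    poisson_ratio: float = POISSON_RATIO,
                    density: float = 1.0) -> "MaterialField":
        return cls(np.full(n_elements, density), np.full(n_elements, modulus),
                   poisson_ratio)


def map_materials(volume: "ImageVolume", mesh: "VoxelMesh",
                  mapping: Optional[MaterialMapping] = None,
                  stiffness_floor: float = 1e-6) -> MaterialField:
    """Assign per-element density and modulus from the source voxels.

    Negative gray values (below the density floor) are clamped with a
    warning; elements whose modulus falls below ``stiffness_floor`` (MPa)
    are left in the field but reported in the returned array's metadata
    via a warning, since they can make the stiffness matrix singular.
    """
    mapping = mapping or MaterialMapping()
    gv = volume.voxels[tuple(mesh.element_voxels.T)]
    if not np.all(np.isfinite(gv)):
        raise ValueError("non-finite gray values under mesh elements")
    rho = mapping.density(gv)
    n_neg = int(np.count_nonzero(rho < mapping.density_floor))
    if n_neg:
        warnings.warn(
            f"map_materials: {n_neg} element(s) below the density floor "
            f"{mapping.density_floor} g/cc were clamped", stacklevel=2)
        rho = np.maximum(rho, mapping.density_floor)
    E = mapping.modulus(rho)
    n_soft = int(np.count_nonzero(E < stiffness_floor))
    if n_soft:
        warnings.warn(
            f"map_materials: {n_soft} element(s) have modulus below "
            f"{stiffness_floor} MPa (near-zero stiffness)", stacklevel=2)
    return MaterialField(rho, E, mapping.poisson_ratio)


@dataclass
class BilinearTissueLaw:
    """Sign-dependent bilinear elastic-plastic tissue law.

    The uniaxial response is linear up to the yield strain — 0.8%
    magnitude in compression, 0.48% in tension — and continues with a
    reduced hardening slope (``hardening_ratio`` times the elastic
    modulus) beyond it.
    """

    compressive_yield_strain: float = 0.008
    tensile_yield_strain: float = 0.0048
    hardening_ratio: float = 0.05

    def __post_init__(self) -> None:
        if self.compressive_yield_strain <= 0 or self.tensile_yield_strain <= 0:
            raise ValueError("yield strains must be positive magnitudes")
        if not (0.0 <= self.hardening_ratio < 1.0):
            raise ValueError("hardening_ratio must lie in [0, 1)")

    @property
    def breakpoints(self) -> tuple:
        """Signed transition strains (compressive, tensile)."""
        return (-self.compressive_yield_strain, self.tensile_yield_strain)

    def stress(self, strain: np.ndarray, modulus: float) -> np.ndarray:
        """Uniaxial stress (MPa) at signed strain for a given elastic
        modulus; compression negative."""
        eps = np.asarray(strain, dtype=float)
        H = self.hardening_ratio * modulus
        ey_c, ey_t = self.compressive_yield_strain, self.tensile_yield_strain
        out = modulus * eps
        out = np.where(eps > ey_t,
                       modulus * ey_t + H * (eps - ey_t), out)
        out = np.where(eps < -ey_c,
                       -modulus * ey_c + H * (eps + ey_c), out)
        return out

    def yield_strain(self, sign: float) -> float:
        """Yield strain magnitude for tensile (sign > 0) or compressive
        (sign <= 0) loading."""
        return self.tensile_yield_strain if sign > 0 else self.compressive_yield_strain

    def secant_modulus(self, eq_strain: np.ndarray, modulus: np.ndarray,
                       sign: np.ndarray) -> np.ndarray:
        """Secant modulus at an equivalent strain magnitude, used by the
        incremental elastoplastic solve."""
        eq = np.asarray(eq_strain, dtype=float)
        E0 = np.asarray(modulus, dtype=float)
        ey = np.where(np.asarray(sign) > 0, self.tensile_yield_strain,
                      self.compressive_yield_strain)
        with np.errstate(divide="ignore", invalid="ignore"):
            sec = E0 * (ey + self.hardening_ratio * (eq - ey)) / eq
        return np.where(eq > ey, sec, E0)
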