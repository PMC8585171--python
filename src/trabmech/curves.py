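"""Reduction of compression stress-strain records.

From one record the module extracts the Young's modulus (least-squares
slope over an auto-detected linear window), the 0.2%-offset yield point,
the curve maxima, and the facet-angle-corrected allowable stress
``[sigma] = sigma_yield / cos(theta)``.  Compressive stress and strain
are stored as positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "StressStrainCurve",
    "CurveAnalysisResult",
    "BilinearFit",
    "NoYieldError",
    "ElasticWindowError",
    "fit_youngs_modulus",
    "yield_offset",
    "allowable_stress",
    "curve_maxima",
    "fit_bilinear",
    "analyze_curve",
]


class NoYieldError(RuntimeError):
    """The offset line never intersects the curve (elastic to failure)."""


class ElasticWindowError(RuntimeError):
    """No linear window of at least three points could be detected."""


@dataclass
class StressStrainCurve:
    """A monotone-strain stress record, optionally with the raw
    force/displacement channels and specimen geometry."""

    strain: np.ndarray
    stress: np.ndarray  # MPa
    force: Optional[np.ndarray] = None  # N
    displacement: Optional[np.ndarray] = None  # mm
    area: Optional[float] = None  # mm^2
    height: Optional[float] = None  # mm

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D")
        if self.strain.size < 3:
            raise ValueError("need at least 3 samples")
        if self.strain[0] < 0:
            raise ValueError("strain must start at >= 0")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be nondecreasing")

    @classmethod
    def from_force_displacement(cls, force: np.ndarray,
                                displacement: np.ndarray, area: float,
                                height: float) -> "StressStrainCurve":
        """Engineering stress/strain from a force-displacement record."""
        force = np.asarray(force, dtype=float)
        displacement = np.asarray(displacement, dtype=float)
        return cls(strain=displacement / height, stress=force / area,
                   force=force, displacement=displacement,
                   area=area, height=height)


@dataclass
class CurveAnalysisResult:
    youngs_modulus: float  # MPa
    yield_stress: float    # MPa (NaN if no yield)
    yield_strain: float
    stress_max: float
    strain_max: float
    force_max: float
    allowable_stress: float  # MPa
    elastic_window: Tuple[float, float]  # (Es, Ee) strains
    theta: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "youngs_modulus": self.youngs_modulus,
            "yield_stress": self.yield_stress,
            "yield_strain": self.yield_strain,
            "stress_max": self.stress_max,
            "strain_max": self.strain_max,
            "force_max": self.force_max,
            "allowable_stress": self.allowable_stress,
            "elastic_start": self.elastic_window[0],
            "elastic_end": self.elastic_window[1],
            "theta": self.theta,
        }


def fit_youngs_modulus(curve: StressStrainCurve, band: float = 0.05,
                       window: Optional[Tuple[float, float]] = None,
                       start_fraction: float = 0.25
                       ) -> Tuple[float, Tuple[float, float]]:
    """Least-squares modulus over the detected initial linear region.

    Detection: local secant slopes are taken over a stride of about a
    sixth of the record (single-sample secants are hopelessly noisy);
    the elastic window is the longest contiguous run of stride slopes
    that stay within ``band`` (relative) of the run's median slope and
    that begins within the first ``start_fraction`` of the strain range
    (the elastic regime of a compression record starts at the origin —
    without this constraint a long post-yield hardening segment would
    win the search).  The modulus is the least-squares slope over the
    selected samples.  An explicit strain ``window`` overrides
    detection.  Returns (E in MPa, (Es, Ee) strain window).
    """
    eps, sig = curve.strain, curve.stress
    if window is not None:
        lo, hi = window
        sel = (eps >= lo) & (eps <= hi)
        if sel.sum() < 3:
            raise ElasticWindowError("manual window holds fewer than 3 points")
        i, j = np.flatnonzero(sel)[[0, -1]]
    else:
        n = eps.size
        k = max(1, n // 6)
        span = eps[k:] - eps[:-k]
        good = span > 0
        slopes = np.full(n - k, np.nan)
        slopes[good] = (sig[k:] - sig[:-k])[good] / span[good]
        start_limit = eps[0] + start_fraction * (eps[-1] - eps[0])
        m = slopes.size
        best = None  # (length, a, b) over stride-slope indices
        for a in range(m):
            if not good[a] or eps[a] > start_limit:
                continue
            for b in range(m - 1, a - 1, -1):
                if best is not None and b - a < best[0]:
                    break
                w = slopes[a:b + 1]
                if np.any(~good[a:b + 1]):
                    continue
                med = np.median(w)
                if med == 0:
                    continue
                if np.all(np.abs(w - med) <= band * abs(med)):
                    if best is None or b - a > best[0]:
                        best = (b - a, a, b)
                    break
        if best is None:
            raise ElasticWindowError(
                "no initial linear window within the slope band")
        i, j = best[1], best[2] + k
        # trim trailing samples that have drifted off the elastic line
        # (stride slopes smear the breakpoint by up to one stride)
        while j - i >= 3:
            slope, icept = np.polyfit(eps[i:j + 1], sig[i:j + 1], 1)
            resid = sig[i:j + 1] - (slope * eps[i:j + 1] + icept)
            scale = max(1.4826 * np.median(np.abs(resid)),
                        1e-9 * max(np.abs(sig).max(), 1.0))
            if abs(resid[-1]) > 3.0 * scale:
                j -= 1
            else:
                break
    x, y = eps[i:j + 1], sig[i:j + 1]
    if x.size < 3:
        raise ElasticWindowError("detected window holds fewer than 3 points")
    E = float(np.polyfit(x, y, 1)[0])
    return E, (float(eps[i]), float(eps[j]))


def yield_offset(curve: StressStrainCurve, modulus: float,
                 offset: float = 0.002) -> Tuple[float, float]:
    """0.2%-offset yield point: intersection of the curve with the line
    ``sigma = E * (strain - offset)``, located by linear interpolation
    between the bracketing samples.  Returns (yield stress MPa, strain
    at the intersection).  Raises :class:`NoYieldError` if the line
    never catches the curve."""
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    eps, sig = curve.strain, curve.stress
    gap = sig - modulus * (eps - offset)  # positive while curve above line
    for k in range(eps.size - 1):
        if gap[k] >= 0 and gap[k + 1] < 0:
            t = gap[k] / (gap[k] - gap[k + 1])
            ey = eps[k] + t * (eps[k + 1] - eps[k])
            sy = sig[k] + t * (sig[k + 1] - sig[k])
            return float(sy), float(ey)
    raise NoYieldError("offset line does not intersect the curve before "
                       "maximum strain (specimen failed elastically)")


def allowable_stress(yield_stress: float, theta: float) -> float:
    """[sigma] = sigma_yield / cos(theta): the allowable stress of a
    facet region whose shear direction makes angle ``theta`` (degrees)
    with gravity.  Undefined at theta >= 90 degrees."""
    if not (0.0 <= theta < 90.0):
        raise ValueError(f"theta must lie in [0, 90) degrees, got {theta}")
    return yield_stress / np.cos(np.deg2rad(theta))


def curve_maxima(curve: StressStrainCurve
                 ) -> Tuple[float, float, float]:
    """(stress_max, strain_max, force_max).  Force comes from the force
    channel when present, else stress_max * area."""
    stress_max = float(curve.stress.max())
    strain_max = float(curve.strain.max())
    if curve.force is not None:
        force_max = float(np.max(curve.force))
    elif curve.area is not None:
        force_max = stress_max * curve.area
    else:
        raise ValueError("force_max needs a force channel or specimen area")
    return stress_max, strain_max, force_max


@dataclass
class BilinearFit:
    """Continuous two-segment linear fit of a stress-strain record."""

    modulus: float            # first-segment slope (E)
    hardening_modulus: float  # second-segment slope (H)
    breakpoint: float         # strain at the segment junction
    sse: float
    degenerate: bool = False  # breakpoint unidentifiable (collinear data)


def fit_bilinear(curve: StressStrainCurve,
                 min_points: int = 2) -> BilinearFit:
    """Least-squares continuous piecewise-linear fit with a free
    breakpoint: grid search over interior sample strains, per-breakpoint
    linear least squares on the basis {1, eps, max(eps - b, 0)}.
    Collinear data leave the breakpoint unidentifiable and set the
    ``degenerate`` flag."""
    eps, sig = curve.strain, curve.stress
    if eps.size < 5:
        raise ValueError("need at least 5 points for a bilinear fit")
    best = None
    for k in range(min_points, eps.size - min_points):
        b = eps[k]
        X = np.column_stack([np.ones_like(eps), eps,
                             np.maximum(eps - b, 0.0)])
        coef, *_ = np.linalg.lstsq(X, sig, rcond=None)
        resid = sig - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, coef)
    sse, b, coef = best
    E = float(coef[1])
    H = float(coef[1] + coef[2])
    # equal segment slopes: the data are one line and b is arbitrary
    degenerate = abs(coef[2]) <= 1e-8 * max(abs(E), 1.0)
    return BilinearFit(modulus=E, hardening_modulus=H, breakpoint=float(b),
                       sse=sse, degenerate=degenerate)


def analyze_curve(curve: StressStrainCurve, theta: float = 45.0,
                  band: float = 0.05, offset: float = 0.002,
                  window: Optional[Tuple[float, float]] = None
                  ) -> CurveAnalysisResult:
    """Full reduction of one record to the mechanical parameter set."""
    E, win = fit_youngs_modulus(curve, band=band, window=window)
    try:
        sy, ey = yield_offset(curve, E, offset=offset)
        allow = allowable_stress(sy, theta)
    except NoYieldError:
        sy = ey = allow = float("nan")
    try:
        smax, emax, fmax = curve_maxima(curve)
    except ValueError:
        smax = float(curve.stress.max())
        emax = float(curve.strain.max())
        fmax = float("nan")
    return CurveAnalysisResult(
        youngs_modulus=E, yield_stress=sy, yield_strain=ey,
        stress_max=smax, strain_max=emax, force_max=fmax,
        allowable_stress=allow, elastic_window=win, theta=theta)
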