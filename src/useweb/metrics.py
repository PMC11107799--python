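"""Quantitative evaluation of phase-velocity maps.

Region-of-interest statistics (mean, sample SD, coefficient of variation
``CV = SD/MEAN * 100%``), inclusion contrast-to-noise ratio
``CNR = 20 log10(|mean_inc - mean_bg| / SD_bg)`` in dB, nominal shear
speeds ``sqrt(E/(3 rho))``, and lateral cross-section profiles with edge
estimates.  Statistics use only valid (unmasked) pixels; SD is the sample
standard deviation (n - 1), configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .reconstruct import PhaseVelocityMap

__all__ = [
    "Roi",
    "roi_stats",
    "cnr",
    "nominal_speed",
    "wavelength",
    "cross_profile",
    "profile_edges",
]

MIN_ROI_PIXELS = 16


@dataclass(frozen=True)
class Roi:
    """Rectangular or disk region of interest, geometry in metres.

    ``rectangle``: ``center`` (z, x) with ``height`` x ``width``.
    ``disk``: ``center`` (z, x) with ``radius``.
    """

    kind: str
    center: Tuple[float, float]
    height: float = 0.0
    width: float = 0.0
    radius: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "disk"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "rectangle" and (self.height <= 0 or self.width <= 0):
            raise ValueError("rectangle ROI needs positive height and width")
        if self.kind == "disk" and self.radius <= 0:
            raise ValueError("disk ROI needs a positive radius")

    @staticmethod
    def rectangle(center, height, width, label="") -> "Roi":
        return Roi(kind="rectangle", center=center, height=height, width=width, label=label)

    @staticmethod
    def disk(center, radius, label="") -> "Roi":
        return Roi(kind="disk", center=center, radius=radius, label=label)

    def select(self, m: PhaseVelocityMap) -> np.ndarray:
        """Boolean pixel mask of the ROI on the map's grid."""
        zz = m.z[:, None] - self.center[0]
        xx = m.x[None, :] - self.center[1]
        if self.kind == "rectangle":
            return (np.abs(zz) <= self.height / 2) & (np.abs(xx) <= self.width / 2)
        return zz**2 + xx**2 <= self.radius**2


def roi_stats(m: PhaseVelocityMap, roi: Roi, ddof: int = 1) -> dict:
    """Mean, SD and CV (%) of the valid map pixels inside an ROI."""
    sel = roi.select(m) & m.mask
    n = int(sel.sum())
    if n < MIN_ROI_PIXELS:
        raise ValueError(f"ROI covers only {n} valid pixels (needs >= {MIN_ROI_PIXELS})")
    vals = m.cph[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    return {
        "label": roi.label,
        "mean": mean,
        "sd": sd,
        "cv_percent": 100.0 * sd / mean,
        "n_pixels": n,
    }


def cnr(m: PhaseVelocityMap, inclusion_roi: Roi, background_roi: Roi, ddof: int = 1) -> float:
    """Inclusion/background contrast-to-noise ratio in dB.

    ``20 log10(|mean_inc - mean_bg| / SD_bg)``; equal region means give
    ``-inf``; a zero background SD is rejected.
    """
    s_inc = roi_stats(m, inclusion_roi, ddof=ddof)
    s_bg = roi_stats(m, background_roi, ddof=ddof)
    if s_bg["sd"] == 0:
        raise ValueError("background SD is zero; CNR undefined")
    contrast = abs(s_inc["mean"] - s_bg["mean"])
    if contrast == 0:
        return -math.inf
    return 20.0 * math.log10(contrast / s_bg["sd"])


def nominal_speed(E: float, rho: float = 1000.0) -> float:
    """Nominal shear-wave speed ``sqrt(E / (3 rho))`` of an elastic medium."""
    if E <= 0 or rho <= 0:
        raise ValueError("E and rho must be strictly positive")
    return math.sqrt(E / (3.0 * rho))


def wavelength(c: float, f: float) -> float:
    """Shear wavelength ``lambda = c / f`` (m)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return c / f


def cross_profile(
    m: PhaseVelocityMap, depth: float, smooth: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Lateral profile of the map at the row nearest ``depth``.

    With ``smooth`` the profile is averaged over the row and its two
    neighbours (valid pixels only).  Returns ``(x, profile)``.
    """
    z = m.z
    if depth < z[0] - m.dz / 2 or depth > z[-1] + m.dz / 2:
        raise ValueError(f"depth {depth * 1e3:.2f} mm outside the map grid")
    i = int(np.argmin(np.abs(z - depth)))
    rows = m.cph[max(i - 1, 0) : i + 2] if smooth else m.cph[i : i + 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(rows, axis=0)
    return m.x.copy(), profile


def profile_edges(
    x: np.ndarray,
    profile: np.ndarray,
    inner_mean: Optional[float] = None,
    outer_mean: Optional[float] = None,
) -> np.ndarray:
    """Positions where a profile crosses the midpoint between region means.

    By default the inner mean is taken over the central quarter of the
    valid profile and the outer mean over the first and last quarters;
    crossings are linearly interpolated between samples.  Returns an array
    of edge positions (m), empty for a flat profile.
    """
    valid = np.isfinite(profile)
    xv, pv = x[valid], profile[valid]
    if xv.size < 8:
        raise ValueError("profile too short for edge detection")
    q = xv.size // 4
    if inner_mean is None:
        mid = xv.size // 2
        inner_mean = float(pv[mid - q // 2 : mid + q // 2 + 1].mean())
    if outer_mean is None:
        outer_mean = float(np.concatenate([pv[:q], pv[-q:]]).mean())
    if inner_mean == outer_mean:
        return np.array([])
    level = 0.5 * (inner_mean + outer_mean)
    s = pv - level
    crossings = []
    for i in np.where(np.diff(np.signbit(s)))[0]:
        x0, x1 = xv[i], xv[i + 1]
        y0, y1 = s[i], s[i + 1]
        crossings.append(x0 - y0 * (x1 - x0) / (y1 - y0))
    return np.asarray(crossings)
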