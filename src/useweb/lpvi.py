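"""Local Phase Velocity Imaging (LPVI) — the baseline reconstructor.

LPVI transforms the wavefield to the temporal-frequency domain, selects the
complex spatial field ``V(z, x)`` at the analysis frequency, and performs a
short-space 2D spatial Fourier transform over sliding Tukey windows; the
dominant local wavenumber within a velocity search annulus gives
``c_ph = 2 pi f0 / |k|`` per window.  An optional velocity-band Butterworth
wavenumber filter (k-filter) can be applied to the frequency frame before
windowing.  Window geometry, peak picking and map assembly are shared with
the slant-wavenumber reconstructor so the two methods are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import KFilterSpec, directional_filter, equalize_lateral, push_mute
from .reconstruct import (
    PhaseVelocityMap,
    WindowSpec,
    _combine_direction_maps,
    _direction_plan,
    _mask_muted_columns,
    _padded_shape,
    _PeakPicker,
    _signal_weight,
)
from .wavefield import Wavefield

__all__ = ["LpviConfig", "temporal_spectrum", "lpvi_map"]


@dataclass
class LpviConfig:
    """Configuration of the LPVI reconstructor (mirrors the slant method's)."""

    f0: float
    window: WindowSpec = field(default_factory=WindowSpec)
    kfilter: Optional[KFilterSpec] = None
    search_band: Tuple[float, float] = (0.5, 10.0)
    pad_factor: float = 4.0
    pushes: Optional[Sequence[float]] = None
    directional: bool = True
    mute: bool = True
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        cmin, cmax = self.search_band
        if not (0 < cmin < cmax):
            raise ValueError("search band must satisfy 0 < c_min < c_max")


def temporal_spectrum(w: Wavefield, f0: float, pad: int = 2) -> Tuple[np.ndarray, float]:
    """Per-pixel temporal Fourier coefficient at the bin nearest ``f0``.

    The record is zero-padded ``pad`` times for finer frequency placement.
    Returns the complex field ``V(z, x)`` and the actual bin frequency used.
    """
    if f0 > w.nyquist:
        raise ValueError(f"f0 = {f0:.0f} Hz exceeds the Nyquist limit {w.nyquist:.0f} Hz")
    n = int(w.nt * pad)
    freqs = np.fft.rfftfreq(n, w.dt)
    j = int(np.argmin(np.abs(freqs - f0)))
    V = sfft.rfft(w.v, n=n, axis=2)[:, :, j] * w.dt
    return V, float(freqs[j])


def _apply_kfilter(V: np.ndarray, spec: KFilterSpec, f: float, dz: float, dx: float) -> np.ndarray:
    kz = 2 * np.pi * np.fft.fftfreq(V.shape[0], dz)
    kx = 2 * np.pi * np.fft.fftfreq(V.shape[1], dx)
    kmag = np.hypot(kz[:, None], kx[None, :])
    return sfft.ifft2(sfft.fft2(V) * spec.gain(kmag, f))


def lpvi_map(w: Wavefield, cfg: LpviConfig) -> PhaseVelocityMap:
    """Reconstruct a phase-velocity map with the short-space 2D-FT method."""
    wz, wx = cfg.window.samples(w.dz, w.dx)
    if wz > w.nz or wx > w.nx:
        raise ValueError("analysis window is larger than the field of view")
    stride = cfg.window.stride
    taper = cfg.window.taper2d(wz, wx)
    npz, npx = _padded_shape(wz, wx, cfg.pad_factor)
    kz = 2 * np.pi * np.fft.fftfreq(npz, w.dz)
    kx = 2 * np.pi * np.fft.fftfreq(npx, w.dx)

    plan = _direction_plan(w, cfg.pushes)
    if cfg.mute and cfg.pushes:
        w = push_mute(w, cfg.pushes)
    maps, weights = [], []
    f_used = cfg.f0
    for direction, _xp in plan:
        wd = directional_filter(w, direction) if (cfg.directional and direction) else w
        weights.append(_signal_weight(wd, cfg.f0)[None, :])
        if cfg.equalize:
            wd = equalize_lateral(wd)
        V, f_used = temporal_spectrum(wd, cfg.f0)
        if cfg.kfilter is not None:
            V = _apply_kfilter(V, cfg.kfilter, f_used, w.dz, w.dx)
        picker = _PeakPicker(kz, kx, f_used, cfg.search_band)
        za = np.arange(0, w.nz - wz + 1, stride)
        xa = np.arange(0, w.nx - wx + 1, stride)
        full = np.full((w.nz, w.nx), np.nan)
        fullq = np.zeros((w.nz, w.nx))
        row_chunk = max(1, int(2.5e7 / (len(xa) * npz * npx * 4)))
        lattice = np.full((len(za), len(xa)), np.nan)
        lattice_q = np.zeros((len(za), len(xa)))
        for c0 in range(0, len(za), row_chunk):
            rows = za[c0 : c0 + row_chunk]
            block = V[rows[0] : rows[-1] + wz]
            sw = sliding_window_view(block, (wz, wx))[::stride, ::stride]
            spec = np.abs(sfft.fft2(sw * taper, s=(npz, npx), axes=(-2, -1)))
            _, _, kmag, q = picker.pick_with_quality(spec.astype(np.float32, copy=False))
            with np.errstate(divide="ignore", invalid="ignore"):
                lattice[c0 : c0 + len(rows)] = 2 * np.pi * f_used / kmag
            lattice_q[c0 : c0 + len(rows)] = q
        full[np.ix_(za + wz // 2, xa + wx // 2)] = lattice
        fullq[np.ix_(za + wz // 2, xa + wx // 2)] = lattice_q
        maps.append(full)
    cph = _combine_direction_maps(maps, weights)
    if cfg.mute and cfg.pushes:
        cph = _mask_muted_columns(cph, w.x, cfg.pushes)
    return PhaseVelocityMap(
        cph=cph,
        f0=f_used,
        dz=w.dz,
        dx=w.dx,
        z0=w.z0,
        x0=w.x0,
        method="lpvi",
        meta={
            "window_mm": (cfg.window.height * 1e3, cfg.window.width * 1e3),
            "stride": stride,
            "pad_factor": cfg.pad_factor,
            "kfilter": cfg.kfilter is not None,
        },
    )
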