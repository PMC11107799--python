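"""2D phase-velocity imaging via slant wavenumber analysis (USEWEB core).

Pipeline per direction of travel:

1. directional filtering of the wavefield (optional, :mod:`useweb.preprocess`);
2. S-transform decomposition at the analysis frequency or band
   (:mod:`useweb.stockwell`), giving a complex field ``H(z, x, tau)``;
3. slant slicing along lines ``tau = xbar / u`` through the push event, for a
   series of steering group velocities ``u`` — when ``u`` matches the local
   group velocity the slice follows the wave-arrival ridge and the whole
   spatial window carries the coherent phase ``exp(-i k xbar)``;
4. per spatial window: 2D spatial spectrum amplitude of the slant slice
   (zero-padded FFT), maximised element-wise over the steering series;
5. the spectral peak within a velocity search annulus gives the local
   wavenumber magnitude, and ``c_ph = 2 pi f0 / |k|`` the pixel value.

With two pushes the left-to-right and right-to-left intermediate maps are
averaged.  All wavenumbers are rad/m internally; the FFT axes (cycles/m)
are converted once where they are created.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import h5py
import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import tukey

from .preprocess import MUTE_RADIUS, MUTE_TAPER, directional_filter, equalize_lateral, push_mute
from .stockwell import SpectralVolume, STransformConfig, decompose
from .wavefield import Wavefield

__all__ = [
    "WindowSpec",
    "SteeringGrid",
    "PhaseVelocityMap",
    "UsewebConfig",
    "extract_window",
    "slant_slice",
    "spectral_amplitude",
    "max_over_steering",
    "pick_wavenumber",
    "reconstruct_map",
    "save_map",
    "load_map",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class WindowSpec:
    """Sliding spatial analysis window.

    ``height`` x ``width`` in metres (rounded to an odd number of samples so
    the window has a centre pixel); ``taper`` is the Tukey cosine-taper ratio
    (0 = rectangular, 1 = Hann); ``stride`` is the lattice step, in samples,
    between window centres.
    """

    height: float = 4.47e-3
    width: float = 4.47e-3
    taper: float = 0.25
    stride: int = 1

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("window dimensions must be positive")
        if not (0 <= self.taper <= 1):
            raise ValueError("taper ratio must be in [0, 1]")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def samples(self, dz: float, dx: float) -> Tuple[int, int]:
        """Odd sample counts (rows, cols) covering the window extent."""
        wz = max(int(round(self.height / dz)) | 1, 3)
        wx = max(int(round(self.width / dx)) | 1, 3)
        return wz, wx

    def taper2d(self, wz: int, wx: int) -> np.ndarray:
        return np.outer(tukey(wz, self.taper), tukey(wx, self.taper))


@dataclass(frozen=True)
class SteeringGrid:
    """Series of steering group velocities ``u_m = xbar_m / (t_m - m dt)``.

    ``xbar_m`` is the maximum lateral distance from the push within the FOV
    and ``t_m`` the record length, so the slant lines pivot at the push event
    and sweep the whole space-time plane.  The series is clamped to
    ``[u_min, u_max]`` (unclamped it tails into uselessly small velocities)
    and uniformly decimated to at most ``max_values`` entries, which already
    oversamples the steering-alignment width of the Gaussian voice envelope.
    """

    u_min: float = 0.5
    u_max: float = 15.0
    max_values: int = 64

    def __post_init__(self) -> None:
        if not (0 < self.u_min < self.u_max):
            raise ValueError("require 0 < u_min < u_max")
        if self.max_values < 1:
            raise ValueError("max_values must be >= 1")

    def values(self, x_max: float, t_max: float, dt: float) -> np.ndarray:
        if x_max <= 0 or t_max <= dt:
            raise ValueError("degenerate steering geometry")
        m = np.arange(int(math.floor((t_max - 1e-12) / dt)))
        denom = t_max - m * dt
        u = x_max / denom
        u = u[(u >= self.u_min) & (u <= self.u_max)]
        if u.size == 0:
            raise ValueError(
                f"no steering velocities in [{self.u_min}, {self.u_max}] m/s for "
                f"x_max={x_max:.3g} m, t_max={t_max:.3g} s"
            )
        if u.size > self.max_values:
            idx = np.unique(np.round(np.linspace(0, u.size - 1, self.max_values)).astype(int))
            u = u[idx]
        return u


@dataclass
class PhaseVelocityMap:
    """2D phase-velocity image ``c_ph(z, x)`` at one frequency (or band)."""

    cph: np.ndarray
    f0: float
    dz: float
    dx: float
    z0: float = 0.0
    x0: float = 0.0
    method: str = "useweb"
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        """Valid-pixel mask (True where a velocity was reconstructed)."""
        return np.isfinite(self.cph)

    @property
    def z(self) -> np.ndarray:
        return self.z0 + self.dz * np.arange(self.cph.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.cph.shape[1])


def save_map(path, m: PhaseVelocityMap) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("cph", data=m.cph, track_times=False)
        h5.create_dataset("mask", data=m.mask, track_times=False)
        for name in ("f0", "dz", "dx", "z0", "x0"):
            h5.create_dataset(name, data=float(getattr(m, name)), track_times=False)
        h5.attrs["method"] = m.method
        for key, val in m.meta.items():
            try:
                h5.attrs[key] = val
            except TypeError:
                h5.attrs[key] = str(val)


def load_map(path) -> PhaseVelocityMap:
    with h5py.File(path, "r") as h5:
        attrs = dict(h5.attrs)
        return PhaseVelocityMap(
            cph=h5["cph"][...],
            f0=float(h5["f0"][()]),
            dz=float(h5["dz"][()]),
            dx=float(h5["dx"][()]),
            z0=float(h5["z0"][()]),
            x0=float(h5["x0"][()]),
            method=str(attrs.pop("method", "useweb")),
            meta=attrs,
        )


@dataclass
class UsewebConfig:
    """Everything :func:`reconstruct_map` needs besides the wavefield."""

    stransform: STransformConfig
    window: WindowSpec = field(default_factory=WindowSpec)
    steering: SteeringGrid = field(default_factory=SteeringGrid)
    search_band: Tuple[float, float] = (0.5, 10.0)
    pad_factor: float = 4.0
    band_policy: str = "mean_k"  # or "mean_map"
    pushes: Optional[Sequence[float]] = None
    directional: bool = True
    mute: bool = True
    equalize: bool = True
    dtype: type = np.complex128

    def __post_init__(self) -> None:
        cmin, cmax = self.search_band
        if not (0 < cmin < cmax):
            raise ValueError("search band must satisfy 0 < c_min < c_max")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if self.band_policy not in ("mean_k", "mean_map"):
            raise ValueError(f"unknown band policy {self.band_policy!r}")


# ---------------------------------------------------------------------------
# elementary operations (single-window granularity)
# ---------------------------------------------------------------------------
def extract_window(
    H: SpectralVolume, center: Tuple[float, float], spec: WindowSpec
) -> Tuple[np.ndarray, Tuple[slice, slice]]:
    """Tukey-windowed sub-volume of ``H`` around a physical centre (z, x).

    The taper is constant along tau.  Windows straddling the FOV edge are
    clipped to the intersection (the matching part of the taper is used);
    an empty intersection raises.
    Returns ``(Hw, (z_slice, x_slice))`` with the index ranges used.
    """
    nz, nx = H.H.shape[:2]
    wz, wx = spec.samples(H.dz, H.dx)
    iz = int(round((center[0] - H.z0) / H.dz))
    ix = int(round((center[1] - H.x0) / H.dx))
    z_lo, z_hi = iz - wz // 2, iz + wz // 2 + 1
    x_lo, x_hi = ix - wx // 2, ix + wx // 2 + 1
    if z_hi <= 0 or z_lo >= nz or x_hi <= 0 or x_lo >= nx:
        raise ValueError("window footprint does not intersect the field of view")
    zc = slice(max(z_lo, 0), min(z_hi, nz))
    xc = slice(max(x_lo, 0), min(x_hi, nx))
    taper = spec.taper2d(wz, wx)[
        zc.start - z_lo : zc.stop - z_lo, xc.start - x_lo : xc.stop - x_lo
    ]
    return H.H[zc, xc] * taper[:, :, None], (zc, xc)


def slant_slice(Hw: np.ndarray, u: float, x_from_push: np.ndarray, dt: float) -> np.ndarray:
    """Constant-time slant slice ``SF(zbar, xbar) = Hw(zbar, xbar, xbar/u)``.

    ``x_from_push`` gives, per window column, the lateral distance (m) from
    the active push line, so the slant lines pivot at the push event.  The
    slice time is linearly interpolated between frames and is zero beyond
    the record.
    """
    if u <= 0:
        raise ValueError("steering group velocity must be positive")
    Hw = np.asarray(Hw)
    nt = Hw.shape[2]
    pos = np.asarray(x_from_push, dtype=float) / (u * dt)  # fractional frame index
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    valid = (pos >= 0) & (i0 <= nt - 1)
    i0c = np.clip(i0, 0, nt - 1)
    i1c = np.clip(i0 + 1, 0, nt - 1)
    cols = np.arange(Hw.shape[1])
    sf = Hw[:, cols, i0c] * (1.0 - frac) + Hw[:, cols, i1c] * frac
    sf[:, ~valid] = 0.0
    return sf


def _padded_shape(wz: int, wx: int, pad_factor: float) -> Tuple[int, int]:
    return (
        sfft.next_fast_len(int(math.ceil(wz * pad_factor))),
        sfft.next_fast_len(int(math.ceil(wx * pad_factor))),
    )


def spectral_amplitude(
    SF: np.ndarray, dz: float, dx: float, pad_factor: float = 4.0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude of the 2D spatial spectrum of a slant slice.

    Zero-padded FFT per axis, scaled by the cell area so it approximates the
    continuous transform.  Returns ``(Lambda, kz, kx)`` with wavenumber axes
    in rad/m, FFT (unshifted) ordering.
    """
    if not np.all(np.isfinite(SF)):
        raise ValueError("slant slice contains non-finite values")
    npz, npx = _padded_shape(SF.shape[0], SF.shape[1], pad_factor)
    lam = np.abs(sfft.fft2(SF, s=(npz, npx))) * dz * dx
    kz = 2 * np.pi * np.fft.fftfreq(npz, dz)
    kx = 2 * np.pi * np.fft.fftfreq(npx, dx)
    return lam, kz, kx


def max_over_steering(lam_stack: np.ndarray) -> np.ndarray:
    """Element-wise maximum over the steering-velocity axis (axis 0)."""
    lam_stack = np.asarray(lam_stack)
    if lam_stack.ndim < 3 or lam_stack.shape[0] < 1:
        raise ValueError("need a stack with at least one steering value")
    return lam_stack.max(axis=0)


class _PeakPicker:
    """Annulus-restricted spectral argmax with deterministic tie-breaks.

    Restricts to ``2 pi f0 / c_max <= |k| <= 2 pi f0 / c_min``, scans bins in
    ascending (|k|, kx) order so that exact ties resolve to the smallest
    wavenumber (then smallest kx), and refines the peak with independent
    3-point parabolic interpolation along kz and kx.
    """

    def __init__(self, kz, kx, f0, search_band, refine=True):
        self.kz = np.asarray(kz)
        self.kx = np.asarray(kx)
        self.f0 = float(f0)
        cmin, cmax = search_band
        kmag = np.hypot(self.kz[:, None], self.kx[None, :])
        kmin = 2 * np.pi * f0 / cmax
        kmax = 2 * np.pi * f0 / cmin
        mask = (kmag >= kmin) & (kmag <= kmax)
        if not mask.any():
            raise ValueError(
                f"velocity band {search_band} m/s maps to an empty wavenumber annulus "
                "at this padding; increase pad_factor or widen the band"
            )
        flat_keys = np.broadcast_to(self.kx[None, :], kmag.shape).ravel()
        self.order = np.lexsort((flat_keys, kmag.ravel()))
        self.order = self.order[mask.ravel()[self.order]]
        self.refine = refine
        self.shape = kmag.shape
        self.dkz = abs(self.kz[1] - self.kz[0])
        self.dkx = abs(self.kx[1] - self.kx[0])
        # signed bin index per axis (monotone surrogate for the wrapped axes)
        self.iz_signed = np.fft.fftfreq(self.shape[0]) * self.shape[0]
        self.ix_signed = np.fft.fftfreq(self.shape[1]) * self.shape[1]

    @staticmethod
    def _parabolic_offset(km, k0, kp):
        denom = km - 2.0 * k0 + kp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (km - kp) / denom
        delta = np.where((denom < 0) & np.isfinite(delta), delta, 0.0)
        return np.clip(delta, -0.5, 0.5)

    def pick(self, K: np.ndarray):
        """Peak of one or many spectra.

        ``K``: array (..., n_kz, n_kx), non-negative amplitudes in FFT
        ordering.  Returns ``(kz_pk, kx_pk, kmag)`` arrays of the leading
        shape, NaN where no positive peak exists inside the annulus.
        """
        kz_pk, kx_pk, kmag, _ = self.pick_with_quality(K)
        return kz_pk, kx_pk, kmag

    def pick_with_quality(self, K: np.ndarray):
        """Like :meth:`pick`, plus the peak prominence (peak / annulus median)."""
        K = np.asarray(K)
        lead = K.shape[:-2]
        flat = K.reshape(-1, K.shape[-2] * K.shape[-1])
        sel = flat[:, self.order]
        best = np.argmax(sel, axis=1)
        peak_val = sel[np.arange(sel.shape[0]), best]
        med = np.median(sel, axis=1)
        flat_idx = self.order[best]
        p = flat_idx // self.shape[1]
        q = flat_idx % self.shape[1]
        if self.refine:
            nz_, nx_ = self.shape
            kzm = flat[np.arange(flat.shape[0]), (p - 1) % nz_ * nx_ + q]
            kzp = flat[np.arange(flat.shape[0]), (p + 1) % nz_ * nx_ + q]
            kxm = flat[np.arange(flat.shape[0]), p * nx_ + (q - 1) % nx_]
            kxp = flat[np.arange(flat.shape[0]), p * nx_ + (q + 1) % nx_]
            dz_off = self._parabolic_offset(kzm, peak_val, kzp)
            dx_off = self._parabolic_offset(kxm, peak_val, kxp)
        else:
            dz_off = np.zeros(flat.shape[0])
            dx_off = np.zeros(flat.shape[0])
        kz_pk = (self.iz_signed[p] + dz_off) * self.dkz
        kx_pk = (self.ix_signed[q] + dx_off) * self.dkx
        bad = ~(peak_val > 0) | ~np.isfinite(peak_val)
        kz_pk = np.where(bad, np.nan, kz_pk)
        kx_pk = np.where(bad, np.nan, kx_pk)
        kmag = np.hypot(kz_pk, kx_pk)
        with np.errstate(divide="ignore", invalid="ignore"):
            quality = np.where(med > 0, peak_val / med, np.where(peak_val > 0, np.inf, 0.0))
        quality = np.where(bad, 0.0, quality)
        return (
            kz_pk.reshape(lead),
            kx_pk.reshape(lead),
            kmag.reshape(lead),
            quality.reshape(lead),
        )


def pick_wavenumber(
    K: np.ndarray,
    kz: np.ndarray,
    kx: np.ndarray,
    f0: float,
    search_band: Tuple[float, float] = (0.5, 10.0),
    refine: bool = True,
) -> Tuple[float, float, float]:
    """Locate the dominant wavenumber of a single spectrum ``K(kz, kx)``.

    The search is restricted to the annulus mapped out by the velocity band;
    exact ties resolve to the smallest ``|k|`` then smallest ``kx``.
    Returns ``(kz, kx, |k|)`` in rad/m.
    """
    picker = _PeakPicker(kz, kx, f0, search_band, refine=refine)
    kz_pk, kx_pk, kmag = picker.pick(K[None, ...])
    return float(kz_pk[0]), float(kx_pk[0]), float(kmag[0])


# ---------------------------------------------------------------------------
# full-map reconstruction
# ---------------------------------------------------------------------------
def _direction_plan(w: Wavefield, pushes: Optional[Sequence[float]]):
    """(direction, push position) pairs for the acquisitions to reconstruct."""
    if not pushes:
        return [(None, float(w.x0))]
    pushes = sorted(float(p) for p in pushes)
    if len(pushes) == 1:
        xp = pushes[0]
        mid = w.x0 + 0.5 * w.dx * (w.nx - 1)
        return [("left_to_right" if xp <= mid else "right_to_left", xp)]
    return [("left_to_right", pushes[0]), ("right_to_left", pushes[-1])]


def _interp_slant(H: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear time interpolation of ``H(z, x, t)`` at per-column frame index."""
    nt = H.shape[2]
    i0 = np.floor(pos).astype(int)
    frac = (pos - i0).astype(H.real.dtype)
    valid = (pos >= 0) & (i0 <= nt - 1)
    i0c = np.clip(i0, 0, nt - 1)
    i1c = np.clip(i0 + 1, 0, nt - 1)
    cols = np.arange(H.shape[1])
    out = H[:, cols, i0c] * (1.0 - frac) + H[:, cols, i1c] * frac
    out[:, ~valid] = 0.0
    return out


def _map_one_direction(
    volumes: Sequence[SpectralVolume],
    d_from_push: np.ndarray,
    cfg: UsewebConfig,
    t_max: float,
) -> np.ndarray:
    H0 = volumes[0]
    nz, nx, nt = H0.H.shape
    dz, dx, dt = H0.dz, H0.dx, H0.dt
    wz, wx = cfg.window.samples(dz, dx)
    if wz > nz or wx > nx:
        raise ValueError("analysis window is larger than the field of view")
    stride = cfg.window.stride
    taper = cfg.window.taper2d(wz, wx)
    npz, npx = _padded_shape(wz, wx, cfg.pad_factor)
    kz = 2 * np.pi * np.fft.fftfreq(npz, dz)
    kx = 2 * np.pi * np.fft.fftfreq(npx, dx)
    u_values = cfg.steering.values(float(d_from_push.max()), t_max, dt)

    za = np.arange(0, nz - wz + 1, stride)  # top rows of windows
    xa = np.arange(0, nx - wx + 1, stride)
    centers_z = za + wz // 2
    centers_x = xa + wx // 2

    f0_center = cfg.stransform.f0
    if cfg.band_policy == "mean_map":
        pickers = [
            _PeakPicker(kz, kx, vol.f0, cfg.search_band) for vol in volumes
        ]
    else:
        pickers = [_PeakPicker(kz, kx, f0_center, cfg.search_band)]

    cmaps = np.full((len(pickers), len(za), len(xa)), np.nan)
    quals = np.zeros((len(pickers), len(za), len(xa)))
    row_chunk = max(1, int(2.5e7 / (len(xa) * npz * npx * 4)))
    cdtype = np.complex64 if cfg.dtype == np.complex64 else np.complex128
    for c0 in range(0, len(za), row_chunk):
        rows = za[c0 : c0 + row_chunk]
        r_lo, r_hi = rows[0], rows[-1] + wz
        acc_mean = None
        per_vol = []
        for vol in volumes:
            Hrows = np.ascontiguousarray(vol.H[r_lo:r_hi], dtype=cdtype)
            acc_max = None
            for u in u_values:
                pos = d_from_push / (u * dt)
                G = _interp_slant(Hrows, pos)
                sw = sliding_window_view(G, (wz, wx))[::stride, ::stride]
                patches = sw * taper
                spec = np.abs(sfft.fft2(patches, s=(npz, npx), axes=(-2, -1)))
                spec = spec.astype(np.float32, copy=False)
                acc_max = spec if acc_max is None else np.maximum(acc_max, spec, out=acc_max)
            if cfg.band_policy == "mean_map":
                per_vol.append(acc_max)
            else:
                acc_mean = acc_max if acc_mean is None else acc_mean + acc_max
        if cfg.band_policy == "mean_map":
            stacks = per_vol
        else:
            stacks = [acc_mean / len(volumes)]
        for i, (picker, stack) in enumerate(zip(pickers, stacks)):
            _, _, kmag, q = picker.pick_with_quality(stack)
            with np.errstate(divide="ignore", invalid="ignore"):
                cmaps[i, c0 : c0 + len(rows)] = 2 * np.pi * picker.f0 / kmag
            quals[i, c0 : c0 + len(rows)] = q

    cmap_lattice = _nanmean(cmaps, axis=0)
    qual_lattice = quals.mean(axis=0)
    full = np.full((nz, nx), np.nan)
    full[np.ix_(centers_z, centers_x)] = cmap_lattice
    fullq = np.zeros((nz, nx))
    fullq[np.ix_(centers_z, centers_x)] = qual_lattice
    return full, fullq


def _nanmean(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=axis)


def _signal_weight(wd: Wavefield, f0: float) -> np.ndarray:
    """Lateral signal-power profile of a filtered field at the analysis frequency.

    Mean squared magnitude over depth of the temporal Fourier coefficient at
    the bin nearest ``f0`` — i.e. how much wave this acquisition actually
    carries at each lateral position, before any amplitude equalisation.
    """
    freqs = np.fft.rfftfreq(wd.nt, wd.dt)
    j = int(np.argmin(np.abs(freqs - f0)))
    t = wd.t
    coeff = np.tensordot(wd.v, np.exp(-2j * np.pi * freqs[j] * t), axes=([2], [0])) * wd.dt
    return np.mean(np.abs(coeff) ** 2, axis=0)  # (nx,)


def _mask_muted_columns(cph: np.ndarray, x: np.ndarray, pushes: Sequence[float]) -> np.ndarray:
    """NaN-mask pixels whose lateral position lies in a muted push zone."""
    out = cph.copy()
    for xp in pushes:
        out[:, np.abs(x - float(xp)) < MUTE_RADIUS + MUTE_TAPER] = np.nan
    return out


def _combine_direction_maps(maps: Sequence[np.ndarray], weights: Sequence[np.ndarray]) -> np.ndarray:
    """Signal-weighted average of per-direction estimates.

    Each direction reliably covers the side of the FOV nearer its own push;
    far from it the wave has attenuated away and the window estimates are
    noise.  Weighting each direction by its local signal power at the
    analysis frequency lets the acquisition that actually observes a wave
    dominate; where the weights vanish the plain mean is used.
    """
    M = np.stack(maps)
    W = np.stack([np.broadcast_to(w_, m.shape) for w_, m in zip(weights, maps)]).astype(float)
    W = np.where(np.isfinite(M), W, 0.0)
    wsum = W.sum(axis=0)
    num = np.nansum(np.where(W > 0, M * W, 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = num / wsum
    plain = _nanmean(M, axis=0)
    return np.where(wsum > 0, weighted, plain)


def reconstruct_map(w: Wavefield, cfg: UsewebConfig) -> PhaseVelocityMap:
    """Reconstruct the 2D phase-velocity map of a wavefield.

    When ``cfg.pushes`` holds two push positions the field is directionally
    filtered into the left-to-right and right-to-left travelling components,
    each is reconstructed with its own slant origin at its push line, and the
    intermediate maps are averaged (pixels covered by only one direction
    keep that direction's estimate).  Pixels whose windows exceed the FOV or
    fall off the stride lattice are NaN-masked.
    """
    plan = _direction_plan(w, cfg.pushes)
    t_max = w.nt * w.dt
    if cfg.mute and cfg.pushes:
        w = push_mute(w, cfg.pushes)
    maps, weights = [], []
    for direction, xp in plan:
        wd = directional_filter(w, direction) if (cfg.directional and direction) else w
        weights.append(_signal_weight(wd, cfg.stransform.f0)[None, :])
        if cfg.equalize:
            wd = equalize_lateral(wd)
        volumes = decompose(wd, cfg.stransform, dtype=cfg.dtype)
        d = np.abs(w.x - xp)
        m, _q = _map_one_direction(volumes, d, cfg, t_max)
        maps.append(m)
    cph = _combine_direction_maps(maps, weights)
    if cfg.mute and cfg.pushes:
        cph = _mask_muted_columns(cph, w.x, cfg.pushes)
    return PhaseVelocityMap(
        cph=cph,
        f0=cfg.stransform.f0,
        dz=w.dz,
        dx=w.dx,
        z0=w.z0,
        x0=w.x0,
        method="useweb",
        meta={
            "window_mm": (cfg.window.height * 1e3, cfg.window.width * 1e3),
            "stride": cfg.window.stride,
            "pad_factor": cfg.pad_factor,
            "band_policy": cfg.band_policy,
            "fb": cfg.stransform.fb,
        },
    )
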