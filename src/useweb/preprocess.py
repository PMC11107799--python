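"""Wavefield conditioning before reconstruction.

Directional filtering separates left-to-right and right-to-left travelling
shear waves in the lateral/temporal spectrum; the wavenumber band-pass
(k-filter) attenuates spatial wavelengths outside a velocity-derived band;
DC removal and depth averaging are the small utilities used by the 1D
dispersion estimators.

All frequency-domain operations pad the transformed axes by 25% (reflected
samples) before the FFT and crop afterwards, to limit circular-wraparound
artifacts; shapes and grid metadata are always preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .wavefield import Wavefield

__all__ = [
    "KFilterSpec",
    "directional_filter",
    "equalize_lateral",
    "k_bandpass",
    "remove_dc",
    "depth_average",
    "push_mute",
]

PAD_FRACTION = 0.25


@dataclass(frozen=True)
class KFilterSpec:
    """Velocity-band wavenumber filter specification.

    At each temporal frequency ``f`` the passband covers wavenumber
    magnitudes ``k`` between ``2 pi f / (v0 + dv)`` and ``2 pi f / (v0 - dv)``
    (rad/m), realised as a Butterworth band-pass of the given order.
    """

    v0: float
    dv: float = 1.0
    order: int = 1

    def __post_init__(self) -> None:
        if self.v0 - self.dv <= 0:
            raise ValueError(f"require v0 - dv > 0, got v0={self.v0}, dv={self.dv}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def band(self, f: float) -> tuple[float, float]:
        """(k_low, k_high) in rad/m at temporal frequency ``f`` (Hz)."""
        f = abs(f)
        return 2 * np.pi * f / (self.v0 + self.dv), 2 * np.pi * f / (self.v0 - self.dv)

    def gain(self, k: np.ndarray, f: float) -> np.ndarray:
        """Butterworth band-pass magnitude response at wavenumber ``k``."""
        klo, khi = self.band(f)
        if khi <= 0:
            # degenerate zero-frequency band: pass DC only
            return (np.asarray(k) == 0).astype(float)
        kc = np.sqrt(klo * khi)
        bw = khi - klo
        k = np.asarray(k, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(k > 0, kc / bw * (k / kc - kc / k), np.inf)
        return 1.0 / np.sqrt(1.0 + q ** (2 * self.order))


def _pad_amount(n: int) -> int:
    return max(int(round(n * PAD_FRACTION)), 2)


def _reflect_pad(a: np.ndarray, axes: tuple[int, ...]) -> tuple[np.ndarray, list]:
    pads = [(0, 0)] * a.ndim
    for ax in axes:
        p = min(_pad_amount(a.shape[ax]), a.shape[ax] - 1)
        pads[ax] = (p, p)
    return np.pad(a, pads, mode="reflect"), pads


def _crop(a: np.ndarray, pads: list) -> np.ndarray:
    sl = tuple(slice(p[0], a.shape[i] - p[1]) for i, p in enumerate(pads))
    return a[sl]


def _direction_weight(n_kx: int, taper_bins: int) -> np.ndarray:
    """Weight over the kx axis passing kx < 0 (FFT ordering), half at kx = 0.

    A raised-cosine transition of ``taper_bins`` bins on each side of kx = 0
    limits ringing from the hard spectral edge.
    """
    kx = np.fft.fftfreq(n_kx, d=1.0)  # sign carrier only
    w = np.where(kx < 0, 1.0, 0.0)
    w[kx == 0] = 0.5
    if n_kx % 2 == 0:
        w[n_kx // 2] = 0.5  # Nyquist bin is its own mirror: share it too
    if taper_bins > 0:
        idx = np.fft.fftfreq(n_kx, d=1.0 / n_kx)  # signed bin index
        band = np.abs(idx) <= taper_bins
        w[band] = 0.5 * (1.0 - np.sin(0.5 * np.pi * idx[band] / taper_bins))
    return w


def directional_filter(
    w: Wavefield, direction: str, taper_bins: int = 3, equalize: bool = True
) -> Wavefield:
    """Keep only waves travelling in one lateral direction.

    The field is taken to the temporal-frequency domain; for each frequency
    the spatial spectrum is restricted to the half-plane consistent with the
    requested travel direction (a wave ``exp(i(2 pi f t - k x))`` with
    ``k > 0`` travels left-to-right, i.e. occupies ``f kx < 0`` in FFT sign
    convention).  The kx = 0 ridge is shared half/half between the two
    directions, so the left- and right-filtered fields sum back to the input
    up to the shared ridge; a raised-cosine transition of ``taper_bins``
    limits ringing.

    With ``equalize`` (default) every frequency frame is divided by its own
    smoothed lateral magnitude envelope before masking and multiplied back
    afterwards.  A half-plane mask has a spatial kernel with 1/x tails; on
    strongly attenuated wavefields the tails shed by the near-push columns
    would otherwise swamp the distant signal.  Equalisation reduces each
    frame to (nearly) pure phase, for which the half-plane split is
    essentially exact; amplitudes are fully restored afterwards, and for
    amplitude-uniform fields the step is a no-op.
    """
    if direction not in ("left_to_right", "right_to_left"):
        raise ValueError(f"unknown direction {direction!r}")
    if w.nx < 4 or w.nt < 4:
        raise ValueError("need at least 4 samples along x and t")
    V = sfft.rfft(w.v, axis=2)  # (nz, nx, nf), frequencies f >= 0
    if equalize:
        gain = _lateral_gain(V, w.dx)
        V = V * gain[None, :, :]
    # reflect-pad the lateral axis to limit wrap-around of the mask kernel
    p = min(_pad_amount(w.nx), w.nx - 1)
    V = np.pad(V, ((0, 0), (p, p), (0, 0)), mode="reflect")
    n_kx = V.shape[1]
    w_neg = _direction_weight(n_kx, taper_bins)  # passes kx < 0 <=> rightward, f > 0
    w_pos = np.roll(w_neg[::-1], 1)
    keep = w_neg if direction == "left_to_right" else w_pos
    V0 = V[:, p : p + w.nx, 0].copy()
    Vk = sfft.fft(V, axis=1)
    Vk *= keep[None, :, None]
    V = sfft.ifft(Vk, axis=1)[:, p : p + w.nx, :]
    V[:, :, 0] = 0.5 * V0  # the f = 0 plane is direction-less: share half/half
    if equalize:
        V = V / gain[None, :, :]
    out = sfft.irfft(V, n=w.nt, axis=2)
    return w.with_v(out)


def k_bandpass(w: Wavefield, spec: KFilterSpec) -> Wavefield:
    """Velocity-band Butterworth wavenumber filter, per temporal frequency.

    The field is transformed over time; each temporal-frequency frame is
    filtered in the 2D spatial-frequency domain on the wavenumber magnitude
    ``sqrt(kz^2 + kx^2)`` with the band derived from ``spec`` at that
    frequency.  Output is real with the input shape.
    """
    vp, pads = _reflect_pad(w.v, axes=(0, 1))
    V = sfft.rfft(vp, axis=2)
    freqs = np.fft.rfftfreq(w.nt, w.dt)
    kz = 2 * np.pi * np.fft.fftfreq(vp.shape[0], w.dz)
    kx = 2 * np.pi * np.fft.fftfreq(vp.shape[1], w.dx)
    kmag = np.sqrt(kz[:, None] ** 2 + kx[None, :] ** 2)
    F = sfft.fft2(V, axes=(0, 1))
    for i, f in enumerate(freqs):
        F[:, :, i] *= spec.gain(kmag, f)
    out = sfft.irfft(sfft.ifft2(F, axes=(0, 1)), n=w.nt, axis=2).real
    return w.with_v(_crop(out, pads))


#: default lateral extent of the push-region mute and its cosine roll-off, m
MUTE_RADIUS = 2.5e-3
MUTE_TAPER = 1.0e-3


def push_mute(
    w: Wavefield,
    pushes,
    r_mute: float = MUTE_RADIUS,
    taper_x: float = MUTE_TAPER,
) -> Wavefield:
    """Mute the lateral neighbourhood of the push lines.

    The acoustic-radiation-force region itself carries no usable shear-wave
    signal (motion there is dominated by the push event, and in real
    acquisitions the tracking data under the push beams is unreliable).
    Worse, half-plane directional filtering smears that near-delta spatial
    footprint into a slowly decaying lateral tail that can dominate strongly
    attenuated waves far from the push.  This mute zeroes lateral positions
    within ``r_mute`` of a push line with a cosine roll-off of ``taper_x``.
    It is purely spatial — a multiplication by ``g(x)`` — so it cannot mix
    temporal frequencies (a time-gated mute would: its moving edge slices
    through the strong slow low-frequency packets and radiates broadband,
    fast-phase-velocity artifacts into the analysis band).
    """
    pushes = [float(p) for p in np.atleast_1d(pushes)]
    if not pushes:
        return w.with_v(w.v.copy())
    d = np.min(np.abs(w.x[None, :] - np.asarray(pushes)[:, None]), axis=0)  # (nx,)
    gx = np.clip((d - r_mute) / max(taper_x, 1e-12), 0.0, 1.0)
    gate_x = 0.5 * (1.0 - np.cos(np.pi * gx))
    return w.with_v(w.v * gate_x[None, :, None])


def _lateral_gain(V: np.ndarray, dx: float, smooth: float = 1.0e-3) -> np.ndarray:
    """Inverse lateral magnitude envelope per temporal frequency.

    ``V`` is the rfft of the field over time, shape (nz, nx, nf).  The
    envelope is the z-aggregated magnitude per (x, f), smoothed over ~1 mm
    laterally and floored at 1e-6 of its per-frequency maximum so that
    numerically empty regions are not amplified without bound.
    """
    from scipy.ndimage import gaussian_filter1d

    env = np.sqrt(np.mean(np.abs(V) ** 2, axis=0))  # (nx, nf)
    env = gaussian_filter1d(env, max(smooth / dx, 1.0), axis=0, mode="nearest")
    floor = env.max(axis=0, keepdims=True) * 1e-6
    return 1.0 / np.maximum(env, np.where(floor > 0, floor, 1.0))


def equalize_lateral(w: Wavefield, smooth: float = 1.0e-3) -> Wavefield:
    """Flatten the lateral amplitude decay of every temporal frequency.

    Each frequency frame of the field is divided by its own smoothed lateral
    magnitude envelope (aggregated over depth).  Phases — and therefore all
    wavenumber content — are untouched; what changes is that an attenuated
    travelling wave ``exp(-(alpha + i k) x)`` becomes the pure phase ramp
    ``exp(-i k x)``.  This removes the two ways strong attenuation biases
    spectral peak estimators low: the asymmetric amplitude tilt across an
    analysis window, and the dominance of less-attenuated neighbouring
    frequencies inside a finite-resolution voice.  The price is that in
    regions where the wave has decayed below the noise, noise is amplified
    to unit scale; window estimates there degrade gracefully into masked or
    outlier pixels rather than being biased.
    """
    V = sfft.rfft(w.v, axis=2)
    gain = _lateral_gain(V, w.dx, smooth)
    out = sfft.irfft(V * gain[None, :, :], n=w.nt, axis=2)
    return w.with_v(out)


def remove_dc(w: Wavefield) -> Wavefield:
    """Subtract the temporal mean of every (z, x) trace."""
    return w.with_v(w.v - w.v.mean(axis=2, keepdims=True))


def depth_average(w: Wavefield, center_z: float, span: float) -> np.ndarray:
    """Arithmetic mean over the depth rows within ``center_z +/- span/2``.

    Returns the 2D lateral/temporal field ``v(x, t)``.  A span smaller than
    one row spacing extracts the single nearest row.
    """
    z = w.z
    lo, hi = center_z - span / 2.0, center_z + span / 2.0
    if lo < z[0] - w.dz / 2 or hi > z[-1] + w.dz / 2:
        raise ValueError(
            f"depth span [{lo * 1e3:.2f}, {hi * 1e3:.2f}] mm outside grid "
            f"[{z[0] * 1e3:.2f}, {z[-1] * 1e3:.2f}] mm"
        )
    rows = np.where((z >= lo) & (z <= hi))[0]
    if rows.size == 0:
        rows = np.array([int(np.argmin(np.abs(z - center_z)))])
    return w.v[rows].mean(axis=0)
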