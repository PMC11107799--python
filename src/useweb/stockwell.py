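"""Generalized Stockwell (S-) transform.

The S-transform decomposes a time series into a time-frequency plane using a
frequency-dependent Gaussian window,

    S[v](tau, f) = integral v(t) W(tau - t, f) exp(-i 2 pi f t) dt,

with W a Gaussian of temporal standard deviation ``sqrt(beta)/f``: narrow at
high frequency, wide at low frequency.  Because the oscillatory kernel is
referenced to the time origin (not to ``tau``), the phase of ``S`` at a
voice frequency equals the Fourier phase of that component — a travelling
wave ``cos(2 pi f0 (t - x/c))`` yields ``S(tau, f0) ~ a(tau - x/c)
exp(-i k x)``: a time-localised envelope carrying the spatial phase.  This
is the property the slant wavenumber analysis builds on.

Discretely the transform is the circular convolution of
``v[t] exp(-i 2 pi f t) dt`` with the periodised sampled window, evaluated
per voice with FFTs; it is bit-compatible with the literal O(N^2) summation.

Two amplitude normalisations of the window are provided:

* ``"printed"`` (default): prefactor ``|f| / (2 pi beta)``;
* ``"unit_area"``: prefactor ``|f| / sqrt(2 pi beta)``, which makes the
  window integrate to one so that the time marginal of ``S`` recovers the
  Fourier coefficient exactly.

The two differ by the constant ``sqrt(2 pi beta)`` only; peak positions —
all this package ever extracts — are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import scipy.fft as sfft

from .wavefield import Wavefield

__all__ = ["STransformConfig", "SpectralVolume", "s_transform_1d", "decompose", "voice_window"]


@dataclass(frozen=True)
class STransformConfig:
    """Frequency selection and window scaling for the decomposition.

    ``f0`` is the analysis frequency (Hz).  With ``fb > 0`` a band
    ``f0 - fb ... f0 + fb`` is analysed, sampled at ``n_band`` evenly spaced
    voices.  ``beta`` scales the Gaussian window width (``beta = 1`` is the
    classical S-transform; larger values trade temporal for frequency
    resolution).
    """

    f0: float
    fb: float = 0.0
    beta: float = 1.0
    n_band: int = 5
    normalization: str = "printed"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not (0 <= self.fb < self.f0):
            raise ValueError("require 0 <= fb < f0")
        if self.normalization not in ("printed", "unit_area"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def frequencies(self) -> np.ndarray:
        if self.fb == 0:
            return np.array([self.f0])
        return np.linspace(self.f0 - self.fb, self.f0 + self.fb, self.n_band)


@dataclass
class SpectralVolume:
    """Complex S-transform field ``H(z, x, tau)`` at one voice frequency."""

    H: np.ndarray
    f0: float
    dz: float
    dx: float
    dt: float
    z0: float = 0.0
    x0: float = 0.0

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.H.shape[1])

    @property
    def tau(self) -> np.ndarray:
        return self.dt * np.arange(self.H.shape[2])


def voice_window(
    f: float, n: int, dt: float, beta: float = 1.0, normalization: str = "printed"
) -> np.ndarray:
    """Sampled, periodised Gaussian voice window on the circular lag grid.

    Entry ``i`` holds the window at lag ``((i + n//2) mod n) - n//2`` samples,
    i.e. FFT ordering with wrap-around, summed over enough period images that
    truncation is below double precision.
    """
    if f <= 0:
        raise ValueError("voice frequency must be positive (the window degenerates at f = 0)")
    lags = ((np.arange(n) + n // 2) % n - n // 2) * dt
    T = n * dt
    sigma_t = math.sqrt(beta) / f
    n_wrap = max(1, int(math.ceil(7.0 * sigma_t / T)) + 1)
    acc = np.zeros(n)
    for r in range(-n_wrap, n_wrap + 1):
        acc += np.exp(-(f**2) * (lags + r * T) ** 2 / (2.0 * beta))
    if normalization == "printed":
        pref = abs(f) / (2.0 * np.pi * beta)
    elif normalization == "unit_area":
        pref = abs(f) / math.sqrt(2.0 * np.pi * beta)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return pref * acc


def s_transform_1d(
    signal: np.ndarray,
    f: Union[float, Sequence[float]],
    beta: float = 1.0,
    dt: float = 1.0,
    normalization: str = "printed",
) -> np.ndarray:
    """S-transform of a uniformly sampled series at the given voice frequencies.

    Returns a complex array of shape ``(n_tau, n_f)`` (``n_tau`` equals the
    signal length).  Linear in the input; the time marginal
    ``sum_tau S(tau, f) * dt`` recovers the Fourier coefficient at ``f``
    scaled by the window area (exactly 1 for ``unit_area`` normalisation).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    freqs = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("voice frequencies must be strictly positive")
    n = signal.size
    t = dt * np.arange(n)
    out = np.empty((n, freqs.size), dtype=complex)
    for j, fj in enumerate(freqs):
        g = signal * np.exp(-2j * np.pi * fj * t) * dt
        wj = voice_window(fj, n, dt, beta, normalization)
        out[:, j] = sfft.ifft(sfft.fft(g) * sfft.fft(wj))
    return out


def decompose(w: Wavefield, cfg: STransformConfig, dtype=np.complex128) -> list[SpectralVolume]:
    """S-transform every (z, x) trace of a wavefield at the configured voices.

    Equivalent to applying :func:`s_transform_1d` trace by trace and slicing
    at each voice frequency, but evaluated in row blocks for speed.  Returns
    one :class:`SpectralVolume` per voice frequency.
    """
    nyq = 0.5 / w.dt
    freqs = cfg.frequencies
    if np.any(freqs > nyq):
        raise ValueError(
            f"requested frequency {freqs.max():.0f} Hz exceeds the Nyquist limit "
            f"{nyq:.0f} Hz of this wavefield"
        )
    nz, nx, nt = w.v.shape
    t = w.dt * np.arange(nt)
    volumes = []
    for fj in freqs:
        wj = sfft.fft(voice_window(fj, nt, w.dt, cfg.beta, cfg.normalization))
        H = np.empty((nz, nx, nt), dtype=dtype)
        mod = np.exp(-2j * np.pi * fj * t) * w.dt
        block = max(1, int(2e6 // (nx * nt)))
        for i0 in range(0, nz, block):
            g = w.v[i0 : i0 + block] * mod
            H[i0 : i0 + block] = sfft.ifft(sfft.fft(g, axis=-1) * wj, axis=-1)
        volumes.append(
            SpectralVolume(H=H, f0=float(fj), dz=w.dz, dx=w.dx, dt=w.dt, z0=w.z0, x0=w.x0)
        )
    return volumes
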