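"""1D phase-velocity dispersion estimation and material-model fitting.

Operates on a lateral/temporal line field ``v(x, t)`` (typically the
directional-filtered, depth-averaged, DC-removed record at the focal
depth).  Two estimators are provided:

* ``dispersion_2dft`` — the classical frequency-wavenumber method: the
  dispersion curve is the ridge of the 2D Fourier magnitude ``|V(f, k)|``;
* ``dispersion_gst_sfk`` — the S-transform / slant-wavenumber analogue: per
  frequency, slant slices of the S-transform field over a steering-velocity
  series are spatially Fourier transformed and maximised over steering,
  which keeps the ridge detectable at frequencies where plain 2D-FT loses
  it in attenuating media.

Both mask frequencies whose spectral peak lacks prominence (peak below
3x the row median), and both refine peaks parabolically.  A nonlinear
least-squares fit with multi-start initialisation identifies Kelvin-Voigt
or standard-linear-solid parameters from a measured curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.optimize import least_squares
from scipy.signal.windows import tukey

from .materials import MaterialModel
from .reconstruct import SteeringGrid
from .stockwell import s_transform_1d

__all__ = [
    "DispersionCurve",
    "fk_spectrum",
    "dispersion_2dft",
    "dispersion_gst_sfk",
    "fit_material_model",
]

#: peak must exceed this multiple of the spectrum-row median to be trusted
PROMINENCE_FLOOR = 3.0


@dataclass
class DispersionCurve:
    """Phase velocity vs frequency with a per-point quality score."""

    f: np.ndarray
    c: np.ndarray
    quality: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if not np.all(np.diff(self.f) > 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_hz": self.f, "c_mps": self.c, "quality": self.quality, "method": self.method}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "DispersionCurve":
        df = pd.read_csv(path)
        method = str(df["method"].iloc[0]) if "method" in df and len(df) else ""
        return DispersionCurve(
            f=df["f_hz"].to_numpy(), c=df["c_mps"].to_numpy(),
            quality=df.get("quality", pd.Series(np.ones(len(df)))).to_numpy(),
            method=method,
        )


def fk_spectrum(
    v: np.ndarray, dx: float, dt: float, pad: int = 4, normalize_rows: bool = False
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D Fourier magnitude of a line field over (frequency, wavenumber).

    Returns ``(M, f, k)``: ``M[i, j]`` is the magnitude at temporal frequency
    ``f[i] >= 0`` (Hz) and *signed* wavenumber ``k[j]`` (rad/m, monotone
    axis).  With ``normalize_rows`` each frequency row is scaled by its
    maximum (display convention for ridge plots).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] < 8 or v.shape[1] < 8:
        raise ValueError("need a 2D (x, t) field with at least 8 samples per axis")
    nx, nt = v.shape
    npk = sfft.next_fast_len(nx * pad)
    npf = sfft.next_fast_len(nt * pad)
    V = sfft.fft2(v, s=(npk, npf))
    M = np.abs(V[:, : npf // 2 + 1])  # keep f >= 0
    M = np.fft.fftshift(M, axes=0)
    k = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(npk, dx))
    f = np.arange(npf // 2 + 1) / (npf * dt)
    if normalize_rows:
        M = M / np.maximum(M.max(axis=0, keepdims=True), 1e-300)
    return M.T, f, k


def _refine_peak(row: np.ndarray, j: int) -> float:
    if 0 < j < row.size - 1:
        a, b, c = row[j - 1], row[j], row[j + 1]
        denom = a - 2 * b + c
        if denom < 0:
            return j + float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return float(j)


def _ridge_to_curve(
    rows: np.ndarray,
    k_axis: np.ndarray,
    f_grid: np.ndarray,
    search_band: Tuple[float, float],
    method: str,
) -> DispersionCurve:
    """Per-frequency peak of ``rows[i]`` over the wavenumber axis."""
    cmin, cmax = search_band
    dk = k_axis[1] - k_axis[0]
    c = np.full(f_grid.size, np.nan)
    quality = np.zeros(f_grid.size)
    for i, f in enumerate(f_grid):
        row = rows[i]
        kmin, kmax = 2 * np.pi * f / cmax, 2 * np.pi * f / cmin
        sel = (k_axis >= kmin) & (k_axis <= kmax)
        if not sel.any():
            continue
        med = float(np.median(row[sel]))
        j_local = int(np.argmax(row[sel]))
        j = np.where(sel)[0][j_local]
        peak = row[j]
        if peak <= 0 or (med > 0 and peak < PROMINENCE_FLOOR * med):
            quality[i] = peak / med if med > 0 else 0.0
            continue
        jr = _refine_peak(row, j)
        k_pk = k_axis[0] + jr * dk
        if k_pk > 0:
            c[i] = 2 * np.pi * f / k_pk
            quality[i] = peak / med if med > 0 else np.inf
    return DispersionCurve(f=f_grid, c=c, quality=quality, method=method)


def dispersion_2dft(
    v: np.ndarray,
    dx: float,
    dt: float,
    f_grid: Sequence[float],
    search_band: Tuple[float, float] = (0.5, 10.0),
    pad: int = 4,
) -> DispersionCurve:
    """Dispersion curve from the f-k ridge of the 2D Fourier transform.

    Assumes a rightward-travelling line field (flip ``v`` along x for the
    other direction); per frequency, ``c = 2 pi f / k_peak`` with the peak
    searched inside the velocity band and refined parabolically.
    """
    M, f_axis, k_axis = fk_spectrum(v, dx, dt, pad=pad)
    f_grid = np.asarray(f_grid, dtype=float)
    # rightward waves live at (f > 0, k < 0): fold onto the positive-k side
    neg = k_axis < 0
    k_fold = -k_axis[neg][::-1]
    rows = np.empty((f_grid.size, k_fold.size))
    for i, f in enumerate(f_grid):
        idx = int(np.argmin(np.abs(f_axis - f)))
        rows[i] = M[idx, neg][::-1]
    return _ridge_to_curve(rows, k_fold, f_grid, search_band, method="2dft")


def dispersion_gst_sfk(
    v: np.ndarray,
    dx: float,
    dt: float,
    f_grid: Sequence[float],
    beta: float = 1.0,
    steering: Optional[SteeringGrid] = None,
    search_band: Tuple[float, float] = (0.5, 10.0),
    pad: int = 4,
    x_from_push: float = 0.0,
    taper: float = 0.25,
) -> DispersionCurve:
    """Dispersion curve from steering-maximised slant spectra.

    For each frequency: S-transform every lateral trace, slice the resulting
    ``H(x, tau)`` along ``tau = (x_from_push + x) / u`` for the steering
    series, spatially Fourier transform each Tukey-tapered slice, take the
    element-wise maximum over steering, and pick the wavenumber peak.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[0] < 8 or v.shape[1] < 8:
        raise ValueError("need a 2D (x, t) field with at least 8 samples per axis")
    steering = steering or SteeringGrid()
    nx, nt = v.shape
    x_rel = x_from_push + dx * np.arange(nx)
    t_max = nt * dt
    u_values = steering.values(float(x_rel.max()), t_max, dt)
    npk = sfft.next_fast_len(nx * pad)
    k_axis = 2 * np.pi * np.arange(npk // 2 + 1) / (npk * dx)
    win = tukey(nx, taper)
    f_grid = np.asarray(f_grid, dtype=float)
    rows = np.empty((f_grid.size, k_axis.size))
    for i, f in enumerate(f_grid):
        H = s_transform_1d_field(v, f, beta, dt)  # (nx, nt) complex
        K = np.zeros(k_axis.size)
        for u in u_values:
            pos = x_rel / (u * dt)
            i0 = np.floor(pos).astype(int)
            frac = pos - i0
            valid = (pos >= 0) & (i0 <= nt - 1)
            i0c = np.clip(i0, 0, nt - 1)
            i1c = np.clip(i0 + 1, 0, nt - 1)
            idx = np.arange(nx)
            sf = H[idx, i0c] * (1 - frac) + H[idx, i1c] * frac
            sf[~valid] = 0.0
            # rightward phase exp(-ikx): its peak sits on the negative-k side,
            # so transform the conjugate to read it on the positive side
            spec = np.abs(sfft.fft(np.conj(sf * win), n=npk))[: npk // 2 + 1]
            np.maximum(K, spec, out=K)
        rows[i] = K
    return _ridge_to_curve(rows, k_axis, f_grid, search_band, method="gst_sfk")


def s_transform_1d_field(v: np.ndarray, f: float, beta: float, dt: float) -> np.ndarray:
    """S-transform of every row of ``v(x, t)`` at a single voice frequency."""
    out = np.empty(v.shape, dtype=complex)
    for ix in range(v.shape[0]):
        out[ix] = s_transform_1d(v[ix], f, beta=beta, dt=dt)[:, 0]
    return out


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------
@dataclass
class FitResult:
    model: MaterialModel
    residual_norm: float
    converged: bool
    n_starts: int
    details: dict = field(default_factory=dict)


def _model_from_params(kind: str, params: np.ndarray, rho: float) -> MaterialModel:
    if kind == "kelvin_voigt":
        return MaterialModel.kelvin_voigt(mu=params[0], eta=params[1], rho=rho)
    return MaterialModel.sls(E1=params[0], E2=params[1], eta=params[2], rho=rho)


def fit_material_model(
    curve: DispersionCurve,
    kind: str,
    rho: float = 1000.0,
) -> FitResult:
    """Identify viscoelastic parameters from a dispersion curve.

    Minimises ``sum_f (c_model(f) - c_data(f))^2`` over the unmasked points
    with bounded trust-region least squares, multi-started from a log-spaced
    parameter grid (moduli about 1-100 kPa, viscosity 0.1-30 Pa s) to avoid
    local minima.  Requires at least 5 valid points spanning a 2x frequency
    ratio.
    """
    if kind not in ("kelvin_voigt", "sls"):
        raise ValueError(f"unsupported model kind {kind!r}")
    sel = curve.valid & (curve.f > 0)
    f = curve.f[sel]
    c = curve.c[sel]
    if f.size < 5 or f.max() / f.min() < 2:
        raise ValueError("need >= 5 valid points spanning at least a 2x frequency ratio")

    def residual(params):
        model = _model_from_params(kind, params, rho)
        return model.phase_velocity(f) - c

    if kind == "kelvin_voigt":
        mu_grid = np.geomspace(1e3 / 3, 1e5 / 3, 4)
        eta_grid = np.array([0.3, 2.0, 10.0])
        starts = [(m, e) for m in mu_grid for e in eta_grid]
        bounds = ([10.0, 0.0], [1e7, 1e3])
    else:
        e_grid = np.geomspace(1e3, 1e5, 4)
        eta_grid = np.array([1.0, 5.0, 20.0])
        starts = [(e1, e2, e) for e1 in e_grid for e2 in e_grid for e in eta_grid]
        bounds = ([10.0, 10.0, 0.0], [1e7, 1e7, 1e3])

    best = None
    for start in starts:
        try:
            res = least_squares(residual, np.asarray(start, float), bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("material-model fit failed to converge from every start")
    model = _model_from_params(kind, best.x, rho)
    return FitResult(
        model=model,
        residual_norm=float(math.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
        n_starts=len(starts),
        details={"optimality": float(best.optimality), "n_points": int(f.size)},
    )
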