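"""Rheological material models and their shear-wave dispersion laws.

Three linear viscoelastic models are supported, each described by its complex
shear modulus ``G*(omega)``:

* ``elastic`` — ``G* = mu`` with ``mu = E/3`` (incompressible conversion used
  throughout the package), giving a frequency-independent speed
  ``c = sqrt(E/(3 rho))`` and zero attenuation;
* ``kelvin_voigt`` — spring in parallel with a dashpot, ``G* = mu + i omega eta``;
* ``sls`` — standard linear solid: a spring (Young's modulus ``E1``) in series
  with a Kelvin-Voigt element (spring ``E2`` parallel to dashpot ``eta``).
  Moduli are converted to shear scale (``mu_i = E_i/3``), so
  ``G* = mu1 (mu2 + i omega eta) / (mu1 + mu2 + i omega eta)``.

Phase velocity and attenuation follow from the complex wavenumber
``k* = omega sqrt(rho / G*)``:  ``c = omega / Re(k*)`` and ``alpha = -Im(k*)``
(Np/m, non-negative for passive materials).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["MaterialModel", "dispersion_law"]

#: fixed incompressible-medium conversion between Young's and shear modulus
E_OVER_MU = 3.0


@dataclass(frozen=True)
class MaterialModel:
    """Rheological parameters plus a dispersion-law evaluator.

    ``kind`` selects which fields are meaningful: ``elastic`` uses ``E``;
    ``kelvin_voigt`` uses ``mu`` (Pa) and ``eta`` (Pa s); ``sls`` uses
    ``E1``, ``E2`` (Pa) and ``eta`` (Pa s).  ``rho`` is the density in kg/m^3.
    """

    kind: str
    rho: float = 1000.0
    E: Optional[float] = None
    mu: Optional[float] = None
    eta: Optional[float] = None
    E1: Optional[float] = None
    E2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("elastic", "kelvin_voigt", "sls"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        required = {
            "elastic": ("E",),
            "kelvin_voigt": ("mu", "eta"),
            "sls": ("E1", "E2", "eta"),
        }[self.kind]
        for name in required + ("rho",):
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise ValueError(f"{self.kind} model requires finite {name}")
        for name in ("E", "mu", "E1", "E2", "rho"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be strictly positive, got {val}")
        if self.eta is not None and self.eta < 0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")

    # -- convenience constructors -----------------------------------------
    @staticmethod
    def elastic(E: float, rho: float = 1000.0) -> "MaterialModel":
        return MaterialModel(kind="elastic", E=E, rho=rho)

    @staticmethod
    def kelvin_voigt(mu: float, eta: float, rho: float = 1000.0) -> "MaterialModel":
        return MaterialModel(kind="kelvin_voigt", mu=mu, eta=eta, rho=rho)

    @staticmethod
    def sls(E1: float, E2: float, eta: float, rho: float = 1000.0) -> "MaterialModel":
        return MaterialModel(kind="sls", E1=E1, E2=E2, eta=eta, rho=rho)

    # ---------------------------------------------------------------------
    def complex_shear_modulus(self, f) -> np.ndarray:
        """``G*(omega)`` in Pa at temporal frequency ``f`` (Hz)."""
        f = np.asarray(f, dtype=float)
        omega = 2.0 * np.pi * f
        if self.kind == "elastic":
            return np.broadcast_to(self.E / E_OVER_MU + 0j, f.shape).copy()
        if self.kind == "kelvin_voigt":
            return self.mu + 1j * omega * self.eta
        mu1 = self.E1 / E_OVER_MU
        mu2 = self.E2 / E_OVER_MU
        kv = mu2 + 1j * omega * self.eta
        return mu1 * kv / (mu1 + kv)

    def phase_velocity(self, f) -> np.ndarray:
        return dispersion_law(self, f)[0]

    def as_dict(self) -> dict:
        d = {"kind": self.kind, "rho": self.rho}
        for name in ("E", "mu", "eta", "E1", "E2"):
            val = getattr(self, name)
            if val is not None:
                d[name] = float(val)
        return d


def dispersion_law(model: MaterialModel, f) -> Tuple[np.ndarray, np.ndarray]:
    """Phase velocity ``c(f)`` (m/s) and attenuation ``alpha(f)`` (Np/m).

    Evaluates the complex wavenumber ``k* = omega sqrt(rho/G*)`` with the
    principal square root; ``c = omega/Re(k*)``, ``alpha = -Im(k*)``.
    At ``f = 0`` the zero-frequency limits are returned: ``alpha = 0`` and
    ``c = sqrt(G*(0)/rho)`` (both models have a finite static modulus).

    Parameters
    ----------
    model:
        Validated material model.
    f:
        Non-negative frequency grid, Hz (scalar or array).
    """
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be finite and non-negative")
    G = model.complex_shear_modulus(f)
    omega = 2.0 * np.pi * f
    slowness = np.sqrt(model.rho / G)  # complex slowness, s/m
    c = 1.0 / np.real(slowness)
    alpha = -omega * np.imag(slowness)
    # exact zero-frequency limit (avoids 0 * imag round-off in alpha)
    alpha = np.where(f == 0, 0.0, alpha)
    if scalar:
        return c[0], alpha[0]
    return c, alpha
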