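"""Spatiotemporal wavefield container and HDF5-style array I/O.

The universal input of the imaging pipeline is the particle-velocity movie
``v(z, x, t)`` sampled on a regular grid: depth rows, lateral columns, time
frames.  Velocity units are arbitrary (every estimator in this package keys
on spectral peak *positions*, not amplitudes); grid spacings are SI (m, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["Wavefield", "save_wavefield", "load_wavefield"]


@dataclass
class Wavefield:
    """A real 3D particle-velocity array with axis metadata.

    Parameters
    ----------
    v:
        Real array indexed ``(z, x, t)``.
    dz, dx:
        Spatial sample spacings in metres (strictly positive).
    dt:
        Frame interval in seconds (strictly positive).
    z0, x0:
        Physical coordinate of the first sample of each spatial axis, metres.
    """

    v: np.ndarray
    dz: float
    dx: float
    dt: float
    z0: float = 0.0
    x0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v)
        if self.v.ndim != 3:
            raise ValueError(f"v must be 3D (z, x, t); got shape {self.v.shape}")
        if not np.isrealobj(self.v):
            raise ValueError("v must be real-valued")
        for name in ("dz", "dx", "dt"):
            val = float(getattr(self, name))
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {val}")
            setattr(self, name, val)

    # -- axes -------------------------------------------------------------
    @property
    def nz(self) -> int:
        return self.v.shape[0]

    @property
    def nx(self) -> int:
        return self.v.shape[1]

    @property
    def nt(self) -> int:
        return self.v.shape[2]

    @property
    def z(self) -> np.ndarray:
        """Depth coordinates of the rows, metres."""
        return self.z0 + self.dz * np.arange(self.nz)

    @property
    def x(self) -> np.ndarray:
        """Lateral coordinates of the columns, metres."""
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def t(self) -> np.ndarray:
        """Frame times, seconds."""
        return self.dt * np.arange(self.nt)

    @property
    def nyquist(self) -> float:
        """Temporal Nyquist frequency, Hz."""
        return 0.5 / self.dt

    def with_v(self, v: np.ndarray) -> "Wavefield":
        """Copy of this wavefield with a new array and identical metadata."""
        return replace(self, v=v)


def save_wavefield(path, w: Wavefield, truth=None) -> None:
    """Write a wavefield (and optional ground truth) to an HDF5 container.

    Layout: datasets ``/v``, scalars ``/dz /dx /dt /z0 /x0``; ground-truth
    phase-velocity maps under ``/truth`` (see :mod:`useweb.synthetic`).
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("v", data=w.v, track_times=False)
        for name in ("dz", "dx", "dt", "z0", "x0"):
            h5.create_dataset(name, data=float(getattr(w, name)), track_times=False)
        for key, val in w.meta.items():
            try:
                h5.attrs[key] = val
            except TypeError:
                h5.attrs[key] = str(val)
        if truth is not None:
            g = h5.create_group("truth")
            truth.to_h5(g)


def load_wavefield(path) -> Wavefield:
    with h5py.File(path, "r") as h5:
        w = Wavefield(
            v=h5["v"][...],
            dz=float(h5["dz"][()]),
            dx=float(h5["dx"][()]),
            dt=float(h5["dt"][()]),
            z0=float(h5["z0"][()]) if "z0" in h5 else 0.0,
            x0=float(h5["x0"][()]) if "x0" in h5 else 0.0,
            meta=dict(h5.attrs),
        )
    return w
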