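"""Shared fixtures: small synthetic scenes sized for fast, deterministic tests."""

import numpy as np
import pytest

from useweb import MaterialModel, Scene, Pulse, synthesize_wavefield


def small_scene(background, *, snr_db=np.inf, seed=0, inclusion=None,
                lateral_mm=24.0, depth_mm=10.0, duration_ms=70.0, pushes_mm=(2.0, 22.0)):
    """A reduced-size scene that keeps the default sampling (pitch, frame rate)."""
    return Scene(
        background=background,
        depth_extent=depth_mm * 1e-3,
        lateral_extent=lateral_mm * 1e-3,
        duration=duration_ms * 1e-3,
        z0=15e-3,
        focal_depth=20e-3,
        depth_sigma=4e-3,
        push_positions=tuple(p * 1e-3 for p in pushes_mm),
        pulse=Pulse(center_frequency=700.0, bandwidth=1400.0),
        inclusion=inclusion,
        snr_db=snr_db,
        seed=seed,
    )


@pytest.fixture(scope="session")
def elastic_scene():
    return small_scene(MaterialModel.elastic(E=25e3))


@pytest.fixture(scope="session")
def elastic_field(elastic_scene):
    return synthesize_wavefield(elastic_scene)


@pytest.fixture(scope="session")
def kv_scene():
    return small_scene(MaterialModel.kelvin_voigt(mu=5e3, eta=2.0))


@pytest.fixture(scope="session")
def kv_field(kv_scene):
    return synthesize_wavefield(kv_scene)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def plane_wave_field(c=3.0, f0=600.0, nz=24, nx=96, nt=160, dz=0.154e-3, dx=0.154e-3,
                     dt=1 / 4167.0, direction=+1, amplitude=1.0):
    """Analytic monochromatic plane wave travelling laterally; returns a Wavefield."""
    from useweb import Wavefield

    x = dx * np.arange(nx)
    t = dt * np.arange(nt)
    k = 2 * np.pi * f0 / c
    phase = 2 * np.pi * f0 * t[None, :] - direction * k * x[:, None]
    v = amplitude * np.cos(phase)
    return Wavefield(v=np.broadcast_to(v, (nz, nx, nt)).copy(), dz=dz, dx=dx, dt=dt)
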