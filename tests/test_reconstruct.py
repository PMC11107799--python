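"""Slant-wavenumber reconstruction: elementary ops, loop oracle, full maps."""

import numpy as np
import pytest

from useweb import (
    MaterialModel,
    Roi,
    STransformConfig,
    SteeringGrid,
    UsewebConfig,
    WindowSpec,
    dispersion_law,
    pick_wavenumber,
    reconstruct_map,
    roi_stats,
)
from useweb.reconstruct import (
    _padded_shape,
    extract_window,
    max_over_steering,
    slant_slice,
    spectral_amplitude,
)
from useweb.stockwell import SpectralVolume


DT = 1.0 / 4167.0
DX = 0.154e-3


def _volume(H, dz=DX, dx=DX, dt=DT, f0=800.0):
    return SpectralVolume(H=H, f0=f0, dz=dz, dx=dx, dt=dt)


class TestExtractWindow:
    def test_rectangular_taper_is_pure_restriction(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(20, 30, 8)) + 1j * rng.normal(size=(20, 30, 8))
        vol = _volume(H)
        spec = WindowSpec(height=9 * DX, width=9 * DX, taper=0.0)
        Hw, (zs, xs) = extract_window(vol, (10 * DX, 15 * DX), spec)
        assert np.allclose(Hw, H[zs, xs])
        assert Hw.shape == (9, 9, 8)

    def test_constant_field_full_taper_returns_taper_profile(self):
        H = np.ones((20, 30, 4), dtype=complex)
        vol = _volume(H)
        spec = WindowSpec(height=9 * DX, width=9 * DX, taper=1.0)
        Hw, _ = extract_window(vol, (10 * DX, 15 * DX), spec)
        assert np.allclose(Hw[:, :, 0], spec.taper2d(9, 9))

    def test_corner_window_clips_to_intersection(self):
        H = np.ones((20, 30, 4), dtype=complex)
        vol = _volume(H)
        spec = WindowSpec(height=9 * DX, width=9 * DX, taper=0.0)
        Hw, _ = extract_window(vol, (0.0, 0.0), spec)
        assert Hw.shape == (5, 5, 4)  # centre at the corner keeps 5 of 9 samples
        with pytest.raises(ValueError):
            extract_window(vol, (-10 * DX, 0.0), spec)


class TestSlantSlice:
    def test_infinite_u_limit_is_time_origin_slice(self):
        rng = np.random.default_rng(1)
        Hw = rng.normal(size=(5, 7, 16)) + 1j * rng.normal(size=(5, 7, 16))
        d = DX * np.arange(7)
        sf = slant_slice(Hw, 1e9, d, DT)
        assert np.allclose(sf, Hw[:, :, 0], atol=1e-6)

    def test_zero_volume_gives_zero_slice(self):
        Hw = np.zeros((4, 6, 12), dtype=complex)
        assert np.all(slant_slice(Hw, 2.0, DX * np.arange(6), DT) == 0)

    def test_steering_scan_peaks_at_group_velocity(self):
        # envelope travelling at cg: the slant mean is maximal when u = cg
        cg, f0 = 2.5, 800.0
        nx, nt = 24, 160
        x = DX * np.arange(nx)
        tau = DT * np.arange(nt)
        sigma = 1.2e-3
        env = np.exp(-((tau[None, :] - x[:, None] / cg) ** 2) / (2 * sigma**2))
        H = env * np.exp(-1j * 2 * np.pi * f0 / cg * x)[:, None]
        Hw = H[None, :, :]
        u_grid = np.linspace(1.0, 6.0, 51)
        score = [np.abs(slant_slice(Hw, u, x, DT).mean()) for u in u_grid]
        assert u_grid[int(np.argmax(score))] == pytest.approx(cg, abs=0.2)

    def test_nonpositive_u_rejected(self):
        with pytest.raises(ValueError):
            slant_slice(np.zeros((2, 3, 4), complex), 0.0, DX * np.arange(3), DT)


class TestSpectralAmplitude:
    def test_pure_exponential_peaks_at_its_wavenumber(self):
        k0 = 900.0  # rad/m
        nxw = 21
        x = DX * np.arange(nxw)
        SF = np.exp(-1j * k0 * x)[None, :] * np.ones((nxw, 1))
        lam, kz, kx = spectral_amplitude(SF, DX, DX, pad_factor=4)
        p, q = np.unravel_index(np.argmax(lam), lam.shape)
        dkx = abs(kx[1] - kx[0])
        assert kz[p] == 0.0
        assert abs(abs(kx[q]) - k0) <= dkx

    def test_parseval_identity_without_padding(self):
        rng = np.random.default_rng(2)
        SF = rng.normal(size=(12, 15)) + 1j * rng.normal(size=(12, 15))
        lam, kz, kx = spectral_amplitude(SF, DX, DX, pad_factor=1)
        # dk-areas in cycles/m to match the transform convention
        dk_area = (abs(kz[1] - kz[0]) / (2 * np.pi)) * (abs(kx[1] - kx[0]) / (2 * np.pi))
        lhs = np.sum(np.abs(SF) ** 2) * DX * DX
        rhs = np.sum(lam**2) * dk_area
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_real_input_gives_centrosymmetric_magnitude(self):
        rng = np.random.default_rng(3)
        SF = rng.normal(size=(10, 11))
        lam, _, _ = spectral_amplitude(SF, DX, DX, pad_factor=2)
        flipped = np.roll(lam[::-1, ::-1], (1, 1), axis=(0, 1))
        assert np.allclose(lam, flipped, atol=1e-9 * lam.max())


class TestMaxOverSteering:
    def test_single_slice_identity_and_dominance(self):
        rng = np.random.default_rng(4)
        stack = rng.uniform(size=(5, 8, 9))
        K = max_over_steering(stack)
        assert np.array_equal(max_over_steering(stack[:1]), stack[0])
        assert np.all(K >= stack)
        dup = np.concatenate([stack, stack[2:3]], axis=0)
        assert np.array_equal(max_over_steering(dup), K)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_over_steering(np.zeros((0, 4, 4)))


class TestPickWavenumber:
    def test_single_nonzero_bin_is_returned(self):
        npz = npx = 32
        kz = 2 * np.pi * np.fft.fftfreq(npz, DX)
        kx = 2 * np.pi * np.fft.fftfreq(npx, DX)
        K = np.zeros((npz, npx))
        K[0, 3] = 1.0
        kzp, kxp, kmag = pick_wavenumber(K, kz, kx, f0=800.0, search_band=(0.5, 10.0))
        assert kzp == pytest.approx(0.0)
        assert kxp == pytest.approx(kx[3])

    def test_plane_wave_at_nominal_inclusion_speed(self):
        # c = 5.16 m/s at 800 Hz -> |k| = 2 pi 800 / 5.16 = 974 rad/m
        c, f0 = 5.16, 800.0
        nw = 29
        x = DX * np.arange(nw)
        SF = np.exp(-1j * (2 * np.pi * f0 / c) * x)[None, :] * np.ones((nw, 1))
        lam, kz, kx = spectral_amplitude(SF, DX, DX, pad_factor=4)
        _, _, kmag = pick_wavenumber(lam, kz, kx, f0=f0)
        dk = abs(kx[1] - kx[0])
        assert abs(kmag - 2 * np.pi * f0 / c) <= dk
        assert 2 * np.pi * f0 / kmag == pytest.approx(c, rel=0.05)

    def test_equal_maxima_tie_break_to_smaller_wavenumber(self):
        npz = npx = 24
        kz = 2 * np.pi * np.fft.fftfreq(npz, DX)
        kx = 2 * np.pi * np.fft.fftfreq(npx, DX)
        K = np.zeros((npz, npx))
        K[0, 2] = K[0, 6] = 0.7  # same amplitude, different |k|
        _, kxp, _ = pick_wavenumber(K, kz, kx, f0=800.0, refine=False)
        assert kxp == pytest.approx(kx[2])

    def test_empty_annulus_rejected(self):
        kz = kx = 2 * np.pi * np.fft.fftfreq(8, DX)
        with pytest.raises(ValueError):
            pick_wavenumber(np.ones((8, 8)), kz, kx, f0=1.0, search_band=(9.99, 10.0))


# ---------------------------------------------------------------------------
# literal loop-based oracle of the slant pipeline on one window
# ---------------------------------------------------------------------------
def oracle_single_window(Hw, d_cols, dz, dx, dt, u_values, npz, npx, f0, band):
    """Slant slices, explicit DFT, steering max, annulus argmax, refinement —
    written as plain loops with no FFT shortcuts."""
    nzw, nxw, nt = Hw.shape
    K = np.zeros((npz, npx))
    for u in u_values:
        SF = np.zeros((nzw, nxw), dtype=complex)
        for j in range(nxw):
            pos = d_cols[j] / (u * dt)
            i0 = int(np.floor(pos))
            frac = pos - i0
            if pos < 0 or i0 > nt - 1:
                continue
            a = Hw[:, j, min(i0, nt - 1)]
            b = Hw[:, j, min(i0 + 1, nt - 1)]
            SF[:, j] = a * (1 - frac) + b * frac
        for p in range(npz):
            for q in range(npx):
                phase = np.exp(
                    -2j
                    * np.pi
                    * (
                        p * np.arange(nzw)[:, None] / npz
                        + q * np.arange(nxw)[None, :] / npx
                    )
                )
                amp = abs(np.sum(SF * phase)) * dz * dx
                if amp > K[p, q]:
                    K[p, q] = amp
    kz = 2 * np.pi * np.fft.fftfreq(npz, dz)
    kx = 2 * np.pi * np.fft.fftfreq(npx, dx)
    kmin = 2 * np.pi * f0 / band[1]
    kmax = 2 * np.pi * f0 / band[0]
    best = None
    for p in range(npz):
        for q in range(npx):
            kmag = np.hypot(kz[p], kx[q])
            if not (kmin <= kmag <= kmax):
                continue
            key = (-K[p, q], kmag, kx[q])
            if best is None or key < best[0]:
                best = (key, p, q)
    _, p, q = best

    def refine(a, b, c):
        den = a - 2 * b + c
        if den < 0:
            return float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
        return 0.0

    dpz = refine(K[(p - 1) % npz, q], K[p, q], K[(p + 1) % npz, q])
    dpx = refine(K[p, (q - 1) % npx], K[p, q], K[p, (q + 1) % npx])
    iz = np.fft.fftfreq(npz)[p] * npz
    ix = np.fft.fftfreq(npx)[q] * npx
    kz_pk = (iz + dpz) * (2 * np.pi / (npz * dz))
    kx_pk = (ix + dpx) * (2 * np.pi / (npx * dx))
    return 2 * np.pi * f0 / np.hypot(kz_pk, kx_pk)


def test_single_window_pipeline_matches_loop_oracle():
    rng = np.random.default_rng(5)
    nzw = nxw = 9
    nt = 40
    f0 = 800.0
    # generic complex volume: travelling ridge plus random clutter
    x = DX * np.arange(nxw)
    tau = DT * np.arange(nt)
    env = np.exp(-((tau[None, :] - x[:, None] / 2.5 - 2e-3) ** 2) / (2 * 1.5e-3**2))
    H = env * np.exp(-1j * 2 * np.pi * f0 / 2.5 * x)[:, None]
    Hw = (
        np.broadcast_to(H, (nzw, nxw, nt)).copy()
        + 0.05 * (rng.normal(size=(nzw, nxw, nt)) + 1j * rng.normal(size=(nzw, nxw, nt)))
    )
    d_cols = 6e-3 + x  # window 6 mm from the push
    u_values = [1.5, 2.5, 4.0]
    band = (0.5, 10.0)
    pad = 4.0
    npz, npx = _padded_shape(nzw, nxw, pad)

    lam_stack = []
    for u in u_values:
        sf = slant_slice(Hw, u, d_cols, DT)
        lam, kz, kx = spectral_amplitude(sf, DX, DX, pad_factor=pad)
        lam_stack.append(lam)
    K = max_over_steering(np.stack(lam_stack))
    _, _, kmag = pick_wavenumber(K, kz, kx, f0=f0, search_band=band)
    c_impl = 2 * np.pi * f0 / kmag

    c_oracle = oracle_single_window(Hw, d_cols, DX, DX, DT, u_values, npz, npx, f0, band)
    assert abs(c_impl - c_oracle) / c_oracle < 1e-8


# ---------------------------------------------------------------------------
# full maps on simulated scenes
# ---------------------------------------------------------------------------
def _fast_cfg(f0, pushes, stride=3, fb=0.0, band_policy="mean_k"):
    return UsewebConfig(
        stransform=STransformConfig(f0=f0, fb=fb),
        window=WindowSpec(stride=stride),
        steering=SteeringGrid(max_values=32),
        pad_factor=2.75,
        band_policy=band_policy,
        pushes=list(pushes),
        dtype=np.complex64,
    )


ROI_MID = Roi.rectangle((20e-3, 12e-3), 6e-3, 10e-3)


def test_homogeneous_elastic_map_is_accurate_and_uniform(elastic_scene, elastic_field):
    w, _ = elastic_field
    m = reconstruct_map(w, _fast_cfg(600.0, elastic_scene.push_positions))
    s = roi_stats(m, ROI_MID)
    c_true = np.sqrt(25e3 / (3.0 * 1000.0))
    assert s["mean"] == pytest.approx(c_true, rel=0.02)
    assert s["cv_percent"] < 5.0


@pytest.mark.parametrize(
    "f0,rel",
    [(400.0, 0.05), (800.0, 0.03)],
    ids=["400Hz-long-wavelength", "800Hz"],
)
def test_homogeneous_kv_map_tracks_dispersion_law(kv_scene, kv_field, f0, rel):
    # at 400 Hz the wavelength (~7 mm) exceeds the 4.47 mm window, which
    # biases the annulus peak slightly low in |k|; tolerance reflects that
    w, _ = kv_field
    m = reconstruct_map(w, _fast_cfg(f0, kv_scene.push_positions))
    s = roi_stats(m, ROI_MID)
    c_true, _ = dispersion_law(kv_scene.background, f0)
    assert s["mean"] == pytest.approx(c_true, rel=rel)
    assert s["cv_percent"] < 8.0


def test_map_is_invariant_to_amplitude_scaling(elastic_scene, elastic_field):
    w, _ = elastic_field
    cfg = _fast_cfg(600.0, elastic_scene.push_positions, stride=6)
    m1 = reconstruct_map(w, cfg)
    m2 = reconstruct_map(w.with_v(w.v * 37.0), cfg)
    both = m1.mask & m2.mask
    assert both.sum() > 50
    assert np.allclose(m1.cph[both], m2.cph[both], rtol=1e-4)


def test_band_reconstruction_close_to_single_frequency(elastic_scene, elastic_field):
    w, _ = elastic_field
    m_band = reconstruct_map(
        w, _fast_cfg(600.0, elastic_scene.push_positions, stride=6, fb=100.0)
    )
    s = roi_stats(m_band, ROI_MID)
    assert s["mean"] == pytest.approx(np.sqrt(25e3 / 3e3), rel=0.03)


def test_window_larger_than_fov_rejected(elastic_field):
    w, _ = elastic_field
    cfg = UsewebConfig(
        stransform=STransformConfig(f0=600.0),
        window=WindowSpec(height=0.1, width=0.1),
    )
    with pytest.raises(ValueError, match="larger than"):
        reconstruct_map(w, cfg)
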