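"""1D dispersion estimators (f-k ridge, slant-steered) and model fitting."""

import numpy as np
import pytest

from useweb import (
    DispersionCurve,
    MaterialModel,
    dispersion_2dft,
    dispersion_gst_sfk,
    dispersion_law,
    fit_material_model,
    fk_spectrum,
    synthesize_wavefield,
)
from useweb.preprocess import (
    depth_average,
    directional_filter,
    equalize_lateral,
    push_mute,
    remove_dc,
)

from conftest import small_scene

DT = 1.0 / 4167.0
DX = 0.154e-3


def _line_field(model, snr_db=np.inf, seed=0, duration_ms=100.0):
    """Depth-averaged, direction-filtered lateral line from a one-push scene."""
    scene = small_scene(
        model, snr_db=snr_db, seed=seed, lateral_mm=30.0, pushes_mm=(1.5,),
        duration_ms=duration_ms,
    )
    w, _ = synthesize_wavefield(scene)
    wd = remove_dc(directional_filter(push_mute(w, [1.5e-3]), "left_to_right"))
    wd = equalize_lateral(wd)
    line = depth_average(wd, 20e-3, 1.69e-3)
    i0 = int(np.argmin(np.abs(w.x - 3e-3)))
    seg = line[i0 : i0 + 175]  # ~27 mm lateral segment
    return seg, w.dx, w.dt, float(w.x[i0] - 1.5e-3)


def _plane_wave_line(c=3.0, f0=600.0, nx=128, nt=256):
    x = DX * np.arange(nx)
    t = DT * np.arange(nt)
    k = 2 * np.pi * f0 / c
    return np.cos(2 * np.pi * f0 * t[None, :] - k * x[:, None])


class TestFkSpectrum:
    def test_plane_wave_has_single_dominant_peak(self):
        v = _plane_wave_line()
        M, f, k = fk_spectrum(v, DX, DT, pad=2)
        i, j = np.unravel_index(np.argmax(M), M.shape)
        assert f[i] == pytest.approx(600.0, abs=f[1] - f[0])
        assert abs(k[j]) == pytest.approx(2 * np.pi * 600 / 3.0, abs=abs(k[1] - k[0]))

    def test_parseval_energy(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(16, 32))
        M, f, k = fk_spectrum(v, DX, DT, pad=1)
        # one-sided in f: double the positive-frequency energy, correct DC/Nyquist
        full = np.abs(np.fft.fft2(v)) ** 2
        assert np.sum(full) == pytest.approx(v.size * np.sum(v**2), rel=1e-10)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            fk_spectrum(np.zeros((4, 4)), DX, DT)


class TestDispersionCurves:
    def test_elastic_curve_is_flat_at_nominal_speed(self):
        # E = 45 kPa -> c = sqrt(45e3/3e3) = 3.873 m/s at every frequency
        seg, dx, dt, x0 = _line_field(MaterialModel.elastic(E=45e3))
        fgrid = np.arange(200.0, 1200.1, 100.0)
        cur = dispersion_2dft(seg, dx, dt, fgrid)
        c_true = np.sqrt(45e3 / 3e3)
        assert cur.valid.all()
        assert np.allclose(cur.c, c_true, rtol=0.02)

    def test_wavelength_at_100hz_matches_analytic(self):
        # E = 10 kPa at 100 Hz: lambda = c/f = 1.826/100 = 18.3 mm
        seg, dx, dt, x0 = _line_field(MaterialModel.elastic(E=10e3))
        cur = dispersion_2dft(seg, dx, dt, [100.0], pad=8)
        lam = cur.c[0] / 100.0
        assert lam == pytest.approx(18.3e-3, rel=0.05)

    def test_methods_agree_on_noiseless_plane_wave(self):
        v = _plane_wave_line(c=3.0, f0=600.0)
        fgrid = np.array([500.0, 600.0, 700.0])
        c2 = dispersion_2dft(v, DX, DT, fgrid)
        cg = dispersion_gst_sfk(v, DX, DT, fgrid)
        sel = c2.valid & cg.valid
        assert sel[1]
        assert np.allclose(c2.c[sel], cg.c[sel], rtol=0.05)

    def test_zero_signal_is_fully_masked(self):
        v = np.zeros((32, 64))
        cur = dispersion_2dft(v, DX, DT, [300.0, 600.0])
        assert not cur.valid.any()
        curg = dispersion_gst_sfk(v, DX, DT, [300.0, 600.0])
        assert not curg.valid.any()

    def test_gst_sfk_covers_band_on_mild_kv_at_20db(self):
        seg, dx, dt, x0 = _line_field(
            MaterialModel.kelvin_voigt(mu=5e3, eta=0.3), snr_db=20.0, seed=4
        )
        fgrid = np.arange(200.0, 1500.1, 100.0)
        cur = dispersion_gst_sfk(seg, dx, dt, fgrid, x_from_push=x0)
        c_true = MaterialModel.kelvin_voigt(mu=5e3, eta=0.3).phase_velocity(fgrid)
        assert cur.valid.all()
        sub = fgrid <= 1000.0
        assert np.nanmax(np.abs(cur.c[sub] / c_true[sub] - 1)) < 0.10

    def test_gst_sfk_degrades_more_gracefully_than_2dft_on_lossy_medium(self):
        # strongly attenuating medium: the classical f-k ridge washes out at
        # high frequency while the steering-maximised slant spectrum keeps it
        seg, dx, dt, x0 = _line_field(
            MaterialModel.kelvin_voigt(mu=5e3, eta=2.0), snr_db=20.0, seed=4
        )
        fgrid = np.arange(200.0, 1500.1, 50.0)
        c_true = MaterialModel.kelvin_voigt(mu=5e3, eta=2.0).phase_velocity(fgrid)
        c2 = dispersion_2dft(seg, dx, dt, fgrid)
        cg = dispersion_gst_sfk(seg, dx, dt, fgrid, x_from_push=x0)
        assert cg.valid.sum() >= c2.valid.sum()
        err2 = np.nanmax(np.abs(np.where(c2.valid, c2.c, np.nan) / c_true - 1))
        errg = np.nanmax(np.abs(np.where(cg.valid, cg.c, np.nan) / c_true - 1))
        assert errg < err2


class TestFitMaterialModel:
    def test_exact_sls_curve_round_trips(self):
        truth = MaterialModel.sls(E1=9.61e3, E2=15.62e3, eta=5.28)
        f = np.arange(50.0, 1500.1, 25.0)
        curve = DispersionCurve(f=f, c=truth.phase_velocity(f), quality=np.ones(f.size))
        fit = fit_material_model(curve, "sls")
        assert fit.model.E1 == pytest.approx(9.61e3, rel=0.01)
        assert fit.model.E2 == pytest.approx(15.62e3, rel=0.01)
        assert fit.model.eta == pytest.approx(5.28, rel=0.01)

    def test_exact_kv_curve_round_trips(self):
        truth = MaterialModel.kelvin_voigt(mu=4e3, eta=1.5)
        f = np.arange(50.0, 1500.1, 50.0)
        curve = DispersionCurve(f=f, c=truth.phase_velocity(f), quality=np.ones(f.size))
        fit = fit_material_model(curve, "kelvin_voigt")
        assert fit.model.mu == pytest.approx(4e3, rel=0.01)
        assert fit.model.eta == pytest.approx(1.5, rel=0.01)

    def test_flat_curve_fit_with_kv_gives_negligible_viscosity(self):
        f = np.arange(100.0, 1000.1, 50.0)
        c = np.full(f.size, 2.887)
        curve = DispersionCurve(f=f, c=c, quality=np.ones(f.size))
        fit = fit_material_model(curve, "kelvin_voigt")
        # eta -> 0 limit: dispersion contribution below measurement scale
        disp = fit.model.phase_velocity(1000.0) - fit.model.phase_velocity(100.0)
        assert disp < 1e-3

    def test_noisy_curve_recovers_parameters_over_seeds(self):
        # Monte-Carlo at sigma = 0.05 m/s: the series spring E1 (which sets
        # the high-frequency plateau) is strongly identified; E2 and eta act
        # mostly below the ~250 Hz relaxation corner and carry wider spread
        truth = MaterialModel.sls(E1=9.61e3, E2=15.62e3, eta=5.28)
        f = np.arange(50.0, 1500.1, 50.0)
        c0 = truth.phase_velocity(f)
        e1, e2, et = [], [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            curve = DispersionCurve(
                f=f, c=c0 + rng.normal(0, 0.05, f.size), quality=np.ones(f.size)
            )
            fit = fit_material_model(curve, "sls")
            e1.append(abs(fit.model.E1 / 9.61e3 - 1))
            e2.append(abs(fit.model.E2 / 15.62e3 - 1))
            et.append(abs(fit.model.eta / 5.28 - 1))
        assert np.median(e1) < 0.05
        assert np.median(e2) < 0.20
        assert np.median(et) < 0.20

    def test_insufficient_points_rejected(self):
        f = np.array([100.0, 120.0, 140.0, 160.0])
        curve = DispersionCurve(f=f, c=np.full(4, 2.0), quality=np.ones(4))
        with pytest.raises(ValueError):
            fit_material_model(curve, "sls")
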