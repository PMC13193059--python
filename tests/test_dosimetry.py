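"""Dose computation, contraction, DVH metrics, error reports."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

import remicro as rm
from remicro.constants import MEAN_BETA_ENERGY_J, MEAN_LIFETIME_S
from remicro.dosimetry import (
    _convolve_circular_fft,
    _kernel_fft_circular,
    _superpose,
)


def _grid(counts, pitch=30.0):
    return rm.MicrosphereGrid(counts=counts, pitch_um=pitch)


class TestConvolutionEngines:
    def test_superposition_matches_fft_oracle(self):
        # random 32^3 occupancy, 9^3 toy kernel: sparse superposition must
        # equal direct linear convolution to float64 precision
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(32, 32, 32)).astype(np.uint16)
        kernel = rm.toy_kernel("uniform_sphere", half_width=4, value=2.5,
                               radius_voxels=3.0).grid
        sup = _superpose(counts, kernel)
        oracle = fftconvolve(counts.astype(float), kernel, mode="same")
        assert np.abs(sup - oracle).max() / oracle.max() < 1e-9

    def test_circular_fft_equals_linear_on_interior(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 2, size=(40, 40, 40)).astype(np.uint16)
        kernel = rm.toy_kernel("uniform_sphere", half_width=5, value=1.0,
                               radius_voxels=4.0).grid
        kf = _kernel_fft_circular(kernel, 40)
        circ = _convolve_circular_fft(counts, kf)
        lin = fftconvolve(counts.astype(float), kernel, mode="same")
        m = 5
        sl = (slice(m, -m),) * 3
        assert np.abs(circ[sl] - lin[sl]).max() / lin.max() < 1e-5

    def test_single_sphere_delta_kernel(self):
        counts = np.zeros((16, 16, 16), dtype=np.uint16)
        counts[8, 8, 8] = 1
        dvk = rm.toy_kernel("delta", value=4.0)
        cfg = rm.DosimetryConfig(specific_activity_bq=300.0)
        dose = rm.compute_dose(_grid(counts), dvk, cfg, engine="superposition")
        expected = cfg.tau_s * 300.0 * 4.0
        assert dose.values[8, 8, 8] == pytest.approx(expected, rel=1e-6)
        assert np.count_nonzero(dose.values) == 1

    def test_linearity_in_activity_and_superposition(self):
        counts = np.zeros((20, 20, 20), dtype=np.uint16)
        counts[5, 5, 5] = 1
        counts[12, 14, 9] = 2
        dvk = rm.toy_kernel("uniform_sphere", half_width=3, radius_voxels=2.0)
        c1 = rm.DosimetryConfig(specific_activity_bq=100.0)
        c2 = rm.DosimetryConfig(specific_activity_bq=300.0)
        d1 = rm.compute_dose(_grid(counts), dvk, c1, engine="superposition")
        d2 = rm.compute_dose(_grid(counts), dvk, c2, engine="superposition")
        assert np.allclose(3.0 * d1.values, d2.values, rtol=1e-6)

    def test_pitch_mismatch_rejected(self):
        dvk = rm.toy_kernel("delta", pitch_um=30.0)
        with pytest.raises(ValueError):
            rm.compute_dose(_grid(np.zeros((8, 8, 8), dtype=np.uint16),
                                  pitch=40.0), dvk)

    def test_global_energy_conservation(self):
        # sources at least a kernel half-width from every face: the total
        # absorbed energy equals decays x energy per decay
        counts = np.zeros((24, 24, 24), dtype=np.uint16)
        counts[8:16, 8:16, 8:16] = 1
        dvk = rm.renormalize(rm.toy_kernel("uniform_sphere", half_width=4,
                                           radius_voxels=3.0))
        cfg = rm.DosimetryConfig(specific_activity_bq=50.0)
        dose = rm.compute_dose(_grid(counts), dvk, cfg, engine="superposition")
        energy = dose.values.sum(dtype=np.float64) * dvk.voxel_mass_kg
        decays = cfg.tau_s * 50.0 * counts.sum()
        assert energy == pytest.approx(decays * MEAN_BETA_ENERGY_J, rel=1e-6)


class TestContract:
    def test_interior_dims(self):
        dose = rm.DoseGrid(values=np.zeros((100, 100, 100), dtype=np.float32),
                           pitch_um=30.0)
        assert rm.contract(dose, 10).dims == (80, 80, 80)
        # the production margin removes 160 voxels per axis: 735 -> 575
        assert 735 - 2 * 80 == 575

    def test_zero_margin_identity(self):
        dose = rm.DoseGrid(values=np.ones((10, 10, 10), dtype=np.float32),
                           pitch_um=30.0)
        assert rm.contract(dose, 0) is dose

    def test_margin_too_large(self):
        dose = rm.DoseGrid(values=np.ones((10, 10, 10), dtype=np.float32),
                           pitch_um=30.0)
        with pytest.raises(ValueError):
            rm.contract(dose, 5)

    def test_interior_mean_matches_cpe_closed_form(self):
        # one microsphere per voxel with a contained renormalized kernel:
        # the contracted interior sits in charged-particle equilibrium
        counts = np.ones((64, 64, 64), dtype=np.uint16)
        dvk = rm.renormalize(rm.toy_kernel("uniform_sphere", half_width=6,
                                           radius_voxels=5.0))
        cfg = rm.DosimetryConfig(specific_activity_bq=300.0,
                                 contraction_margin=8)
        dose = rm.compute_dose(_grid(counts), dvk, cfg, engine="superposition")
        interior = rm.contract(dose, 8)
        conc = 1.0 / (0.003 ** 3)   # one sphere per 30 um voxel, per mL
        cpe = rm.cpe_mean_dose(conc, 300.0)
        assert interior.values.mean(dtype=np.float64) == pytest.approx(
            cpe, rel=0.01)


class TestMetrics:
    def test_uniform_field(self):
        dose = rm.DoseGrid(values=np.full((10, 10, 10), 100.0,
                                          dtype=np.float32), pitch_um=30.0)
        m = rm.metrics(dose, thresholds=(100.0, 150.0))
        assert m.d_mean == 100.0
        assert m.cov == 0.0
        assert all(v == 100.0 for v in m.d_x.values())
        assert m.v_at[100.0] == 100.0
        assert m.v_at[150.0] == 0.0

    def test_percentile_convention(self):
        dose = rm.DoseGrid(values=np.arange(100, dtype=np.float32
                                            ).reshape(10, 10, 1),
                           pitch_um=30.0)
        m = rm.metrics(dose)
        assert m.d_x[50] == pytest.approx(49.5)

    def test_dx_ordering_and_v_monotone(self):
        rng = np.random.default_rng(2)
        dose = rm.DoseGrid(values=rng.lognormal(4, 1, (20, 20, 20)
                                                ).astype(np.float32),
                           pitch_um=30.0)
        m = rm.metrics(dose, thresholds=(10.0, 50.0, 100.0))
        dx = [m.d_x[x] for x in (1, 5, 10, 50, 90, 95, 99)]
        assert np.all(np.diff(dx) <= 0)
        vs = [m.v_at[t] for t in (10.0, 50.0, 100.0)]
        assert np.all(np.diff(vs) <= 0)


class TestSingleCompartment:
    def test_reference_value(self):
        # 1 GBq in 10.648 ml of 1.03 g/ml tissue
        p = rm.SingleCompartmentParams(activity_GBq=1.0,
                                       mass_kg=10.648e-3 * 1.03)
        assert rm.single_compartment(p) == pytest.approx(4502.4, abs=1.0)

    def test_zero_activity(self):
        p = rm.SingleCompartmentParams(activity_GBq=0.0, mass_kg=0.01)
        assert rm.single_compartment(p) == 0.0


class TestErrorReport:
    def _metrics(self, mean, dx=None):
        return rm.DoseMetrics(d_mean=mean, sd_dose=1.0, cov=0.1,
                              d_x=dx or {50: mean})

    def test_identity(self):
        m = self._metrics(80.0)
        rep = rm.error_report(m, m)
        assert rep.e_mean == 0.0
        assert all(v == 0.0 for v in rep.e_x.values())

    def test_published_example(self):
        rep = rm.error_report(self._metrics(70.3), self._metrics(83.6))
        assert rep.e_mean == pytest.approx(-15.9, abs=0.05)

    def test_scale_invariance(self):
        a, b = self._metrics(70.0), self._metrics(90.0)
        r1 = rm.error_report(a, b)
        a2, b2 = self._metrics(140.0), self._metrics(180.0)
        r2 = rm.error_report(a2, b2)
        assert r1.e_mean == pytest.approx(r2.e_mean)

    def test_zero_reference_flagged(self):
        rep = rm.error_report(self._metrics(50.0),
                              rm.DoseMetrics(d_mean=0.0, sd_dose=0, cov=0,
                                             d_x={50: 0.0}))
        assert np.isnan(rep.e_mean)
        assert "mean" in rep.undefined


def test_cpe_closed_form_value():
    # tau * c * A * E / rho at the headline operating point
    val = rm.cpe_mean_dose(5000.0, 300.0)
    expected = MEAN_LIFETIME_S * 5000.0 * 300.0 * MEAN_BETA_ENERGY_J / 1.03e-3
    assert val == pytest.approx(expected, rel=1e-12)
    assert val == pytest.approx(71.95, abs=0.05)
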