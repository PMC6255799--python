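"""Omega-plot quantification: acquisition identities, fit, closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcest.quantify import (
    OmegaPlotFit,
    QcestConfig,
    b1_from_flip_angle,
    cestr_inverse_difference,
    estimate_ksw,
    ksw_from_omega_plot,
    ksw_map,
    omega_plot_fit,
    omega1_rad_s,
    shape_constants,
)
from qcest.bloch import simulate_pulsed_cest_zspectrum
from qcest.pools import TwoPoolModel


class TestAcquisitionIdentities:
    @pytest.mark.parametrize(
        "fa,expected",
        [(900, 0.73), (1500, 1.22), (2100, 1.71), (3000, 2.45)],
    )
    def test_b1_amplitudes_of_the_protocol(self, fa, expected):
        assert b1_from_flip_angle(fa, 0.08) == pytest.approx(expected, abs=0.01)

    def test_zero_flip_angle(self):
        assert b1_from_flip_angle(0.0, 0.08) == 0.0

    def test_negative_flip_angle_rejected(self):
        with pytest.raises(ValueError):
            b1_from_flip_angle(-90.0, 0.08)

    def test_shape_constants_quarter_sigma(self):
        c1, c2 = shape_constants(0.02, 0.08)
        assert c1 == pytest.approx(np.sqrt(2 * np.pi) / 4, rel=1e-9)
        assert c2 / c1 == pytest.approx(2**0.25, rel=1e-12)

    def test_c1_unity_at_matched_sigma(self):
        c1, _ = shape_constants(0.08 / np.sqrt(2 * np.pi), 0.08)
        assert c1 == pytest.approx(1.0, rel=1e-12)


class TestCestrInverseDifference:
    def test_hand_arithmetic(self):
        assert cestr_inverse_difference(0.5, 0.8) == pytest.approx(0.75)

    def test_equal_z_gives_zero(self):
        assert cestr_inverse_difference(0.37, 0.37) == 0.0

    def test_nonpositive_z_rejected(self):
        with pytest.raises(ValueError):
            cestr_inverse_difference(0.0, 0.5)

    def test_single_pool_symmetry_gives_null_effect(self, scheme):
        pool = TwoPoolModel(f_r=0.0)
        zset = simulate_pulsed_cest_zspectrum(pool, scheme)
        for i in range(zset.n_b1):
            c = cestr_inverse_difference(
                zset.spectrum(i).value_at(1.0), zset.spectrum(i).value_at(-1.0))
            assert abs(c) < 1e-6


class TestOmegaPlot:
    def test_two_points_interpolating_line(self):
        fit = omega_plot_fit(np.array([200.0, 600.0]), np.array([0.05, 0.15]))
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_linear_relation_recovered(self):
        m_true, n_true = 5e6, 10.0
        w1 = omega1_rad_s(np.array([0.73, 1.22, 1.71, 2.45]))
        y = n_true + m_true / w1**2
        fit = omega_plot_fit(w1, 1.0 / y)
        assert fit.slope == pytest.approx(m_true, rel=1e-9)
        assert fit.intercept == pytest.approx(n_true, rel=1e-9)

    def test_nonpositive_points_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            fit = omega_plot_fit(
                np.array([200.0, 400.0, 600.0]), np.array([-0.01, 0.05, 0.1]))
        assert fit.n_used == 2

    def test_under_two_usable_points_raised(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            omega_plot_fit(np.array([200.0, 600.0]), np.array([-0.1, 0.1]))

    def test_noiseless_spectra_linearity_at_k1000(self, scheme):
        pool = TwoPoolModel(k_sw=1000.0)
        zset = simulate_pulsed_cest_zspectrum(pool, scheme)
        _, fit = estimate_ksw(zset, QcestConfig())
        assert fit.r_squared > 0.99


class TestKswClosedForm:
    def test_forward_compose_round_trip(self):
        k_true, r2s = 1000.0, 50.0
        cfg = QcestConfig()
        ratio = k_true * (r2s + k_true) * cfg.c2**2
        fit = OmegaPlotFit(slope=ratio * 7.0, intercept=7.0, r_squared=1.0,
                           omega1=np.array([]), inv_cestr=np.array([]), n_used=4)
        assert ksw_from_omega_plot(fit, cfg.c2, r2s) == pytest.approx(k_true, abs=1e-9)

    def test_zero_r2s_limit(self):
        cfg = QcestConfig()
        fit = OmegaPlotFit(4e6, 2.0, 1.0, np.array([]), np.array([]), 4)
        assert ksw_from_omega_plot(fit, cfg.c2, 0.0) == pytest.approx(
            np.sqrt(4e6 / (2.0 * cfg.c2**2)))

    def test_zero_slope_gives_zero_rate(self):
        fit = OmegaPlotFit(0.0, 5.0, 1.0, np.array([]), np.array([]), 4)
        assert ksw_from_omega_plot(fit, 0.745, 66.7) == 0.0

    def test_nonpositive_intercept_flagged(self):
        fit = OmegaPlotFit(1e6, -1.0, 1.0, np.array([]), np.array([]), 4)
        with pytest.raises(ValueError):
            ksw_from_omega_plot(fit, 0.745, 66.7)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        m=st.floats(1e3, 1e8),
        n=st.floats(0.1, 100.0),
        r2s=st.floats(0.0, 500.0),
    )
    def test_agrees_with_quadratic_root_oracle(self, m, n, r2s):
        # independent oracle: numpy's root finder on k^2 + R2s*k - (m/n)/c2^2
        c2 = 0.745
        fit = OmegaPlotFit(m, n, 1.0, np.array([]), np.array([]), 4)
        k = ksw_from_omega_plot(fit, c2, r2s)
        roots = np.roots([1.0, r2s, -(m / n) / c2**2])
        k_ref = float(max(roots.real))
        assert k == pytest.approx(k_ref, rel=1e-12, abs=1e-9)


@pytest.fixture(scope="module")
def phantom_z(scheme):
    z = {}
    for k in (500.0, 1500.0):
        pool = TwoPoolModel(k_sw=k)
        z[k] = simulate_pulsed_cest_zspectrum(pool, scheme)
    return z


class TestKswMap:
    def test_uniform_phantom_constant_map(self, phantom_z, scheme):
        zs = phantom_z[500.0]
        z = np.broadcast_to(zs.z, (2, 3, *zs.z.shape))
        m, r2 = ksw_map(z, zs.offsets_ppm, zs.b1_ut, QcestConfig(r2_threshold=0.0))
        assert np.nanstd(m) / np.nanmean(m) < 0.01

    def test_two_compartment_ordering(self, phantom_z):
        zs_lo, zs_hi = phantom_z[500.0], phantom_z[1500.0]
        z = np.stack([zs_lo.z, zs_hi.z])
        m, _ = ksw_map(z, zs_lo.offsets_ppm, zs_lo.b1_ut, QcestConfig(r2_threshold=0.0))
        assert m[1] > m[0]

    def test_empty_mask_all_nan(self, phantom_z):
        zs = phantom_z[500.0]
        z = np.broadcast_to(zs.z, (2, *zs.z.shape))
        m, r2 = ksw_map(z, zs.offsets_ppm, zs.b1_ut, QcestConfig(),
                        mask=np.zeros(2, dtype=bool))
        assert np.isnan(m).all() and np.isnan(r2).all()

    def test_failing_voxel_does_not_abort(self, phantom_z):
        zs = phantom_z[500.0]
        z = np.stack([zs.z, np.full_like(zs.z, 0.5)])  # flat spectrum voxel
        m, _ = ksw_map(z, zs.offsets_ppm, zs.b1_ut, QcestConfig(r2_threshold=0.0))
        assert np.isfinite(m[0]) and np.isnan(m[1])
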