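import numpy as np
import pytest

from qcest.pools import TwoPoolModel, disc_cest_scheme, wassr_scheme


@pytest.fixture(scope="session")
def pool():
    """Default GAG-like two-pool system."""
    return TwoPoolModel()


@pytest.fixture(scope="session")
def scheme():
    """The full disc CEST saturation protocol."""
    return disc_cest_scheme()


@pytest.fixture(scope="session")
def wassr():
    return wassr_scheme()


@pytest.fixture(scope="session")
def short_scheme():
    """A cut-down train (few pulses, coarse steps) for oracle comparisons
    where the cost of the reference integrator dominates."""
    return disc_cest_scheme(n_pulses=2, n_steps=16, offsets_ppm=(-1.0, 1.0))


def bloch_ode_oracle(pool, scheme, offset_ppm, flip_angle, rtol=1e-11):
    """Independent reference: adaptive ODE integration of the same
    piecewise-constant pulse train (no matrix exponentials)."""
    from scipy.integrate import solve_ivp

    from qcest.bloch import bloch_mcconnell_matrix, gaussian_pulse_waveform
    from qcest.pools import GAMMA_MHZ_PER_T

    n = scheme.n_steps
    dt = scheme.t_p / n
    shape = gaussian_pulse_waveform(scheme.t_p, scheme.sigma_s, 1.0, n)
    if scheme.apodized:
        edge = np.exp(-((scheme.t_p / 2.0) ** 2) / (2.0 * scheme.sigma_s**2))
        shape = np.maximum((shape - edge) / (1.0 - edge), 0.0)
    if flip_angle == 0.0:
        b1 = np.zeros(n)
    else:
        area = (flip_angle / 360.0) / (GAMMA_MHZ_PER_T * 1e6)
        b1 = shape * (area / (shape.sum() * dt)) * 1e6
    w1 = 2.0 * np.pi * GAMMA_MHZ_PER_T * b1
    m = np.array([0.0, 0.0, 1.0, 0.0, 0.0, pool.f_r, 1.0])
    a_free = bloch_mcconnell_matrix(pool, offset_ppm, 0.0)
    for _ in range(scheme.n_pulses):
        for s in range(n):
            a = bloch_mcconnell_matrix(pool, offset_ppm, w1[s])
            m = solve_ivp(lambda t, y: a @ y, (0.0, dt), m,
                          rtol=rtol, atol=1e-13).y[:, -1]
        if scheme.t_d > 0:
            m = solve_ivp(lambda t, y: a_free @ y, (0.0, scheme.t_d), m,
                          rtol=rtol, atol=1e-13).y[:, -1]
        if scheme.crusher:
            m[[0, 1, 3, 4]] = 0.0
    return m[2]
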