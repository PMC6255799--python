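"""Quantitative CEST: inverse CEST difference, omega-plot, exchange rate.

The exchange rate is estimated concentration-independently from spectra
acquired at several saturation powers.  For each B1 amplitude the inverse
CEST difference

    CESTR_ind = 1/Z(+1.0 ppm) - 1/Z(-1.0 ppm)

is formed from the B0-corrected spectrum.  Under the pulsed-saturation
two-pool model, 1/CESTR_ind is approximately linear in 1/omega1^2:

    1/CESTR_ind ~= R1w/(DC * f_r * k_sw * c1)
                   + k_sw*(R2s + k_sw)*R1w*c2^2/(DC * f_r * k_sw * c1) / omega1^2

where DC is the saturation duty cycle and c1 = sigma*sqrt(2*pi)/t_p,
c2 = c1 * 2**(1/4) encode the Gaussian pulse shape.  Ordinary least squares
of 1/CESTR_ind on 1/omega1^2 yields slope m and intercept n, and the
exchange rate follows from the ratio m/n = k_sw*(R2s + k_sw)*c2^2:

    k_sw = ( sqrt(R2s^2 + 4*m/(n*c2^2)) - R2s ) / 2

Both the solute fraction f_r and R1w cancel in m/n, which is the point of
the method: k_sw is independent of solute concentration and of T1/T2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pools import GAMMA_MHZ_PER_T
from .spectra import ZSpectrumSet

__all__ = [
    "QcestConfig",
    "OmegaPlotFit",
    "b1_from_flip_angle",
    "shape_constants",
    "omega1_rad_s",
    "cestr_inverse_difference",
    "omega_plot_fit",
    "ksw_from_omega_plot",
    "estimate_ksw",
    "ksw_map",
]


def b1_from_flip_angle(flip_angle: float, t_p: float) -> float:
    """Time-average B1 amplitude (uT) of a pulse with the given flip angle.

    ``B1 = (flip/360) / (gamma * t_p)`` with gamma = 42.577 MHz/T; a 900 deg,
    80 ms pulse averages 0.73 uT.
    """
    if t_p <= 0:
        raise ValueError("t_p must be > 0")
    if flip_angle < 0:
        raise ValueError("flip_angle must be >= 0")
    b1_tesla = (flip_angle / 360.0) / (GAMMA_MHZ_PER_T * 1e6 * t_p)
    return b1_tesla * 1e6


def shape_constants(sigma: float, t_p: float) -> tuple[float, float]:
    """Gaussian pulse shape constants ``(c1, c2)``.

    ``c1 = sigma * sqrt(2*pi) / t_p`` relates the pulse's time-average
    amplitude to its peak; ``c2 = c1 * 2**0.25`` plays the same role for the
    mean-square amplitude.
    """
    if sigma <= 0 or t_p <= 0:
        raise ValueError("sigma and t_p must be > 0")
    c1 = sigma * np.sqrt(2.0 * np.pi) / t_p
    return c1, c1 * 2.0**0.25


def omega1_rad_s(b1_ut: np.ndarray | float) -> np.ndarray | float:
    """RF amplitude in angular frequency units: ``omega1 = 2*pi*gamma*B1``."""
    return 2.0 * np.pi * GAMMA_MHZ_PER_T * np.asarray(b1_ut, dtype=float)


def cestr_inverse_difference(z_plus: float, z_minus: float) -> float:
    """Inverse CEST difference ``1/Z(+1 ppm) - 1/Z(-1 ppm)``.

    Positive when the solute pool at +1.0 ppm removes water signal; the
    inverse-Z form cancels direct water saturation to first order.
    """
    if z_plus <= 0 or z_minus <= 0:
        raise ValueError("Z values must be > 0")
    return 1.0 / z_plus - 1.0 / z_minus


@dataclass(frozen=True)
class QcestConfig:
    """Acquisition and model constants needed by the omega-plot analysis.

    ``R2s`` (solute transverse relaxation rate) is required by the closed
    form but is not measurable from the protocol itself; the default
    66.7 1/s is an assumed literature-scale value for GAG hydroxyl protons
    and should be treated as such.
    """

    dc: float = 0.5
    c1: float = float(np.sqrt(2.0 * np.pi) / 4.0)
    c2: float = float(np.sqrt(2.0 * np.pi) / 4.0 * 2.0**0.25)
    R2s: float = 66.7
    label_offset_ppm: float = 1.0
    r2_threshold: float = 0.9
    omega1_in_ut: bool = False  # if True, regress on 1/B1^2 (uT) instead

    def __post_init__(self) -> None:
        if not 0.0 < self.dc <= 1.0:
            raise ValueError("duty cycle must be in (0, 1]")
        if self.R2s < 0:
            raise ValueError("R2s must be >= 0")


@dataclass
class OmegaPlotFit:
    """OLS fit of 1/CESTR_ind against 1/omega1^2."""

    slope: float
    intercept: float
    r_squared: float
    omega1: np.ndarray
    inv_cestr: np.ndarray
    n_used: int


def omega_plot_fit(omega1: np.ndarray, cestr_ind: np.ndarray) -> OmegaPlotFit:
    """Fit the omega-plot line through ``(1/omega1^2, 1/CESTR_ind)`` points.

    Non-positive CESTR_ind values (noise can produce them) are excluded with
    a warning; at least two usable B1 levels are required.
    """
    omega1 = np.asarray(omega1, dtype=float)
    cestr_ind = np.asarray(cestr_ind, dtype=float)
    if omega1.shape != cestr_ind.shape:
        raise ValueError("omega1 and cestr_ind must have equal length")
    usable = cestr_ind > 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} non-positive CESTR_ind point(s)",
            stacklevel=2,
        )
    omega1, cestr_ind = omega1[usable], cestr_ind[usable]
    if np.unique(omega1).size < 2:
        raise ValueError("need >= 2 distinct B1 levels with positive CESTR_ind")
    x = 1.0 / omega1**2
    y = 1.0 / cestr_ind
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return OmegaPlotFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        omega1=omega1,
        inv_cestr=y,
        n_used=int(omega1.size),
    )


def ksw_from_omega_plot(fit: OmegaPlotFit, c2: float, R2s: float) -> float:
    """Exchange rate from the omega-plot slope/intercept ratio.

    ``k_sw = (sqrt(R2s^2 + 4*m/(n*c2^2)) - R2s) / 2`` -- the positive root of
    ``k^2 + R2s*k - (m/n)/c2^2 = 0``.  A non-positive intercept means the
    linear model is non-physical for these data.
    """
    m, n = fit.slope, fit.intercept
    if n <= 0:
        raise ValueError("non-physical omega-plot fit: intercept <= 0")
    if m < 0:
        raise ValueError("non-physical omega-plot fit: slope < 0")
    if m == 0:
        return 0.0
    return float((np.sqrt(R2s**2 + 4.0 * m / (n * c2**2)) - R2s) / 2.0)


def estimate_ksw(zset: ZSpectrumSet, config: QcestConfig) -> tuple[float, OmegaPlotFit]:
    """Full per-ROI estimation: CESTR_ind per B1, omega-plot, closed form.

    ``zset`` must already be B0-corrected so that the ``+/-label_offset_ppm``
    columns sit at the true water-referenced offsets.
    """
    d = config.label_offset_ppm
    cestr = np.array(
        [
            cestr_inverse_difference(
                zset.spectrum(i).value_at(+d), zset.spectrum(i).value_at(-d)
            )
            for i in range(zset.n_b1)
        ]
    )
    x = zset.b1_ut if config.omega1_in_ut else omega1_rad_s(zset.b1_ut)
    fit = omega_plot_fit(np.asarray(x), cestr)
    ksw = ksw_from_omega_plot(fit, config.c2, config.R2s)
    return ksw, fit


def ksw_map(
    z: np.ndarray,
    offsets_ppm: np.ndarray,
    b1_ut: np.ndarray,
    config: QcestConfig,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise exchange-rate map with an R^2 quality-control map.

    Parameters
    ----------
    z : ndarray, shape (..., n_b1, n_offsets)
        B0-corrected Z values per voxel.
    offsets_ppm, b1_ut : 1-D arrays
        Acquisition axes shared by all voxels.
    config : QcestConfig
    mask : boolean ndarray matching the spatial shape, optional

    Returns
    -------
    (ksw_map, r2_map)
        Spatial arrays; voxels outside the mask, failing QC
        (R^2 < ``config.r2_threshold``) or yielding a non-physical fit are
        NaN in both maps (a failing voxel never aborts the map).
    """
    z = np.asarray(z, dtype=float)
    spatial = z.shape[:-2]
    if z.shape[-2:] != (len(b1_ut), len(offsets_ppm)):
        raise ValueError("z trailing dims must be (n_b1, n_offsets)")
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape must match the spatial grid")
    out = np.full(spatial, np.nan)
    r2 = np.full(spatial, np.nan)
    for idx in np.ndindex(*spatial):
        if not mask[idx]:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zset = ZSpectrumSet(offsets_ppm, b1_ut, z[idx])
                k, fit = estimate_ksw(zset, config)
        except (ValueError, KeyError, FloatingPointError):
            continue
        if fit.r_squared < config.r2_threshold:
            continue
        out[idx] = k
        r2[idx] = fit.r_squared
    return out, r2
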