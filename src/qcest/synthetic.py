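"""Synthetic disc phantoms with known ground truth.

Emulates the data the analysis pipeline consumes, from known ground truth:

* multi-B1 CEST Z-spectra and low-power WASSR spectra of a two-pool
  (water + GAG hydroxyl) system, via the Bloch-McConnell integrator;
* inversion-recovery, multi-echo and spin-lock relaxometry series;
* per-disc pH readings (healthy around 7.2, degenerated around 6.3) with
  the exchange rate tied to pH through the calibration
  ``k_sw = a*10**(8-pH) + b``;
* gene-expression (RQ) tables linearly tied to ``k_sw`` with a prescribed
  population R^2 per marker.

Every generator draws from a single seeded ``numpy`` Generator, so a fixed
seed reproduces the dataset bit for bit.  Observations are stored next to
-- never in place of -- the ground truth they were generated from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bloch import simulate_pulsed_cest_zspectrum, simulate_wassr_spectrum
from .calibration import CalibrationModel
from .pools import SaturationScheme, TwoPoolModel, disc_cest_scheme, wassr_scheme
from .relaxometry import RelaxometrySeries
from .spectra import ZSpectrum, ZSpectrumSet

__all__ = [
    "DiscRecord",
    "PhantomDataset",
    "MARKER_TARGET_R2",
    "simulate_inversion_recovery",
    "simulate_monoexp_decay",
    "simulate_rq_values",
    "make_disc_phantom",
    "generate_biomarker_table",
]

# Printed Fig-level population R^2 per marker, used as generator defaults.
MARKER_TARGET_R2 = {
    "CGRP": 0.8758,
    "BDKRB1": 0.8623,
    "COMT": 0.9025,
    "IL6": 0.8368,
    "BDNF": 0.9219,
}

# Acquisition timing defaults (s) of the disc protocol.
DEFAULT_TIS = (0.050, 0.150, 0.350, 0.700, 1.050, 1.400, 2.000)
DEFAULT_TES = (0.012, 0.025, 0.050, 0.099, 0.199, 0.397)
DEFAULT_TSLS = (0.0, 0.010, 0.040, 0.080)


def simulate_inversion_recovery(
    T1: float,
    I0: float,
    eta: float,
    TIs,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> RelaxometrySeries:
    """Inversion-recovery signals ``I = I0*[1-(1+eta)*exp(-TI/T1)]`` + noise."""
    if T1 <= 0:
        raise ValueError("T1 must be > 0")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    ti = np.asarray(TIs, dtype=float)
    if ti.size == 0:
        raise ValueError("TI list is empty")
    sig = I0 * (1.0 - (1.0 + eta) * np.exp(-ti / T1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, ti.size)
    return RelaxometrySeries(ti, sig, "TI")


def simulate_monoexp_decay(
    tau: float,
    I0: float,
    times,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    role: str = "TE",
) -> RelaxometrySeries:
    """Monoexponential decay ``I = I0*exp(-t/tau)`` + noise (TE or TSL)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    sig = I0 * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, t.size)
    return RelaxometrySeries(t, sig, role)


def _add_noise(
    clean: np.ndarray, sd: float, rng: np.random.Generator, model: str
) -> np.ndarray:
    if sd <= 0:
        return clean.copy()
    if model == "gaussian":
        return clean + rng.normal(0.0, sd, clean.shape)
    if model == "rician":
        re = clean + rng.normal(0.0, sd, clean.shape)
        im = rng.normal(0.0, sd, clean.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


@dataclass
class DiscRecord:
    """One disc: ground truth plus the synthetic acquisitions made from it."""

    disc_id: str
    group: str  # "healthy" | "degenerated"
    ph_true: float
    ksw_true: float
    b0_shift_true: float
    relax_true: dict  # T1, T2, T1rho (s)
    pool: TwoPoolModel
    roi_voxels: np.ndarray  # (n_vox, 2) integer grid coordinates
    ph_measured: float
    # observations: voxelwise stacks, last axes match the acquisition grids
    z_clean: np.ndarray  # (n_b1, n_offsets) noiseless
    z_obs: np.ndarray  # (n_vox, n_b1, n_offsets)
    wassr_clean: np.ndarray  # (n_wassr,)
    wassr_obs: np.ndarray  # (n_vox, n_wassr)
    ir_obs: np.ndarray  # (n_vox, n_ti)
    te_obs: np.ndarray  # (n_vox, n_te)
    tsl_obs: np.ndarray  # (n_vox, n_tsl)

    def roi_zset(self, offsets_ppm, b1_ut) -> ZSpectrumSet:
        """ROI-averaged multi-B1 Z-spectrum set."""
        return ZSpectrumSet(offsets_ppm, b1_ut, self.z_obs.mean(axis=0))

    def roi_wassr(self, offsets_ppm) -> ZSpectrum:
        return ZSpectrum(offsets_ppm, self.wassr_obs.mean(axis=0))


@dataclass
class PhantomDataset:
    """A reproducible set of synthetic discs plus the schemes that made them."""

    discs: list
    scheme: SaturationScheme
    wassr: SaturationScheme
    calibration: CalibrationModel
    tis: np.ndarray
    tes: np.ndarray
    tsls: np.ndarray
    noise_sd: float
    noise_model: str
    seed: int

    @property
    def cest_offsets(self) -> np.ndarray:
        return np.sort(np.asarray(self.scheme.offsets_ppm))

    @property
    def wassr_offsets(self) -> np.ndarray:
        return np.sort(np.asarray(self.wassr.offsets_ppm))

    @property
    def b1_ut(self) -> np.ndarray:
        return self.scheme.b1_amplitudes_ut()

    def manifest(self) -> pd.DataFrame:
        """Per-disc ground-truth table (disc id, group, true pH/k_sw, ...)."""
        return pd.DataFrame(
            {
                "disc_id": [d.disc_id for d in self.discs],
                "group": [d.group for d in self.discs],
                "ph_true": [d.ph_true for d in self.discs],
                "ksw_true": [d.ksw_true for d in self.discs],
                "ph_measured": [d.ph_measured for d in self.discs],
                "b0_shift_true": [d.b0_shift_true for d in self.discs],
                "T1_true": [d.relax_true["T1"] for d in self.discs],
                "T2_true": [d.relax_true["T2"] for d in self.discs],
                "T1rho_true": [d.relax_true["T1rho"] for d in self.discs],
                "seed": self.seed,
            }
        )


# Group-level relaxation truths (s): healthy vs degenerated disc tissue at 3 T.
_RELAX_MEANS = {
    "healthy": {"T1": 1.6, "T2": 0.120, "T1rho": 0.100},
    "degenerated": {"T1": 1.2, "T2": 0.060, "T1rho": 0.050},
}
_RELAX_REL_SD = 0.05


def make_disc_phantom(
    n_healthy: int = 4,
    n_degen: int = 12,
    calibration: CalibrationModel | None = None,
    ph_healthy: tuple = (7.2, 0.10),
    ph_degen: tuple = (6.3, 0.15),
    pool_defaults: TwoPoolModel | None = None,
    scheme: SaturationScheme | None = None,
    wassr: SaturationScheme | None = None,
    noise_sd: float = 0.005,
    noise_model: str = "gaussian",
    relax_noise_sd: float = 0.01,
    ph_probe_sd: float = 0.05,
    b0_shift_halfwidth: float = 0.15,
    n_voxels: int = 121,
    seed: int = 0,
    simulate_mri: bool = True,
) -> PhantomDataset:
    """Generate a full synthetic cohort of healthy and degenerated discs.

    Each disc draws its pH from its group distribution (redrawn if outside
    [5.5, 8.0]), takes ``k_sw`` from the calibration model, and receives a
    complete acquisition set: CEST Z-spectra at every B1, a WASSR spectrum
    (both displaced by a per-disc B0 offset), and IR/TE/TSL relaxometry
    series, each observed over ``n_voxels`` ROI voxels with Gaussian (or
    Rician) noise on the normalized signals.

    ``simulate_mri=False`` skips the (comparatively costly) Bloch-McConnell
    spectral simulation and fills the spectral observations with empty
    arrays; pH, exchange-rate and relaxometry ground truth and series are
    still generated, which is enough for calibration/statistics work.
    """
    if n_healthy < 1 or n_degen < 1:
        raise ValueError("counts must be >= 1")
    calibration = calibration or CalibrationModel(a=1.3, b=248.2)
    if calibration.a <= 0:
        raise ValueError("calibration must be strictly decreasing in pH")
    pool_defaults = pool_defaults or TwoPoolModel()
    scheme = scheme or disc_cest_scheme()
    wassr = wassr or wassr_scheme()
    rng = np.random.default_rng(seed)

    tis = np.asarray(DEFAULT_TIS)
    tes = np.asarray(DEFAULT_TES)
    tsls = np.asarray(DEFAULT_TSLS)

    groups = ["healthy"] * n_healthy + ["degenerated"] * n_degen
    discs: list[DiscRecord] = []
    side = int(np.ceil(np.sqrt(n_voxels)))
    for i, group in enumerate(groups):
        mean, sd = ph_healthy if group == "healthy" else ph_degen
        ph = rng.normal(mean, sd)
        while not 5.5 <= ph <= 8.0:
            ph = rng.normal(mean, sd)
        ksw = float(calibration.ksw(ph))
        relax = {
            k: v * (1.0 + rng.normal(0.0, _RELAX_REL_SD))
            for k, v in _RELAX_MEANS[group].items()
        }
        b0 = float(rng.uniform(-b0_shift_halfwidth, b0_shift_halfwidth))
        pool = pool_defaults.with_(
            R1w=1.0 / relax["T1"], R2w=1.0 / relax["T2"], k_sw=ksw
        )

        if simulate_mri:
            zset = simulate_pulsed_cest_zspectrum(pool, scheme, b0)
            wz = simulate_wassr_spectrum(pool, wassr, b0)
            z_clean, wassr_clean = zset.z, wz.z
            z_obs = _add_noise(
                np.broadcast_to(z_clean, (n_voxels, *z_clean.shape)).copy(),
                noise_sd, rng, noise_model,
            )
            wassr_obs = _add_noise(
                np.broadcast_to(wassr_clean, (n_voxels, wassr_clean.size)).copy(),
                noise_sd, rng, noise_model,
            )
        else:
            z_clean = np.empty((0, 0))
            wassr_clean = np.empty(0)
            z_obs = np.empty((n_voxels, 0, 0))
            wassr_obs = np.empty((n_voxels, 0))
        ir_clean = 1.0 - 2.0 * np.exp(-tis / relax["T1"])
        te_clean = np.exp(-tes / relax["T2"])
        tsl_clean = np.exp(-tsls / relax["T1rho"])
        ir_obs = _add_noise(
            np.broadcast_to(ir_clean, (n_voxels, tis.size)).copy(),
            relax_noise_sd, rng, "gaussian",
        )
        te_obs = _add_noise(
            np.broadcast_to(te_clean, (n_voxels, tes.size)).copy(),
            relax_noise_sd, rng, noise_model,
        )
        tsl_obs = _add_noise(
            np.broadcast_to(tsl_clean, (n_voxels, tsls.size)).copy(),
            relax_noise_sd, rng, noise_model,
        )
        vox = np.array(
            [(10 * i + r, c) for r in range(side) for c in range(side)][:n_voxels]
        )
        discs.append(
            DiscRecord(
                disc_id=f"D{i:02d}",
                group=group,
                ph_true=float(ph),
                ksw_true=ksw,
                b0_shift_true=b0,
                relax_true=relax,
                pool=pool,
                roi_voxels=vox,
                ph_measured=float(ph + rng.normal(0.0, ph_probe_sd)),
                z_clean=z_clean,
                z_obs=z_obs,
                wassr_clean=wassr_clean,
                wassr_obs=wassr_obs,
                ir_obs=ir_obs,
                te_obs=te_obs,
                tsl_obs=tsl_obs,
            )
        )
    return PhantomDataset(
        discs=discs,
        scheme=scheme,
        wassr=wassr,
        calibration=calibration,
        tis=tis,
        tes=tes,
        tsls=tsls,
        noise_sd=noise_sd,
        noise_model=noise_model,
        seed=seed,
    )


def simulate_rq_values(
    ksw: np.ndarray,
    target_r2: float,
    beta: float = 0.02,
    alpha: float = 1.0,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Relative-quantification values ``RQ = alpha + beta*k_sw + eps``.

    The noise variance is set from the sample variance of ``ksw`` so that
    the population squared correlation between RQ and k_sw equals
    ``target_r2``.  Values are kept positive by redrawing the rare noise
    draws that would push RQ below zero.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    ksw = np.asarray(ksw, dtype=float)
    if np.ptp(ksw) == 0:
        raise ValueError("degenerate input: constant k_sw")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sd_eps = abs(beta) * ksw.std(ddof=1) * np.sqrt((1.0 - target_r2) / target_r2)
    rq = alpha + beta * ksw + rng.normal(0.0, sd_eps, ksw.size)
    for _ in range(100):
        bad = rq <= 0
        if not bad.any():
            break
        rq[bad] = alpha + beta * ksw[bad] + rng.normal(0.0, sd_eps, int(bad.sum()))
    return np.maximum(rq, 1e-9)


def generate_biomarker_table(
    dataset: PhantomDataset,
    marker_betas: dict | None = None,
    target_r2: dict | None = None,
    compartments: tuple = ("AF", "NP"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-disc marker expression table tied linearly to the exchange rate.

    One row per (disc, marker, compartment) with columns
    ``disc_id, marker, compartment, rq, ksw``; each marker's RQ values are
    generated so the population R^2 against k_sw matches ``target_r2``
    (defaults: the per-marker levels in :data:`MARKER_TARGET_R2`).
    """
    target_r2 = dict(MARKER_TARGET_R2, **(target_r2 or {}))
    marker_betas = marker_betas or {m: 0.02 for m in target_r2}
    ksw = np.array([d.ksw_true for d in dataset.discs])
    if np.ptp(ksw) == 0:
        raise ValueError("degenerate dataset: constant k_sw")
    rng = np.random.default_rng(seed)
    rows = []
    for marker, r2 in target_r2.items():
        for comp in compartments:
            rq = simulate_rq_values(ksw, r2, beta=marker_betas[marker], rng=rng)
            for d, v in zip(dataset.discs, rq):
                rows.append(
                    {
                        "disc_id": d.disc_id,
                        "marker": marker,
                        "compartment": comp,
                        "rq": float(v),
                        "ksw": d.ksw_true,
                    }
                )
    return pd.DataFrame(rows)
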