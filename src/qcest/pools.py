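"""Physical parameter containers for two-pool CEST simulation.

The forward model is a two-pool (water + exchangeable solute) Bloch-McConnell
system.  For glycosaminoglycan (GAG) imaging of the intervertebral disc the
solute pool is the GAG hydroxyl proton resonance at +1.0 ppm from water; its
exchange rate with water, ``k_sw``, is base-catalysed and therefore rises as
the disc acidifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Proton gyromagnetic ratio, MHz/T (equivalently Hz/uT).
GAMMA_MHZ_PER_T = 42.577

#: Hz per ppm per Tesla of static field.
HZ_PER_PPM_PER_T = GAMMA_MHZ_PER_T  # 42.577 Hz/ppm at 1 T


@dataclass(frozen=True)
class TwoPoolModel:
    """Ground-truth relaxation/exchange parameters of a water+solute system.

    Parameters
    ----------
    R1w, R2w : float
        Water longitudinal / transverse relaxation rates (1/s).
    R1s, R2s : float
        Solute pool relaxation rates (1/s).
    f_r : float
        Solute/water proton fraction (dimensionless, ``0 <= f_r < 1``).
    delta_s : float
        Solute chemical shift relative to water (ppm); +1.0 for GAG
        hydroxyl protons.
    k_sw : float
        Solute-to-water proton exchange rate (1/s).
    B0 : float
        Static field strength (T).
    """

    R1w: float = 1.0 / 1.2
    R2w: float = 1.0 / 0.08
    R1s: float = 1.0
    R2s: float = 66.7
    f_r: float = 0.003
    delta_s: float = 1.0
    k_sw: float = 500.0
    B0: float = 3.0

    def __post_init__(self) -> None:
        for name in ("R1w", "R2w", "R1s", "R2s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_r < 1.0:
            raise ValueError(f"f_r must be in [0, 1), got {self.f_r}")
        if self.k_sw < 0:
            raise ValueError(f"k_sw must be >= 0, got {self.k_sw}")
        if self.B0 <= 0:
            raise ValueError(f"B0 must be > 0, got {self.B0}")

    @property
    def hz_per_ppm(self) -> float:
        """Chemical-shift scale of the static field (Hz per ppm)."""
        return HZ_PER_PPM_PER_T * self.B0

    def with_(self, **kwargs) -> "TwoPoolModel":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


# Offsets of the disc CEST protocol: 10 points at +/-1.6, 1.3, 1.0, 0.7, 0.4 ppm.
CEST_OFFSETS_PPM = np.array(
    [-1.6, -1.3, -1.0, -0.7, -0.4, 0.4, 0.7, 1.0, 1.3, 1.6]
)

# WASSR offsets: -0.8 .. 0.8 ppm in 0.2 ppm steps.
WASSR_OFFSETS_PPM = np.round(np.arange(-0.8, 0.81, 0.2), 10)


@dataclass(frozen=True)
class SaturationScheme:
    """Pulsed saturation train geometry.

    A train of ``n_pulses`` Gaussian-shaped RF pulses of duration ``t_p``
    separated by delays ``t_d`` (duty cycle ``t_p/(t_p+t_d)``), played at each
    frequency offset for each nominal flip angle in ``flip_angles``.  The
    nominal flip angle of one pulse relates to its time-average B1 amplitude
    through ``B1 = flip/(gamma * t_p)``.
    """

    n_pulses: int
    t_p: float
    t_d: float
    flip_angles: tuple
    offsets_ppm: tuple
    sigma: float | None = None  # Gaussian width (s); default t_p/4
    crusher: bool = True
    apodized: bool = True  # subtract the truncation-edge amplitude (smooth rolloff)
    n_steps: int = 192  # piecewise-constant RF steps per pulse

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.t_p <= 0:
            raise ValueError("t_p must be > 0")
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if len(self.flip_angles) == 0 or len(self.offsets_ppm) == 0:
            raise ValueError("flip_angles and offsets_ppm must be non-empty")
        object.__setattr__(self, "flip_angles", tuple(float(a) for a in self.flip_angles))
        object.__setattr__(self, "offsets_ppm", tuple(float(o) for o in self.offsets_ppm))

    @property
    def sigma_s(self) -> float:
        """Effective Gaussian width (s); defaults to ``t_p / 4``."""
        return self.t_p / 4.0 if self.sigma is None else self.sigma

    @property
    def duty_cycle(self) -> float:
        return self.t_p / (self.t_p + self.t_d)

    @property
    def total_duration(self) -> float:
        """Total saturation duration ``T_s = n_pulses * (t_p + t_d)`` (s)."""
        return self.n_pulses * (self.t_p + self.t_d)

    def b1_amplitudes_ut(self) -> np.ndarray:
        """Time-average B1 amplitude (uT) for each flip angle."""
        from .quantify import b1_from_flip_angle

        return np.array([b1_from_flip_angle(a, self.t_p) for a in self.flip_angles])


def disc_cest_scheme(**overrides) -> SaturationScheme:
    """The disc gagCEST saturation protocol: 39 Gaussian pulses, t_p = t_d =
    80 ms (duty cycle 50%, T_s = 6240 ms), flip angles 900/1500/2100/3000 deg
    (average B1 of 0.73, 1.22, 1.71 and 2.45 uT), 10 offsets at
    +/-0.4 .. 1.6 ppm."""
    params = dict(
        n_pulses=39,
        t_p=0.080,
        t_d=0.080,
        flip_angles=(900.0, 1500.0, 2100.0, 3000.0),
        offsets_ppm=tuple(CEST_OFFSETS_PPM),
    )
    params.update(overrides)
    return SaturationScheme(**params)


def wassr_scheme(**overrides) -> SaturationScheme:
    """The WASSR direct-saturation protocol: 2 Gaussian pulses, t_p = t_d =
    30 ms (T_s = 120 ms), flip angle 90 deg, offsets -0.8 .. 0.8 ppm in
    0.2 ppm steps."""
    params = dict(
        n_pulses=2,
        t_p=0.030,
        t_d=0.030,
        flip_angles=(90.0,),
        offsets_ppm=tuple(WASSR_OFFSETS_PPM),
    )
    params.update(overrides)
    return SaturationScheme(**params)
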