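"""Z-spectrum containers shared across simulation, B0 correction and qCEST."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ZSpectrum:
    """A single normalized saturation spectrum.

    ``offsets_ppm`` are saturation frequency offsets from the nominal water
    resonance (ppm, sorted ascending); ``z`` are normalized water signals
    ``M_z,sat / M_0`` in ``(0, 1]``.
    """

    offsets_ppm: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.offsets_ppm.shape != self.z.shape or self.offsets_ppm.ndim != 1:
            raise ValueError("offsets and z must be 1-D arrays of equal length")
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.offsets_ppm)

    def value_at(self, offset_ppm: float) -> float:
        """Z at an acquired offset (exact match within 1e-9)."""
        idx = np.nonzero(np.isclose(self.offsets_ppm, offset_ppm, atol=1e-9))[0]
        if idx.size != 1:
            raise KeyError(f"offset {offset_ppm} ppm not acquired")
        return float(self.z[idx[0]])


@dataclass
class ZSpectrumSet:
    """Z-spectra of one voxel/ROI acquired at several B1 amplitudes.

    ``z`` has shape ``(n_b1, n_offsets)``; row ``i`` is the spectrum at
    ``b1_ut[i]`` (time-average B1 amplitude, uT).
    """

    offsets_ppm: np.ndarray
    b1_ut: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.b1_ut = np.asarray(self.b1_ut, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.b1_ut.size, self.offsets_ppm.size):
            raise ValueError(
                f"z shape {self.z.shape} does not match "
                f"({self.b1_ut.size}, {self.offsets_ppm.size})"
            )
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")

    @property
    def n_b1(self) -> int:
        return self.b1_ut.size

    def spectrum(self, i: int) -> ZSpectrum:
        """The spectrum at the ``i``-th B1 amplitude."""
        return ZSpectrum(self.offsets_ppm.copy(), self.z[i].copy())
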