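"""Static-field (B0) correction from WASSR spectra.

A low-power direct-water-saturation spectrum is symmetric about the true
water resonance.  The per-voxel field offset is found by maximum-symmetry
centre-frequency (MSCF) search: the candidate centre C minimizing

    cost(C) = sum_w [ Z(C + w) - Z(C - w) ]^2

over a mirror-offset grid, with the measured spectrum interpolated by a
cubic spline.  A coarse-to-fine grid search (1 mHz-scale resolution in ppm)
is refined by parabolic interpolation around the grid optimum.  CEST
Z-spectra are then re-interpolated so their values are reported at nominal
offsets relative to the *true* water frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .spectra import ZSpectrum, ZSpectrumSet

__all__ = ["B0Estimate", "estimate_b0_shift_mscf", "correct_zspectrum", "b0_map"]

_GRID_STEP_PPM = 0.001
_MIRROR_STEP_PPM = 0.02


@dataclass
class B0Estimate:
    """MSCF search result: the shift plus search diagnostics."""

    shift_ppm: float
    cost: float
    on_boundary: bool
    unimodal: bool

    def __float__(self) -> float:
        return self.shift_ppm


_LOCAL_HALFWIDTH_PPM = 0.1


def _symmetry_cost(spline, centers: np.ndarray, window: float) -> np.ndarray:
    """Mean squared mirror asymmetry of the spline about each candidate
    centre, over a window fixed across candidates."""
    w = np.arange(_MIRROR_STEP_PPM, window + _MIRROR_STEP_PPM / 2, _MIRROR_STEP_PPM)
    c = np.asarray(centers)[:, None]
    d = spline(c + w) - spline(c - w)
    return np.mean(d * d, axis=1)


def estimate_b0_shift_mscf(
    wassr: ZSpectrum, search_halfwidth: float = 0.5
) -> B0Estimate:
    """Estimate the per-voxel B0 offset (ppm) from a WASSR spectrum.

    The search is anchored at the interpolated spectral minimum, then the
    symmetry centre is located on a 0.001 ppm grid within +/-0.1 ppm of the
    anchor, using a mirror window of fixed width for every candidate (a
    candidate-dependent window would favour centres near the acquired edge,
    where only the flat wings are compared).

    Requires at least 5 offsets spanning 0 and an interior spectral minimum.
    A minimum found on the search boundary, or a spectrum whose sampled
    minimum is not unique/interior, is flagged in the returned diagnostics
    rather than raised.
    """
    offs, z = wassr.offsets_ppm, wassr.z
    if offs.size < 5:
        raise ValueError("need >= 5 WASSR offsets")
    if offs[0] > 0 or offs[-1] < 0:
        raise ValueError("WASSR offsets must span 0 ppm")
    i_min = int(np.argmin(z))
    unimodal = 0 < i_min < offs.size - 1 and (
        np.all(np.diff(z[: i_min + 1]) < 0) and np.all(np.diff(z[i_min:]) > 0)
    )
    spline = CubicSpline(offs, z)
    lo, hi = float(offs[0]), float(offs[-1])

    # stage 1: anchor at the interpolated minimum
    dense = np.arange(lo, hi + _GRID_STEP_PPM / 2, _GRID_STEP_PPM)
    anchor = float(dense[np.argmin(spline(dense))])
    anchor = float(np.clip(anchor, -search_halfwidth, search_halfwidth))

    # stage 2: fixed-window symmetry search around the anchor
    g_lo = max(anchor - _LOCAL_HALFWIDTH_PPM, -search_halfwidth)
    g_hi = min(anchor + _LOCAL_HALFWIDTH_PPM, search_halfwidth)
    grid = np.arange(g_lo, g_hi + _GRID_STEP_PPM / 2, _GRID_STEP_PPM)
    window = min(hi - grid[-1], grid[0] - lo)
    if window <= _MIRROR_STEP_PPM:
        raise ValueError("spectral minimum too close to the acquired edge")
    costs = _symmetry_cost(spline, grid, window)
    i = int(np.argmin(costs))
    on_boundary = i in (0, grid.size - 1) and abs(grid[i]) >= search_halfwidth - 1e-9
    shift = float(grid[i])
    if not on_boundary and np.isfinite(costs[i - 1 : i + 2]).all():
        # parabolic refinement through the three grid points around the optimum
        y0, y1, y2 = costs[i - 1 : i + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            shift += _GRID_STEP_PPM * 0.5 * (y0 - y2) / denom
    return B0Estimate(
        shift_ppm=shift,
        cost=float(costs[i]),
        on_boundary=on_boundary,
        unimodal=bool(unimodal),
    )


def correct_zspectrum(cest: ZSpectrumSet, shift_ppm: float) -> ZSpectrumSet:
    """Re-centre a CEST Z-spectrum set on the true water frequency.

    A nominal acquisition offset ``x`` actually sits at ``x - shift``
    relative to water; the corrected value at nominal offset ``w`` is the
    acquired spectrum interpolated at ``w + shift``.  Each B1's spectrum is
    interpolated independently with a shape-preserving (monotone-safe)
    cubic.  Edge offsets whose corrected position would require
    extrapolation are set to NaN (for the disc protocol only the outermost
    +/-1.6 ppm points can be affected); a shift larger than the acquired
    span is an error.
    """
    offs = cest.offsets_ppm
    span = offs[-1] - offs[0]
    if abs(shift_ppm) > span:
        raise ValueError(
            f"shift {shift_ppm} ppm exceeds the acquired offset span "
            f"[{offs[0]}, {offs[-1]}] ppm"
        )
    target = offs + shift_ppm
    z_new = np.full_like(cest.z, np.nan)
    for i in range(cest.n_b1):
        finite = np.isfinite(cest.z[i])
        if finite.sum() < 2:
            continue
        o_f, z_f = offs[finite], cest.z[i, finite]
        inside = (target >= o_f[0] - 1e-12) & (target <= o_f[-1] + 1e-12)
        z_new[i, inside] = PchipInterpolator(o_f, z_f)(target[inside])
    return ZSpectrumSet(offs.copy(), cest.b1_ut.copy(), z_new)


def b0_map(
    wassr_volume: np.ndarray,
    offsets_ppm: np.ndarray,
    search_halfwidth: float = 0.5,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise B0 shift map (ppm) from a WASSR image stack.

    ``wassr_volume`` has shape ``(..., n_offsets)``; voxels outside the mask
    or failing the search are NaN.
    """
    wassr_volume = np.asarray(wassr_volume, dtype=float)
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    spatial = wassr_volume.shape[:-1]
    if wassr_volume.shape[-1] != offsets_ppm.size:
        raise ValueError("last axis must match the offset list")
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    out = np.full(spatial, np.nan)
    for idx in np.ndindex(*spatial):
        if not mask[idx]:
            continue
        try:
            est = estimate_b0_shift_mscf(
                ZSpectrum(offsets_ppm, wassr_volume[idx]), search_halfwidth
            )
        except ValueError:
            continue
        if not est.on_boundary:
            out[idx] = est.shift_ppm
    return out
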