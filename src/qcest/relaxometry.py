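"""Voxelwise/ROI relaxometry: T1 (inversion recovery), T2 and T1rho maps.

Three signal equations are fitted by least squares:

* inversion recovery  ``I = I0 * [1 - (1 + eta) * exp(-TI/T1)]`` with
  inversion efficiency ``eta`` in [0, 1];
* monoexponential decay ``I = I0 * exp(-t/tau)`` for multi-echo (T2, t = TE)
  and spin-lock (T1rho, t = TSL) series.

Magnitude inversion-recovery data lose the sign of the early-TI points; the
IR fit restores polarity by trying every plausible sign-flip prefix (up to
and including the signal minimum) and keeping the lowest-residual fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RelaxometrySeries",
    "FitResult",
    "fit_inversion_recovery",
    "fit_monoexponential",
    "map_fit",
]

_XTOL = 1e-12
_MAX_NFEV = 200 * 10


@dataclass
class RelaxometrySeries:
    """A (timing, signal) series tagged with its acquisition role.

    ``role`` is ``"TI"`` (inversion recovery), ``"TE"`` (multi-echo) or
    ``"TSL"`` (spin-lock); timings in seconds, strictly increasing.
    """

    timings: np.ndarray
    signals: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.timings = np.asarray(self.timings, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.role not in ("TI", "TE", "TSL"):
            raise ValueError(f"unknown series role {self.role!r}")
        if self.timings.ndim != 1 or self.timings.shape != self.signals.shape:
            raise ValueError("timings and signals must be 1-D of equal length")
        if self.timings.size == 0:
            raise ValueError("series is empty")
        if np.any(np.diff(self.timings) <= 0):
            raise ValueError("timings must be strictly increasing")
        if np.any(self.timings < 0):
            raise ValueError("timings must be non-negative")


@dataclass
class FitResult:
    params: dict
    rss: float
    converged: bool
    message: str = ""


def _ir_model(theta: np.ndarray, ti: np.ndarray) -> np.ndarray:
    i0, eta, t1 = theta
    return i0 * (1.0 - (1.0 + eta) * np.exp(-ti / t1))


def fit_inversion_recovery(series: RelaxometrySeries) -> FitResult:
    """Fit ``I = I0*[1 - (1+eta)*exp(-TI/T1)]`` to an inversion-recovery series.

    For all-positive (magnitude) data, candidate sign flips of the leading
    points up to the signal minimum are tried and the lowest-RSS fit kept.
    Non-convergence and degenerate data are flagged, not raised.
    """
    if series.role != "TI":
        raise ValueError("inversion-recovery fit requires a TI series")
    ti, sig = series.timings, series.signals
    if ti.size < 4:
        raise ValueError("need >= 4 points to fit (I0, eta, T1)")
    scale = float(np.max(np.abs(sig)))
    if scale == 0.0:
        return FitResult({"I0": 0.0, "eta": np.nan, "T1": np.nan}, 0.0, False,
                         "all-zero signals")

    if np.all(sig >= 0):
        i_min = int(np.argmin(sig))
        candidates = [np.concatenate([-sig[:k], sig[k:]]) for k in range(i_min + 2)]
    else:
        candidates = [sig]

    best: FitResult | None = None
    for cand in candidates:
        # null-point heuristic: TI where the signal crosses/attains minimum
        t1_0 = max(ti[int(np.argmin(np.abs(cand)))] / np.log(2.0), ti[0])
        theta0 = np.array([scale, 1.0, t1_0])
        try:
            res = least_squares(
                lambda th: _ir_model(th, ti) - cand,
                theta0,
                bounds=([0.0, 0.0, 1e-6], [np.inf, 1.0, np.inf]),
                xtol=_XTOL, ftol=_XTOL, gtol=None, max_nfev=_MAX_NFEV,
            )
        except ValueError:
            continue
        rss = float(2.0 * res.cost)
        fr = FitResult(
            {"I0": float(res.x[0]), "eta": float(res.x[1]), "T1": float(res.x[2])},
            rss, bool(res.success), res.message,
        )
        if best is None or rss < best.rss:
            best = fr
    if best is None:
        return FitResult({"I0": np.nan, "eta": np.nan, "T1": np.nan},
                         np.inf, False, "no candidate converged")
    return best


def fit_monoexponential(series: RelaxometrySeries) -> FitResult:
    """Fit ``I = I0 * exp(-t/tau)``; serves T2 (TE) and T1rho (TSL) series.

    Initialized from the closed-form log-linear regression when all signals
    are positive, then refined by nonlinear least squares.  A series showing
    no decay gets a flagged (non-converged) result with ``tau`` at the
    upper bound ``100 * t_max``.
    """
    if series.role not in ("TE", "TSL"):
        raise ValueError("monoexponential fit requires a TE or TSL series")
    t, sig = series.timings, series.signals
    if t.size < 2:
        raise ValueError("need >= 2 points to fit (I0, tau)")
    if np.ptp(t) == 0:
        raise ValueError("all timings equal")
    tau_max = 100.0 * float(t[-1]) if t[-1] > 0 else 1e6

    if np.all(sig > 0):
        # exact log-linear LS: ln I = ln I0 - t/tau
        b, a = np.polyfit(t, np.log(sig), 1)
        tau0 = -1.0 / b if b < 0 else tau_max
        i0_0 = float(np.exp(a))
    else:
        tau0 = max(float(t[-1] - t[0]), 1e-3)
        i0_0 = max(float(sig[0]), 1e-12)
    tau0 = float(np.clip(tau0, 1e-9, tau_max))

    res = least_squares(
        lambda th: th[0] * np.exp(-t / th[1]) - sig,
        np.array([i0_0, tau0]),
        bounds=([0.0, 1e-9], [np.inf, tau_max]),
        xtol=_XTOL, ftol=_XTOL, gtol=None, max_nfev=_MAX_NFEV,
    )
    tau = float(res.x[1])
    flat = tau >= 0.99 * tau_max
    return FitResult(
        {"I0": float(res.x[0]), "tau": tau},
        float(2.0 * res.cost),
        bool(res.success) and not flat,
        "no measurable decay" if flat else res.message,
    )


def map_fit(
    volume_series: np.ndarray,
    timings: np.ndarray,
    model: str,
    mask: np.ndarray | None = None,
    role: str | None = None,
) -> np.ndarray:
    """Pixel-by-pixel least-squares fitting of a stack of images.

    Parameters
    ----------
    volume_series : ndarray, shape (..., n_timings)
        Image stack, last axis ordered like ``timings``.
    timings : 1-D array (s)
    model : {"IR", "monoexp"}
    mask : boolean ndarray over the spatial grid, optional
    role : series role; defaults to "TI" for IR and "TE" for monoexp

    Returns
    -------
    ndarray over the spatial grid holding T1 (IR) or tau (monoexp) per
    voxel; unmasked and failed voxels are NaN.
    """
    volume_series = np.asarray(volume_series, dtype=float)
    timings = np.asarray(timings, dtype=float)
    if model not in ("IR", "monoexp"):
        raise ValueError(f"unknown model {model!r}")
    if volume_series.shape[-1] != timings.size:
        raise ValueError(
            f"last axis ({volume_series.shape[-1]}) must match "
            f"timings ({timings.size})"
        )
    spatial = volume_series.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape must match the spatial grid")
    role = role or ("TI" if model == "IR" else "TE")
    fit = fit_inversion_recovery if model == "IR" else fit_monoexponential
    key = "T1" if model == "IR" else "tau"

    out = np.full(spatial, np.nan)
    for idx in np.ndindex(*spatial):
        if not mask[idx]:
            continue
        try:
            r = fit(RelaxometrySeries(timings, volume_series[idx], role))
        except ValueError:
            continue
        if r.converged:
            out[idx] = r.params[key]
    return out
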