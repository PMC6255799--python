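"""End-to-end phantom pipeline: simulate -> fit -> correct -> quantify -> stats.

``run_pipeline`` drives the full analysis at ROI (per-disc) level, matching
how per-disc values are reported: relaxometry fits of the ROI-averaged
series, WASSR B0 estimation and Z-spectrum re-centring, omega-plot exchange
-rate estimation, then pH calibration, biomarker correlation and ROC
classification of degenerated vs healthy discs.  All randomness flows from
the single seed in the config; a run writes its resolved config beside the
outputs so it can be re-run identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .b0 import correct_zspectrum, estimate_b0_shift_mscf
from .calibration import fit_ph_calibration, linear_correlation, roc_analysis
from .quantify import QcestConfig, estimate_ksw
from .relaxometry import (
    RelaxometrySeries,
    fit_inversion_recovery,
    fit_monoexponential,
)
from .synthetic import generate_biomarker_table, make_disc_phantom
from .io import write_config

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "qcest_out",
    "phantom": {
        "n_healthy": 4,
        "n_degen": 12,
        "noise_sd": 0.005,
        "noise_model": "gaussian",
        "n_voxels": 121,
        "ph_healthy": [7.2, 0.10],
        "ph_degen": [6.3, 0.15],
        "calibration_a": 1.3,
        "calibration_b": 248.2,
    },
    "qcest": {
        "R2s": 66.7,
        "r2_threshold": 0.9,
    },
    "b0": {
        "search_halfwidth": 0.5,
    },
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if key not in merged:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise KeyError(f"config section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    raise KeyError(f"unknown config key: {key}.{k2}")
                merged[key][k2] = v2
        else:
            merged[key] = val
    return merged


def _analyze_disc(disc, dataset, qcfg: QcestConfig, b0_halfwidth: float) -> dict:
    row: dict = {"disc_id": disc.disc_id, "group": disc.group,
                 "ph_measured": disc.ph_measured}
    ir = fit_inversion_recovery(
        RelaxometrySeries(dataset.tis, disc.ir_obs.mean(axis=0), "TI"))
    t2 = fit_monoexponential(
        RelaxometrySeries(dataset.tes, disc.te_obs.mean(axis=0), "TE"))
    t1r = fit_monoexponential(
        RelaxometrySeries(dataset.tsls, disc.tsl_obs.mean(axis=0), "TSL"))
    row["T1"] = ir.params["T1"] if ir.converged else np.nan
    row["T2"] = t2.params["tau"] if t2.converged else np.nan
    row["T1rho"] = t1r.params["tau"] if t1r.converged else np.nan

    est = estimate_b0_shift_mscf(disc.roi_wassr(dataset.wassr_offsets),
                                 b0_halfwidth)
    row["b0_shift"] = est.shift_ppm if not est.on_boundary else np.nan
    row["b0_flag"] = bool(est.on_boundary)
    try:
        corrected = correct_zspectrum(
            disc.roi_zset(dataset.cest_offsets, dataset.b1_ut),
            row["b0_shift"] if np.isfinite(row["b0_shift"]) else 0.0,
        )
        ksw, fit = estimate_ksw(corrected, qcfg)
        row["ksw"] = ksw
        row["omega_plot_r2"] = fit.r_squared
        row["n_b1_used"] = fit.n_used
    except (ValueError, KeyError) as exc:
        row.update(ksw=np.nan, omega_plot_r2=np.nan, n_b1_used=0)
        row["qc_note"] = str(exc)
    return row


def run_pipeline(config: dict | None = None) -> dict:
    """Run the phantom pipeline; returns the result bundle and writes it.

    The bundle holds the per-disc table, the fitted pH calibration, the ROC
    result, biomarker correlations, and a JSON report with per-stage QC
    counts.
    """
    cfg = validate_config(config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    ph = cfg["phantom"]

    from .calibration import CalibrationModel

    dataset = make_disc_phantom(
        n_healthy=int(ph["n_healthy"]),
        n_degen=int(ph["n_degen"]),
        calibration=CalibrationModel(a=ph["calibration_a"], b=ph["calibration_b"]),
        ph_healthy=tuple(ph["ph_healthy"]),
        ph_degen=tuple(ph["ph_degen"]),
        noise_sd=float(ph["noise_sd"]),
        noise_model=ph["noise_model"],
        n_voxels=int(ph["n_voxels"]),
        seed=seed,
    )
    qcfg = QcestConfig(R2s=float(cfg["qcest"]["R2s"]),
                       r2_threshold=float(cfg["qcest"]["r2_threshold"]))
    rows = [
        _analyze_disc(d, dataset, qcfg, float(cfg["b0"]["search_halfwidth"]))
        for d in dataset.discs
    ]
    table = pd.DataFrame(rows)
    truth = dataset.manifest()
    table = table.merge(
        truth[["disc_id", "ph_true", "ksw_true", "b0_shift_true"]], on="disc_id"
    )

    ok = table["ksw"].notna()
    calib = None
    if ok.sum() >= 3 and np.ptp(table.loc[ok, "ph_measured"]) > 0.3:
        calib = fit_ph_calibration(
            table.loc[ok, "ph_measured"].to_numpy(),
            table.loc[ok, "ksw"].to_numpy(),
        )
    roc = roc_analysis(
        table.loc[ok, "ksw"].to_numpy(),
        (table.loc[ok, "group"] == "degenerated").to_numpy(),
    )

    biomarkers = generate_biomarker_table(dataset, seed=seed + 1)
    marker_stats = []
    for marker, sub in biomarkers.groupby("marker"):
        slope, intercept, r, r2, p = linear_correlation(
            sub["ksw"].to_numpy(), sub["rq"].to_numpy()
        )
        marker_stats.append(
            {"marker": marker, "slope": slope, "intercept": intercept,
             "pearson_r": r, "r_squared": r2, "p_value": p}
        )
    marker_stats = pd.DataFrame(marker_stats)

    # outputs
    table.to_csv(outdir / "discs.csv", index=False)
    biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    marker_stats.to_csv(outdir / "biomarker_correlations.csv", index=False)
    pd.DataFrame(
        {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
         "specificity": roc.specificity}
    ).to_csv(outdir / "roc.csv", index=False)
    if calib is not None:
        (outdir / "calibration.json").write_text(json.dumps(
            {"a": calib.a, "b": calib.b, "r_squared": calib.r_squared}, indent=2))

    by_group = table.groupby("group")["ksw"].mean()
    report = {
        "version": __version__,
        "seed": seed,
        "n_discs": len(table),
        "qc": {
            "relaxometry_failed": int(table[["T1", "T2", "T1rho"]].isna().any(axis=1).sum()),
            "b0_flagged": int(table["b0_flag"].sum()),
            "ksw_failed": int((~ok).sum()),
        },
        "mean_ksw": {g: float(v) for g, v in by_group.items()},
        "roc_auc": roc.auc,
        "youden": {
            "threshold": roc.youden_threshold,
            "sensitivity": roc.youden_sensitivity,
            "specificity": roc.youden_specificity,
        },
        "calibration": None if calib is None else
        {"a": calib.a, "b": calib.b, "r_squared": calib.r_squared},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    write_config(outdir / "resolved_config.yaml", cfg)
    return {
        "config": cfg,
        "table": table,
        "calibration": calib,
        "roc": roc,
        "biomarkers": biomarkers,
        "marker_stats": marker_stats,
        "report": report,
    }
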