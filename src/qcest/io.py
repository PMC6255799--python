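"""Readers and writers: NIfTI volumes/maps, CSV tables, config files."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_map",
    "read_nifti",
    "read_image_series",
    "read_table",
    "load_config",
    "write_config",
    "export_phantom",
]


def write_map(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    """Write a parameter map / volume as NIfTI (float32, identity affine
    unless given)."""
    path = Path(path)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot read NIfTI {path}: {exc}") from exc
    return np.asarray(img.dataobj, dtype=float), img.affine


def read_image_series(paths, expected_count: int | None = None) -> np.ndarray:
    """Load and stack a series of equally-shaped volumes along a new last axis.

    ``expected_count`` (e.g. from a manifest) is checked against the number
    of files.
    """
    paths = [Path(p) for p in paths]
    if expected_count is not None and len(paths) != expected_count:
        raise ValueError(
            f"manifest expects {expected_count} volumes, got {len(paths)}"
        )
    vols = []
    shape = None
    for p in paths:
        data, _ = read_nifti(p)
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise ValueError(f"{p}: shape {data.shape} != {shape}")
        vols.append(data)
    return np.stack(vols, axis=-1)


def read_table(path, required_columns=()) -> pd.DataFrame:
    """Read a CSV table with a mandatory header row.

    Missing required columns raise; extra columns are preserved with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    df = pd.read_csv(path)
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    extra = set(df.columns) - set(required_columns)
    if required_columns and extra:
        warnings.warn(
            f"{path}: extra column(s) {sorted(extra)} preserved", stacklevel=2
        )
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(path, config: dict) -> Path:
    """Write the resolved config beside the outputs (YAML)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def export_phantom(dataset, outdir) -> dict:
    """Export a phantom dataset: NIfTI stacks, CSV manifest, YAML config.

    The spatial grid is (disc, ROI voxel); each acquisition series is one
    NIfTI with the measurement axis last (CEST additionally one file per
    B1 amplitude).  Returns a dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    z = np.stack([d.z_obs for d in dataset.discs])  # (disc, vox, b1, off)
    cest_paths = []
    for k, b1 in enumerate(dataset.b1_ut):
        p = write_map(outdir / f"cest_b1_{k}.nii.gz", z[:, :, k, :])
        cest_paths.append(str(p))
    paths["cest"] = cest_paths
    paths["wassr"] = str(
        write_map(outdir / "wassr.nii.gz", np.stack([d.wassr_obs for d in dataset.discs]))
    )
    for name, attr in (("ir", "ir_obs"), ("te", "te_obs"), ("tsl", "tsl_obs")):
        paths[name] = str(
            write_map(outdir / f"{name}.nii.gz",
                      np.stack([getattr(d, attr) for d in dataset.discs]))
        )
    manifest = outdir / "manifest.csv"
    dataset.manifest().to_csv(manifest, index=False)
    paths["manifest"] = str(manifest)
    scheme = dataset.scheme
    cfg = {
        "seed": dataset.seed,
        "noise_sd": dataset.noise_sd,
        "noise_model": dataset.noise_model,
        "calibration": {"a": dataset.calibration.a, "b": dataset.calibration.b},
        "scheme": {
            "n_pulses": scheme.n_pulses,
            "t_p": scheme.t_p,
            "t_d": scheme.t_d,
            "sigma": scheme.sigma_s,
            "crusher": scheme.crusher,
            "flip_angles": list(scheme.flip_angles),
            "offsets_ppm": list(scheme.offsets_ppm),
            "b1_ut": [float(b) for b in dataset.b1_ut],
        },
        "wassr_offsets_ppm": list(dataset.wassr.offsets_ppm),
        "timings": {
            "TI": list(map(float, dataset.tis)),
            "TE": list(map(float, dataset.tes)),
            "TSL": list(map(float, dataset.tsls)),
        },
    }
    paths["config"] = str(write_config(outdir / "phantom_config.yaml", cfg))
    return paths
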