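"""Readers and writers for the pipeline's file formats.

Time courses and matrices travel as labelled CSV (comma-separated, UTF-8,
"." decimal); volumes, maps and masks as NIfTI; manifests and ground truth
as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd


class TableParseError(ValueError):
    """A delimited table failed validation; the message names the line."""


def read_timeseries_table(path) -> pd.DataFrame:
    """Read a T x N time-series table (header row of unique labels,
    numeric body). Errors name the offending line (1-based, header = 1)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TableParseError(f"{path}: file is empty") from None
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise TableParseError(f"{path}: duplicate column labels {dupes}")
        ncol = len(header)
        body = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise TableParseError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {ncol}"
                )
            vals = []
            for col, cell in zip(header, row):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise TableParseError(
                        f"{path}: non-numeric cell {cell!r} in column "
                        f"{col!r} at line {lineno}"
                    ) from None
            body.append(vals)
    if not body:
        raise TableParseError(f"{path}: no data rows")
    return pd.DataFrame(body, columns=header)


def write_timeseries_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_matrix_csv(path) -> pd.DataFrame:
    """Read a labelled square matrix CSV (row labels in the first column)."""
    frame = pd.read_csv(path, index_col=0)
    return frame


def write_matrix_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path)


def read_covariate_table(path) -> pd.DataFrame:
    """Subject covariate table: subject_id, group, age, sex."""
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(frame.columns)
    if missing:
        raise TableParseError(f"{path}: missing columns {sorted(missing)}")
    return frame


def save_nifti(array: np.ndarray, path, affine=None) -> None:
    """Write a 3-D map/mask or 4-D volume as NIfTI (identity affine by
    default; voxel indices are 0-based)."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file; returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def load_template_dir(template_dir) -> tuple[list[str], np.ndarray]:
    """Load an RSN template set: a directory of 3-D NIfTI maps plus a
    ``labels.json`` manifest mapping label -> filename (order preserved)."""
    template_dir = Path(template_dir)
    with open(template_dir / "labels.json") as fh:
        manifest = json.load(fh)
    labels, maps = [], []
    for label, fname in manifest.items():
        arr, _ = load_nifti(template_dir / fname)
        labels.append(label)
        maps.append(arr)
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"template maps are not co-registered: shapes {shapes}")
    return labels, np.stack(maps)


def save_template_dir(labels, maps, template_dir) -> None:
    template_dir = Path(template_dir)
    template_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for label, arr in zip(labels, maps):
        fname = f"{label}.nii.gz"
        save_nifti(np.asarray(arr), template_dir / fname)
        manifest[label] = fname
    with open(template_dir / "labels.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def write_manifest(entries: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
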