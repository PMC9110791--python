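"""NIfTI and table I/O with light schema validation.

Volumes are written as uncompressed ``.nii`` so that byte-level
reproducibility of a pipeline run depends only on the data (no compression
container metadata). All volumes of one subject are expected to share a
grid; the orchestrator refuses silent resampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["read_nifti", "write_nifti", "read_cohort_tsv", "write_table",
           "write_json", "COHORT_REQUIRED_COLUMNS"]

COHORT_REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex")


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)`` with float data."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_cohort_tsv(path) -> pd.DataFrame:
    """Read a subject table, validating the minimal column schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"cohort table {path} is missing required columns: {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_default) + "\n")
    return path
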