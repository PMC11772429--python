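"""File formats: the per-patient contour JSON schema and the clinical CSV.

Contour files are hierarchical JSON, one per patient::

    {
      "patient_id": "pt-001",
      "units": "mm",                  # mandatory; only "mm" accepted
      "frames": [
        {"phase_fraction": 0.0,
         "points": [[x, y, z], ...],  # ordered closed ring, mm
         "landmarks": {"septal": 0, "lateral": 32,
                        "anterior": 16, "posterior": 48},
         "rv_volume_ml": 180.0},
        ...
      ]
    }

Validation errors cite the JSON path of the offending field. In strict
mode (default) unknown keys are rejected; otherwise they are warned
about and ignored. The clinical table is a CSV with required columns
``patient_id, height_cm, weight_kg, time_days, event`` plus free
numeric covariate columns (``rvef``, ``lvef``, ``tapse_tte``, ...).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .measurement import LANDMARK_NAMES, AnnulusFrame, AnnulusSequence

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_annulus_sequence",
    "write_annulus_sequence",
    "read_clinical_table",
    "REQUIRED_CLINICAL_COLUMNS",
]

REQUIRED_CLINICAL_COLUMNS = ("patient_id", "height_cm", "weight_kg", "time_days", "event")

_TOP_KEYS = {"patient_id", "units", "frames"}
_FRAME_KEYS = {"phase_fraction", "points", "landmarks", "rv_volume_ml"}


class SchemaError(ValueError):
    """A contour or clinical file violates its schema."""


def _check_keys(obj: dict, allowed: set, path: str, strict: bool) -> None:
    unknown = sorted(set(obj) - allowed)
    if unknown:
        if strict:
            raise SchemaError(f"{path}: unknown key(s) {unknown}")
        logger.warning("%s: ignoring unknown key(s) %s", path, unknown)


def read_annulus_sequence(path, strict: bool = True) -> AnnulusSequence:
    """Read and validate a contour JSON file into an AnnulusSequence.

    Raises :class:`SchemaError` with the JSON path of the first
    offending field (missing landmark, wrong units, non-increasing
    phase fractions, malformed points, ...).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")
    _check_keys(doc, _TOP_KEYS, "$", strict)
    for key in ("patient_id", "units", "frames"):
        if key not in doc:
            raise SchemaError(f"$.{key}: required key missing")
    if doc["units"] != "mm":
        raise SchemaError(f"$.units: coordinates must be in 'mm', got {doc['units']!r}")
    if not isinstance(doc["frames"], list) or not doc["frames"]:
        raise SchemaError("$.frames: must be a nonempty list")
    frames = []
    for i, fr in enumerate(doc["frames"]):
        where = f"$.frames[{i}]"
        if not isinstance(fr, dict):
            raise SchemaError(f"{where}: frame must be a JSON object")
        _check_keys(fr, _FRAME_KEYS, where, strict)
        for key in _FRAME_KEYS:
            if key not in fr:
                raise SchemaError(f"{where}.{key}: required key missing")
        pts = np.asarray(fr["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise SchemaError(f"{where}.points: expected a list of [x, y, z] triples")
        lm = fr["landmarks"]
        if not isinstance(lm, dict):
            raise SchemaError(f"{where}.landmarks: must map landmark name to vertex index")
        for name in LANDMARK_NAMES:
            if name not in lm:
                raise SchemaError(f"{where}.landmarks: missing landmark '{name}'")
        try:
            frames.append(
                AnnulusFrame(
                    phase_fraction=float(fr["phase_fraction"]),
                    contour=pts,
                    landmarks={str(k): int(v) for k, v in lm.items()},
                    rv_volume=float(fr["rv_volume_ml"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    try:
        return AnnulusSequence(str(doc["patient_id"]), frames)
    except ValueError as exc:
        raise SchemaError(f"$.frames: {exc}") from exc


def write_annulus_sequence(seq: AnnulusSequence, path) -> Path:
    """Write an AnnulusSequence as schema-conformant contour JSON."""
    path = Path(path)
    doc = {
        "patient_id": seq.patient_id,
        "units": "mm",
        "frames": [
            {
                "phase_fraction": f.phase_fraction,
                "points": [[float(c) for c in row] for row in f.contour],
                "landmarks": {k: int(v) for k, v in sorted(f.landmarks.items())},
                "rv_volume_ml": float(f.rv_volume),
            }
            for f in seq.frames
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate the patient-level clinical CSV.

    Enforces required columns, unique patient ids, and numeric
    parseability of every non-id column; ``event`` must be 0/1 and
    ``time_days`` non-negative.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"{path}: duplicate patient_id(s) {dupes}")
    for col in df.columns:
        if col == "patient_id":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column '{col}' is not numeric: {exc}") from exc
    if not df["event"].dropna().isin([0, 1]).all():
        raise SchemaError(f"{path}: column 'event' must be 0/1")
    if (df["time_days"].dropna() < 0).any():
        raise SchemaError(f"{path}: column 'time_days' must be >= 0")
    return df
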