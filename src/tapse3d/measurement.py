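"""Per-patient CT-TAPSE measurement pipeline.

From a full-cycle sequence of 3D tricuspid annulus contours (one per
cardiac reconstruction phase, each with four labeled anatomical
landmarks and an RV volume), this module derives:

* the end-systolic (ES) and end-diastolic (ED) phases — the phases of
  minimum and maximum RV volume;
* directional TAPSE — the 3D displacement of the septal, lateral,
  anterior and posterior annular landmarks between ED and ES (mm);
* TAPSE volume — the volume of the slab swept between the diastolic and
  systolic annulus, ``D * (A1 + A2) / 2``, where A1 and A2 are the
  shoelace areas of the two annuli projected onto their own best-fit
  planes and D is the orthogonal distance from one annulus centroid to
  the other annulus' best-fit plane (reported in ml);
* body-surface-area (Du Bois) indexed versions of all of the above
  (mm/m², ml/m²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    as_contour,
    centroid,
    fit_plane,
    point_plane_distance,
    polygon_area,
    project_to_plane,
)

__all__ = [
    "LANDMARK_NAMES",
    "MM3_PER_ML",
    "AnnulusFrame",
    "AnnulusSequence",
    "TapseResult",
    "Biometrics",
    "IndexedTapse",
    "select_es_ed",
    "directional_tapse",
    "tapse_volume",
    "measure_sequence",
    "compute_bsa",
    "index_measurements",
]

#: The four annular landmark labels, in canonical reporting order.
LANDMARK_NAMES = ("septal", "lateral", "anterior", "posterior")

#: The single place where mm³ are converted to ml.
MM3_PER_ML = 1000.0


@dataclass
class AnnulusFrame:
    """One cardiac phase: contour (mm), landmark indices, RV volume (ml)."""

    phase_fraction: float
    contour: np.ndarray
    landmarks: dict[str, int]
    rv_volume: float

    def __post_init__(self) -> None:
        self.contour = as_contour(self.contour, label=f"frame at phase {self.phase_fraction}")
        n = len(self.contour)
        missing = [k for k in LANDMARK_NAMES if k not in self.landmarks]
        if missing:
            raise ValueError(
                f"frame at phase {self.phase_fraction}: missing landmark(s) {missing}"
            )
        idx = [self.landmarks[k] for k in LANDMARK_NAMES]
        if any((not isinstance(i, (int, np.integer))) or i < 0 or i >= n for i in idx):
            raise ValueError(
                f"frame at phase {self.phase_fraction}: landmark indices must be in [0, {n})"
            )
        if len(set(int(i) for i in idx)) != len(idx):
            raise ValueError(f"frame at phase {self.phase_fraction}: landmark indices must be distinct")
        if not (self.rv_volume > 0):
            raise ValueError(f"frame at phase {self.phase_fraction}: rv_volume must be > 0 ml")

    def landmark_position(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise KeyError(f"landmark '{name}' missing at phase {self.phase_fraction}")
        return self.contour[int(self.landmarks[name])]


@dataclass
class AnnulusSequence:
    """A patient's full-cycle acquisition: frames at increasing phase fractions."""

    patient_id: str
    frames: list[AnnulusFrame]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError(f"{self.patient_id}: need at least 2 frames")
        phases = [f.phase_fraction for f in self.frames]
        if any(b <= a for a, b in zip(phases, phases[1:])):
            raise ValueError(f"{self.patient_id}: phase fractions must be strictly increasing")
        keys = set(self.frames[0].landmarks)
        for f in self.frames[1:]:
            if set(f.landmarks) != keys:
                raise ValueError(f"{self.patient_id}: inconsistent landmark keys across frames")

    def frame_at(self, phase_fraction: float) -> AnnulusFrame:
        for f in self.frames:
            if f.phase_fraction == phase_fraction:
                return f
        raise KeyError(f"{self.patient_id}: no frame at phase {phase_fraction}")


@dataclass
class TapseResult:
    """The six CT-TAPSE measurements plus the selected phases."""

    es_phase: float
    ed_phase: float
    tapse_septal: float
    tapse_lateral: float
    tapse_anterior: float
    tapse_posterior: float
    area_a1: float
    area_a2: float
    displacement_d: float
    tapse_volume: float  # ml

    def directional(self) -> dict[str, float]:
        return {name: getattr(self, f"tapse_{name}") for name in LANDMARK_NAMES}

    def as_dict(self) -> dict[str, float]:
        return {
            "es_phase": self.es_phase,
            "ed_phase": self.ed_phase,
            **{f"tapse_{k}": v for k, v in self.directional().items()},
            "area_a1": self.area_a1,
            "area_a2": self.area_a2,
            "displacement_d": self.displacement_d,
            "tapse_volume": self.tapse_volume,
        }


def select_es_ed(seq: AnnulusSequence) -> tuple[float, float]:
    """Identify end-systole and end-diastole from the RV volume curve.

    ES is the phase with the minimum RV volume and ED the phase with the
    maximum; ties are broken toward the earliest phase fraction.

    Raises
    ------
    ValueError
        If every frame has the same RV volume (no systole/diastole
        distinguishable).
    """
    vols = np.array([f.rv_volume for f in seq.frames])
    if float(vols.max()) == float(vols.min()):
        raise ValueError(f"{seq.patient_id}: all RV volumes equal; cannot identify ES/ED phases")
    es = seq.frames[int(np.argmin(vols))].phase_fraction
    ed = seq.frames[int(np.argmax(vols))].phase_fraction
    return es, ed


def directional_tapse(
    seq: AnnulusSequence,
    es_phase: float,
    ed_phase: float,
    mode: str = "euclidean",
) -> dict[str, float]:
    """Landmark excursion (mm) between the ED and ES annulus positions.

    ``mode='euclidean'`` (default) returns the full 3D Euclidean
    displacement of each labeled landmark. ``mode='long_axis'`` instead
    projects the displacement onto the ED best-fit-plane normal (a
    long-axis surrogate), provided for sensitivity analysis.
    """
    if mode not in ("euclidean", "long_axis"):
        raise ValueError(f"unknown TAPSE mode {mode!r}")
    es_frame = seq.frame_at(es_phase)
    ed_frame = seq.frame_at(ed_phase)
    axis = None
    if mode == "long_axis":
        axis = fit_plane(ed_frame.contour, label=f"{seq.patient_id} ED contour").normal
    out: dict[str, float] = {}
    for name in LANDMARK_NAMES:
        disp = ed_frame.landmark_position(name) - es_frame.landmark_position(name)
        if axis is None:
            out[name] = float(np.linalg.norm(disp))
        else:
            out[name] = float(abs(disp @ axis))
    return out


def tapse_volume(
    es_frame: AnnulusFrame,
    ed_frame: AnnulusFrame,
    d_reference: str = "ed_plane",
    patient_id: str = "",
) -> dict[str, float]:
    """A1, A2, D and the TAPSE volume from the ES and ED annuli.

    Each contour is projected onto its own best-fit plane; A1 is the
    shoelace area of the projected ED annulus and A2 of the projected ES
    annulus (the assignment is immaterial under the symmetric mean).
    With ``d_reference='ed_plane'`` (default), D is the absolute
    orthogonal distance from the ES contour centroid to the ED best-fit
    plane; ``'symmetric'`` averages that with the reverse distance (the
    two differ only when the planes are not parallel). The volume
    ``D * (A1 + A2) / 2`` is converted from mm³ to ml.
    """
    if d_reference not in ("ed_plane", "symmetric"):
        raise ValueError(f"unknown d_reference {d_reference!r}")
    tag = f"{patient_id} " if patient_id else ""
    plane_ed = fit_plane(ed_frame.contour, label=f"{tag}ED contour (phase {ed_frame.phase_fraction})")
    plane_es = fit_plane(es_frame.contour, label=f"{tag}ES contour (phase {es_frame.phase_fraction})")
    proj_ed = project_to_plane(ed_frame.contour, plane_ed)
    proj_es = project_to_plane(es_frame.contour, plane_es)
    a1 = polygon_area(proj_ed, plane_ed, label=f"{tag}ED contour")
    a2 = polygon_area(proj_es, plane_es, label=f"{tag}ES contour")
    d = point_plane_distance(centroid(es_frame.contour), plane_ed)
    if d_reference == "symmetric":
        d = 0.5 * (d + point_plane_distance(centroid(ed_frame.contour), plane_es))
    volume_ml = d * (a1 + a2) / 2.0 / MM3_PER_ML
    return {"area_a1": a1, "area_a2": a2, "displacement_d": d, "tapse_volume": volume_ml}


def measure_sequence(
    seq: AnnulusSequence,
    tapse_mode: str = "euclidean",
    d_reference: str = "ed_plane",
) -> TapseResult:
    """Run the full measurement pipeline on one annulus sequence."""
    es_phase, ed_phase = select_es_ed(seq)
    directions = directional_tapse(seq, es_phase, ed_phase, mode=tapse_mode)
    vol = tapse_volume(
        seq.frame_at(es_phase), seq.frame_at(ed_phase),
        d_reference=d_reference, patient_id=seq.patient_id,
    )
    return TapseResult(
        es_phase=es_phase,
        ed_phase=ed_phase,
        tapse_septal=directions["septal"],
        tapse_lateral=directions["lateral"],
        tapse_anterior=directions["anterior"],
        tapse_posterior=directions["posterior"],
        **vol,
    )


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m²) by the Du Bois formula.

    ``BSA = 0.007184 * weight^0.425 * height^0.725`` with weight in kg
    and height in cm. Inputs outside plausible adult ranges (height
    100–250 cm, weight 25–300 kg) are rejected.
    """
    if not (100.0 < height_cm < 250.0):
        raise ValueError(f"height {height_cm} cm outside plausible range (100, 250)")
    if not (25.0 < weight_kg < 300.0):
        raise ValueError(f"weight {weight_kg} kg outside plausible range (25, 300)")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


@dataclass
class Biometrics:
    """Height (cm), weight (kg) and the derived Du Bois BSA (m²)."""

    height: float
    weight: float
    bsa: float = field(init=False)

    def __post_init__(self) -> None:
        self.bsa = compute_bsa(self.height, self.weight)


@dataclass
class IndexedTapse:
    """BSA-indexed TAPSE measurements (mm/m², ml/m²)."""

    itapse_septal: float
    itapse_lateral: float
    itapse_anterior: float
    itapse_posterior: float
    itapse_volume: float
    bsa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "itapse_septal": self.itapse_septal,
            "itapse_lateral": self.itapse_lateral,
            "itapse_anterior": self.itapse_anterior,
            "itapse_posterior": self.itapse_posterior,
            "itapse_volume": self.itapse_volume,
            "bsa": self.bsa,
        }


def index_measurements(result: TapseResult, biometrics: Biometrics) -> IndexedTapse:
    """Divide each directional TAPSE and the TAPSE volume by BSA."""
    bsa = biometrics.bsa
    if not (bsa > 0) or not math.isfinite(bsa):
        raise ValueError(f"BSA must be positive and finite, got {bsa}")
    return IndexedTapse(
        itapse_septal=result.tapse_septal / bsa,
        itapse_lateral=result.tapse_lateral / bsa,
        itapse_anterior=result.tapse_anterior / bsa,
        itapse_posterior=result.tapse_posterior / bsa,
        itapse_volume=result.tapse_volume / bsa,
        bsa=bsa,
    )
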