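"""Core data model for co-registered multiparametric short-axis stacks.

A :class:`SubjectStudy` bundles, per short-axis slice, one
:class:`ParametricMap` for each modality (native T1-map in ms, dark-blood
T2-weighted signal intensity, LGE signal intensity), a :class:`HeartGeometry`
describing the myocardial ring (masks, AHA segment labels, transmural
coordinate, skeletal-muscle reference region), and a per-(slice, segment,
modality) quality-control table. Studies round-trip through a directory of
NIfTI volumes plus a versioned JSON sidecar.

Conventions: pixel indices are row-major and 0-based; a pixel's physical area
is ``row_spacing * col_spacing``; slice 0 is the most basal slice. All three
modalities of a slice share one analysis grid and one geometry.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIDECAR_SCHEMA_VERSION = "1.0"

MODALITIES = ("T1", "T2W", "LGE")

#: label-volume codes
BACKGROUND_CODE = 0
SEGMENT_CODES = tuple(range(1, 17))
MUSCLE_CODE = 100

#: AHA 16-segment model: wall name per segment code.
SEGMENT_WALLS: Dict[int, str] = {
    1: "anterior", 2: "anteroseptal", 3: "inferoseptal",
    4: "inferior", 5: "inferolateral", 6: "anterolateral",
    7: "anterior", 8: "anteroseptal", 9: "inferoseptal",
    10: "inferior", 11: "inferolateral", 12: "anterolateral",
    # apical ring has 4 segments; septal/lateral map to one of the paired names
    13: "anterior", 14: "inferoseptal", 15: "inferior", 16: "anterolateral",
}

WALL_NAMES = ("anterior", "anteroseptal", "inferoseptal",
              "inferior", "inferolateral", "anterolateral")

QC_REASONS = ("artifact", "motion", "low-signal", "partial-volume")


class StudyIOError(RuntimeError):
    """Raised when a study directory is missing files or carries bad labels."""


@dataclass(frozen=True)
class ParametricMap:
    """One co-registered 2D slice of a parametric or signal-intensity map.

    ``pixels`` holds finite real values — milliseconds for modality ``T1``,
    arbitrary units for ``T2W`` and ``LGE``. ``slice_index`` 0 is the most
    basal slice.
    """

    pixels: np.ndarray
    pixel_spacing: Tuple[float, float]  # (row mm, col mm)
    slice_index: int
    slice_thickness: float  # mm
    modality: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or min(px.shape) < 16:
            raise ValueError(f"map grid must be 2D and at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("map contains non-finite pixels")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass(frozen=True)
class HeartGeometry:
    """Myocardial ring geometry for one short-axis slice.

    ``transmural`` is the normalized radial depth within the wall: 0 at the
    endocardial border, 1 at the epicardial border, NaN outside the myocardial
    mask. ``segments`` labels the myocardial mask with AHA codes 1-16 and is 0
    elsewhere; the skeletal-muscle mask is disjoint from the myocardium.
    """

    center: Tuple[float, float]  # (row, col) in px
    endo_radius_mm: float
    epi_radius_mm: float
    myo_mask: np.ndarray  # bool
    segments: np.ndarray  # int, 0 background
    muscle_mask: np.ndarray  # bool
    transmural: np.ndarray  # float in [0,1] on myo_mask, NaN elsewhere

    def __post_init__(self) -> None:
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ValueError("degenerate ring: endocardial radius >= epicardial radius")
        if np.any(self.myo_mask & self.muscle_mask):
            raise ValueError("skeletal-muscle mask overlaps the myocardium")
        if np.any((self.segments > 0) != self.myo_mask):
            raise ValueError("segment labels do not partition the myocardial mask")
        tm = self.transmural[self.myo_mask]
        if tm.size and (np.nanmin(tm) < -1e-9 or np.nanmax(tm) > 1 + 1e-9):
            raise ValueError("transmural coordinate out of [0, 1] on the mask")

    @property
    def segment_ids(self) -> Tuple[int, ...]:
        ids = np.unique(self.segments[self.segments > 0])
        return tuple(int(i) for i in ids)

    def segment_mask(self, segment_id: int) -> np.ndarray:
        return self.segments == segment_id


@dataclass(frozen=True)
class StudySlice:
    """All modalities of one short-axis slice on a shared grid, plus geometry."""

    index: int
    maps: Mapping[str, ParametricMap]
    geometry: HeartGeometry

    def __post_init__(self) -> None:
        shapes = {m.pixels.shape for m in self.maps.values()}
        shapes.add(self.geometry.myo_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"slice {self.index}: modalities/geometry grid shapes differ: {shapes}")


class QCTable:
    """Per-(slice, segment, modality) inclusion flags.

    Backed by a DataFrame with columns ``slice, segment, modality, included,
    reason`` (reason empty for included triples). Exactly one row exists per
    (slice, segment, modality) triple of the study.
    """

    COLUMNS = ("slice", "segment", "modality", "included", "reason")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)[list(self.COLUMNS)]
        dup = frame.duplicated(subset=["slice", "segment", "modality"])
        if dup.any():
            raise ValueError("duplicate qc triples")
        self.frame = frame
        self._lookup = {
            (int(r.slice), int(r.segment), r.modality): bool(r.included)
            for r in frame.itertuples()
        }

    @classmethod
    def all_included(cls, slices: Sequence["StudySlice"]) -> "QCTable":
        rows = [
            (sl.index, seg, mod, True, "")
            for sl in slices
            for seg in sl.geometry.segment_ids
            for mod in MODALITIES
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def is_included(self, slice_index: int, segment: int, modality: str) -> bool:
        return self._lookup[(slice_index, segment, modality)]

    def excluded(self) -> pd.DataFrame:
        return self.frame[~self.frame.included]

    def excluded_fraction(self, modality: str) -> float:
        sub = self.frame[self.frame.modality == modality]
        if len(sub) == 0:
            return 0.0
        return float(1.0 - sub.included.mean())

    def included_mask(self, sl: "StudySlice", modality: str) -> np.ndarray:
        """Boolean grid of myocardium belonging to qc-included segments."""
        out = np.zeros_like(sl.geometry.myo_mask)
        for seg in sl.geometry.segment_ids:
            if self.is_included(sl.index, seg, modality):
                out |= sl.geometry.segment_mask(seg)
        return out

    def with_all_included(self) -> "QCTable":
        frame = self.frame.copy()
        frame["included"] = True
        frame["reason"] = ""
        return QCTable(frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QCTable) and self._lookup == other._lookup


@dataclass
class SubjectStudy:
    """One subject: ordered slices, quality-control flags and metadata."""

    subject_id: str
    group: str  # control, I, II, III
    slices: List[StudySlice]
    qc: QCTable
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "I", "II", "III"):
            raise ValueError(f"unknown group {self.group!r}")
        have = {(sl.index, seg, mod)
                for sl in self.slices
                for seg in sl.geometry.segment_ids
                for mod in MODALITIES}
        flagged = set(self.qc._lookup)
        if have != flagged:
            raise ValueError("qc table does not cover exactly the study's (slice, segment, modality) triples")

    @property
    def is_patient(self) -> bool:
        return self.group != "control"

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def maps(self, modality: str) -> List[ParametricMap]:
        return [sl.maps[modality] for sl in self.slices]

    def spacing(self, modality: str) -> Tuple[float, float]:
        return self.slices[0].maps[modality].pixel_spacing


@dataclass(frozen=True)
class QCReport:
    """Per-modality segment-exclusion summary."""

    excluded_fraction: Dict[str, float]
    reasons: Dict[str, Dict[str, int]]

    def __post_init__(self) -> None:
        for f in self.excluded_fraction.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("excluded fraction out of [0, 1]")


def qc_report(study: SubjectStudy) -> QCReport:
    fractions = {m: study.qc.excluded_fraction(m) for m in MODALITIES}
    reasons: Dict[str, Dict[str, int]] = {m: {} for m in MODALITIES}
    for row in study.qc.excluded().itertuples():
        reasons[row.modality][row.reason] = reasons[row.modality].get(row.reason, 0) + 1
    return QCReport(fractions, reasons)


# ---------------------------------------------------------------------------
# geometry construction


def build_aha_segments(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    endo_radius_mm: float,
    epi_radius_mm: float,
    pixel_spacing: Tuple[float, float],
    position: str,
    start_angle_deg: float = -30.0,
) -> np.ndarray:
    """Label a myocardial ring with AHA segments for one slice.

    Basal and mid slices get 6 equiangular segments (codes 1-6 / 7-12), apical
    slices 4 at 90 deg (codes 13-16). The angle convention: 0 deg points to the
    anterior wall (up, decreasing row), increasing counterclockwise on the
    displayed image (toward the septum). ``start_angle_deg`` is the boundary at
    which the first segment of the ring begins (the anterior septal insertion
    is at ``start_angle_deg + 60`` for 6-segment rings).
    """
    if endo_radius_mm >= epi_radius_mm:
        raise ValueError("degenerate ring: endocardial radius >= epicardial radius")
    if position not in ("basal", "mid", "apical"):
        raise ValueError(f"unknown slice position {position!r}")
    rows, cols = np.indices(shape)
    up = (center[0] - rows) * pixel_spacing[0]
    left = (center[1] - cols) * pixel_spacing[1]
    radius = np.hypot(up, left)
    theta = np.degrees(np.arctan2(left, up)) % 360.0

    ring = (radius >= endo_radius_mm) & (radius <= epi_radius_mm)
    n_seg = 4 if position == "apical" else 6
    base_code = {"basal": 1, "mid": 7, "apical": 13}[position]
    start = start_angle_deg if n_seg == 6 else start_angle_deg - 15.0
    sector = np.floor(((theta - start) % 360.0) / (360.0 / n_seg)).astype(int)
    sector = np.clip(sector, 0, n_seg - 1)
    labels = np.where(ring, base_code + sector, 0)
    return labels.astype(np.int16)


def build_ring_geometry(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    endo_radius_mm: float,
    epi_radius_mm: float,
    pixel_spacing: Tuple[float, float],
    position: str,
    muscle_mask: Optional[np.ndarray] = None,
    start_angle_deg: float = -30.0,
) -> HeartGeometry:
    """Build a full :class:`HeartGeometry` (masks, segments, transmural depth)."""
    segments = build_aha_segments(
        shape, center, endo_radius_mm, epi_radius_mm, pixel_spacing, position, start_angle_deg
    )
    myo = segments > 0
    rows, cols = np.indices(shape)
    radius = np.hypot((rows - center[0]) * pixel_spacing[0], (cols - center[1]) * pixel_spacing[1])
    with np.errstate(invalid="ignore"):
        tm = (radius - endo_radius_mm) / (epi_radius_mm - endo_radius_mm)
    tm = np.clip(tm, 0.0, 1.0)
    tm = np.where(myo, tm, np.nan)
    if muscle_mask is None:
        muscle_mask = np.zeros(shape, dtype=bool)
    muscle_mask = muscle_mask & ~myo
    return HeartGeometry(
        center=tuple(map(float, center)),
        endo_radius_mm=float(endo_radius_mm),
        epi_radius_mm=float(epi_radius_mm),
        myo_mask=myo,
        segments=segments,
        muscle_mask=muscle_mask,
        transmural=tm,
    )


def slice_position(index: int, n_slices: int) -> str:
    """Classify a slice as basal/mid/apical by thirds of the stack (base first)."""
    third = n_slices / 3.0
    if index < math.floor(third + 1e-9):
        return "basal"
    if index < math.floor(2 * third + 1e-9):
        return "mid"
    return "apical"


# ---------------------------------------------------------------------------
# I/O

_MODALITY_FILES = {"T1": "t1.nii.gz", "T2W": "t2w.nii.gz", "LGE": "lge.nii.gz"}
_LABEL_FILE = "labels.nii.gz"
_SIDECAR_FILE = "study.json"


def _affine(spacing: Tuple[float, float], thickness: float) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], thickness, 1.0])


def write_study(study: SubjectStudy, path: Path | str) -> Path:
    """Write a study as NIfTI volumes plus a JSON sidecar.

    The sidecar is written with sorted keys and fixed float formatting so that
    write -> read -> write is byte-stable.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    thickness = study.slices[0].maps["T1"].slice_thickness
    for mod, fname in _MODALITY_FILES.items():
        vol = np.stack([sl.maps[mod].pixels for sl in study.slices], axis=-1)
        spacing = study.spacing(mod)
        # float64 so that write -> read round-trips maps to tight tolerance
        img = nib.Nifti1Image(vol.astype(np.float64), _affine(spacing, thickness))
        nib.save(img, str(path / fname))

    labels = []
    for sl in study.slices:
        lab = sl.geometry.segments.astype(np.int16).copy()
        lab[sl.geometry.muscle_mask] = MUSCLE_CODE
        labels.append(lab)
    lab_vol = np.stack(labels, axis=-1)
    nib.save(nib.Nifti1Image(lab_vol, _affine(study.spacing("T1"), thickness)), str(path / _LABEL_FILE))

    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "subject_id": study.subject_id,
        "group": study.group,
        "slice_thickness_mm": thickness,
        "pixel_spacing_mm": {m: list(study.spacing(m)) for m in MODALITIES},
        "geometry": [
            {
                "slice": sl.index,
                "center": list(sl.geometry.center),
                "endo_radius_mm": sl.geometry.endo_radius_mm,
                "epi_radius_mm": sl.geometry.epi_radius_mm,
            }
            for sl in study.slices
        ],
        "qc_excluded": [
            {"slice": int(r.slice), "segment": int(r.segment), "modality": r.modality, "reason": r.reason}
            for r in study.qc.excluded().itertuples()
        ],
        "metadata": study.metadata,
    }
    (path / _SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_study(path: Path | str) -> SubjectStudy:
    """Read a study directory written by :func:`write_study`.

    On a spacing mismatch between the sidecar and a NIfTI header the header
    wins and a warning is logged.
    """
    path = Path(path)
    sidecar_path = path / _SIDECAR_FILE
    if not sidecar_path.exists():
        raise StudyIOError(f"missing sidecar {_SIDECAR_FILE} in {path}")
    sidecar = json.loads(sidecar_path.read_text())

    vols: Dict[str, np.ndarray] = {}
    spacings: Dict[str, Tuple[float, float]] = {}
    thickness = float(sidecar["slice_thickness_mm"])
    for mod, fname in _MODALITY_FILES.items():
        fpath = path / fname
        if not fpath.exists():
            raise StudyIOError(f"missing modality file {fname} for {mod} in {path}")
        img = nib.load(str(fpath))
        vols[mod] = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        hdr_spacing = (round(float(zooms[0]), 6), round(float(zooms[1]), 6))
        sc_spacing = tuple(round(float(v), 6) for v in sidecar["pixel_spacing_mm"][mod])
        if hdr_spacing != sc_spacing:
            logger.warning(
                "%s: %s spacing mismatch sidecar %s vs header %s; using header",
                path.name, mod, sc_spacing, hdr_spacing,
            )
        spacings[mod] = hdr_spacing
        if len(zooms) >= 3:
            thickness = round(float(zooms[2]), 6)

    lab_path = path / _LABEL_FILE
    if not lab_path.exists():
        raise StudyIOError(f"missing label file {_LABEL_FILE} in {path}")
    lab_vol = np.asarray(nib.load(str(lab_path)).dataobj).astype(int)
    valid = {BACKGROUND_CODE, MUSCLE_CODE, *SEGMENT_CODES}
    bad = set(np.unique(lab_vol)) - valid
    if bad:
        raise StudyIOError(f"label volume carries invalid codes {sorted(bad)}")

    n_slices = vols["T1"].shape[2]
    geo_by_slice = {g["slice"]: g for g in sidecar["geometry"]}
    slices: List[StudySlice] = []
    for k in range(n_slices):
        lab = lab_vol[:, :, k]
        muscle = lab == MUSCLE_CODE
        segments = np.where(muscle, 0, lab).astype(np.int16)
        myo = segments > 0
        g = geo_by_slice[k]
        rows, cols = np.indices(lab.shape)
        sp = spacings["T1"]
        radius = np.hypot((rows - g["center"][0]) * sp[0], (cols - g["center"][1]) * sp[1])
        with np.errstate(invalid="ignore"):
            tm = np.clip((radius - g["endo_radius_mm"]) / (g["epi_radius_mm"] - g["endo_radius_mm"]), 0, 1)
        tm = np.where(myo, tm, np.nan)
        geometry = HeartGeometry(
            center=tuple(g["center"]),
            endo_radius_mm=float(g["endo_radius_mm"]),
            epi_radius_mm=float(g["epi_radius_mm"]),
            myo_mask=myo,
            segments=segments,
            muscle_mask=muscle,
            transmural=tm,
        )
        maps = {
            mod: ParametricMap(
                pixels=vols[mod][:, :, k],
                pixel_spacing=spacings[mod],
                slice_index=k,
                slice_thickness=thickness,
                modality=mod,
            )
            for mod in MODALITIES
        }
        slices.append(StudySlice(index=k, maps=maps, geometry=geometry))

    excluded = {(e["slice"], e["segment"], e["modality"]): e["reason"] for e in sidecar["qc_excluded"]}
    rows_qc = []
    for sl in slices:
        for seg in sl.geometry.segment_ids:
            for mod in MODALITIES:
                reason = excluded.get((sl.index, seg, mod))
                rows_qc.append((sl.index, seg, mod, reason is None, reason or ""))
    qc = QCTable(pd.DataFrame(rows_qc, columns=list(QCTable.COLUMNS)))

    return SubjectStudy(
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
        slices=slices,
        qc=qc,
        metadata=sidecar.get("metadata", {}),
    )


def studies_equal(a: SubjectStudy, b: SubjectStudy, atol: float = 1e-6) -> bool:
    """Field-by-field equality: exact for masks/labels, ``atol`` for maps."""
    if (a.subject_id, a.group, a.n_slices) != (b.subject_id, b.group, b.n_slices):
        return False
    if a.qc != b.qc or a.metadata != b.metadata:
        return False
    for sa, sb in zip(a.slices, b.slices):
        ga, gb = sa.geometry, sb.geometry
        if not (np.array_equal(ga.segments, gb.segments) and np.array_equal(ga.muscle_mask, gb.muscle_mask)):
            return False
        if not np.allclose(
            np.nan_to_num(ga.transmural, nan=-1), np.nan_to_num(gb.transmural, nan=-1), atol=atol
        ):
            return False
        for mod in MODALITIES:
            if not np.allclose(sa.maps[mod].pixels, sb.maps[mod].pixels, atol=atol):
                return False
            if sa.maps[mod].pixel_spacing != sb.maps[mod].pixel_spacing:
                return False
    return True
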