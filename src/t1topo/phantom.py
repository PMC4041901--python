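"""Synthetic multiparametric short-axis cohorts with pixel-level ground truth.

The phantom emulates the population structure of a suspected-acute-myocarditis
study: 50 healthy controls plus three patient subgroups — Group I (edema+,
LGE+), Group II (edema-, LGE+) and Group III (edema-, LGE-) with default sizes
41/12/7. Each subject is a 9-slice short-axis stack of three co-registered
maps on one analysis grid:

- native T1-map (ms): per-subject baseline drawn from the group distribution
  (controls 946 +/- 23 ms), plus focal lesion offsets, plus pixel noise;
- dark-blood T2-weighted signal intensity: skeletal-muscle baseline times a
  spatially varying SI-ratio field (controls' global ratio 1.56 +/- 0.15);
- LGE signal intensity: nulled-myocardium baseline with enhancing lesions.

Lesions are annular-sector specs (circumferential center/width, transmural
band, slice span) preferentially subepicardial/midwall in the lateral and
inferior walls — the non-ischemic pattern. Noise is additive Gaussian per
pixel (a Rician approximation adequate at the simulated SNRs). QC flags are
sampled per (slice, segment, modality) at the configured exclusion rates.

Everything is deterministic for a fixed seed; per-subject seeds derive from
the master seed through a counter-based ``SeedSequence`` scheme, so enlarging
a cohort never reshuffles existing subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    MODALITIES,
    QC_REASONS,
    HeartGeometry,
    ParametricMap,
    QCTable,
    StudySlice,
    SubjectStudy,
    build_ring_geometry,
    slice_position,
)

GROUPS = ("control", "I", "II", "III")

DEFAULT_GROUP_SIZES: Dict[str, int] = {"control": 50, "I": 41, "II": 12, "III": 7}


@dataclass(frozen=True)
class GeometryConfig:
    """Shared analysis-grid geometry for all phantom subjects."""

    grid: int = 128
    pixel_spacing: Tuple[float, float] = (0.9, 0.9)  # mm, common analysis grid
    n_slices: int = 9
    slice_thickness: float = 8.0  # mm
    center: Tuple[float, float] = (64.0, 64.0)
    epi_radius_mm: float = 32.0
    wall_thickness_mm: float = 9.0
    muscle_rows: Tuple[int, int] = (106, 120)  # paraspinal block
    muscle_cols: Tuple[int, int] = (34, 94)

    @property
    def endo_radius_mm(self) -> float:
        return self.epi_radius_mm - self.wall_thickness_mm

    def muscle_mask(self) -> np.ndarray:
        m = np.zeros((self.grid, self.grid), dtype=bool)
        m[self.muscle_rows[0]:self.muscle_rows[1], self.muscle_cols[0]:self.muscle_cols[1]] = True
        return m


@dataclass(frozen=True)
class LesionSpec:
    """One annular-sector lesion.

    ``band`` is the transmural depth interval occupied by the lesion as
    fractions of wall depth (0 endocardium, 1 epicardium), e.g. (0.67, 1.0)
    is subepicardial. ``d_t2`` is an offset on the T2 SI-ratio field and
    ``lge`` marks gadolinium enhancement.
    """

    slices: Tuple[int, ...]
    center_angle_deg: float
    width_deg: float
    band: Tuple[float, float]
    d_t1: float  # ms
    d_t2: float  # SI-ratio units
    lge: bool

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"transmural band must satisfy 0 <= lo < hi <= 1, got {self.band}")
        if not (0.0 < self.width_deg <= 360.0):
            raise ValueError(f"angular width must be in (0, 360], got {self.width_deg}")

    def mask(self, geometry: HeartGeometry, pixel_spacing: Tuple[float, float]) -> np.ndarray:
        """Pixel mask of the lesion on one slice (within the myocardium)."""
        rows, cols = np.indices(geometry.myo_mask.shape)
        up = (geometry.center[0] - rows) * pixel_spacing[0]
        left = (geometry.center[1] - cols) * pixel_spacing[1]
        theta = np.degrees(np.arctan2(left, up)) % 360.0
        delta = np.abs((theta - self.center_angle_deg + 180.0) % 360.0 - 180.0)
        in_sector = delta <= self.width_deg / 2.0
        tm = geometry.transmural
        with np.errstate(invalid="ignore"):
            in_band = (tm >= self.band[0]) & (tm <= self.band[1])
        return geometry.myo_mask & in_sector & np.nan_to_num(in_band, nan=False)


@dataclass(frozen=True)
class PatternMenuEntry:
    """One lesion template in a group's sampling menu."""

    weight: float
    band: Tuple[float, float]
    center_angle_deg: float  # 0 = anterior, 90 = septal, 180 = inferior, 270 = lateral
    angle_jitter_deg: float
    width_mean_deg: float
    width_sd_deg: float


@dataclass(frozen=True)
class GroupPreset:
    """Per-group generative parameters, calibrated to printed group statistics.

    ``base_t1`` is the per-subject baseline (non-lesion) myocardial T1
    distribution in ms; lesion pixels sit at baseline + ``lesion_dt1``.
    ``t2_ratio`` is the subject's baseline myocardial/skeletal-muscle SI
    ratio. ``target_*`` values are the population statistics the preset aims
    at; they feed the calibration report, never the detector.
    """

    name: str
    base_t1: Tuple[float, float]  # (mean, sd) ms
    t2_ratio: Tuple[float, float]
    lesion_dt1: Tuple[float, float]  # (mean, sd) ms; 0 sd and 0 mean = no offset
    n_lesions: Tuple[int, int]  # inclusive range
    slice_span: Tuple[int, int]  # inclusive range of contiguous slices per lesion
    pattern_menu: Tuple[PatternMenuEntry, ...]
    edema_prob: float  # per-lesion probability of a T2 offset
    edema_dt2: Tuple[float, float]  # (mean, sd) in SI-ratio units
    lge_prob: float  # per-lesion probability of enhancement
    #: fraction of subjects drawn from a mild tail (near-normal baseline,
    #: sub-threshold T1 lesion offsets, LGE still enhancing); calibrates the
    #: group's share of T1-criterion misses
    mild_fraction: float = 0.0
    mild_base_t1: Tuple[float, float] = (950.0, 20.0)
    mild_lesion_dt1: Tuple[float, float] = (25.0, 10.0)
    lesion_free_fraction: float = 0.0  # fraction of subjects carrying no lesion
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 40.0, "T2W": 25.0, "LGE": 6.0}
    )
    qc_exclusion: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 0.11, "T2W": 0.09, "LGE": 0.03}
    )
    lge_evaluable_fraction: float = 1.0
    ef: Tuple[float, float] = (70.0, 8.0)  # %
    troponin_median_iqr: Optional[Tuple[float, float, float]] = None  # ug/L
    days_from_symptoms: Tuple[float, float] = (3.0, 1.0, 6.0)  # median, q1, q3
    target_mean_t1: Tuple[float, float] = (946.0, 23.0)
    target_t2_ratio: Tuple[float, float] = (1.56, 0.15)
    target_extent: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # median, q1, q3 (%)

    def __post_init__(self) -> None:
        for sd in (self.base_t1[1], self.t2_ratio[1], self.lesion_dt1[1]):
            if sd < 0:
                raise ValueError("negative standard deviation in preset")
        for v in self.noise_sd.values():
            if v < 0:
                raise ValueError("negative noise SD")
        for t in self.target_extent:
            if not 0.0 <= t <= 100.0:
                raise ValueError("extent targets must lie in [0, 100]")


_LATERAL = PatternMenuEntry(0.45, (0.65, 1.0), 270.0, 35.0, 80.0, 20.0)
_INFERIOR = PatternMenuEntry(0.30, (0.65, 1.0), 180.0, 30.0, 70.0, 20.0)
_LATERAL_MID = PatternMenuEntry(0.20, (0.33, 0.70), 250.0, 35.0, 70.0, 20.0)
_TRANSMURAL = PatternMenuEntry(0.05, (0.10, 1.0), 225.0, 40.0, 60.0, 15.0)

CONTROL_PRESET = GroupPreset(
    name="control",
    base_t1=(946.0, 23.0),
    t2_ratio=(1.56, 0.15),
    lesion_dt1=(0.0, 0.0),
    n_lesions=(0, 0),
    slice_span=(0, 0),
    pattern_menu=(),
    edema_prob=0.0,
    edema_dt2=(0.0, 0.0),
    lge_prob=0.0,
    lesion_free_fraction=1.0,
    lge_evaluable_fraction=0.7,  # LGE evaluable in 35 of 50 controls
    ef=(72.0, 6.0),
    target_mean_t1=(946.0, 23.0),
    target_t2_ratio=(1.56, 0.15),
    target_extent=(0.0, 0.0, 0.0),
)

GROUP_I_PRESET = GroupPreset(
    name="I",
    base_t1=(1005.0, 45.0),
    t2_ratio=(1.70, 0.20),
    lesion_dt1=(120.0, 30.0),
    mild_fraction=0.19,
    n_lesions=(2, 3),
    slice_span=(4, 7),
    pattern_menu=(_LATERAL, _INFERIOR, _LATERAL_MID, _TRANSMURAL),
    edema_prob=0.5,
    edema_dt2=(0.35, 0.10),
    lge_prob=0.8,
    ef=(61.0, 13.0),
    troponin_median_iqr=(9.60, 3.40, 21.00),
    days_from_symptoms=(2.0, 1.0, 5.0),
    target_mean_t1=(1030.0, 62.0),
    target_t2_ratio=(1.79, 0.27),
    target_extent=(10.0, 8.0, 12.0),
)

GROUP_II_PRESET = GroupPreset(
    name="II",
    base_t1=(975.0, 30.0),
    t2_ratio=(1.60, 0.16),
    lesion_dt1=(110.0, 20.0),
    n_lesions=(1, 2),
    slice_span=(3, 5),
    pattern_menu=(_LATERAL, _INFERIOR, _LATERAL_MID),
    edema_prob=0.3,
    edema_dt2=(0.12, 0.04),
    lge_prob=1.0,
    ef=(70.0, 11.0),
    troponin_median_iqr=(0.54, 0.25, 4.19),
    days_from_symptoms=(3.0, 2.0, 7.0),
    target_mean_t1=(986.0, 54.0),
    target_t2_ratio=(1.60, 0.16),
    target_extent=(5.0, 3.5, 6.0),
)

GROUP_III_PRESET = GroupPreset(
    name="III",
    base_t1=(946.0, 25.0),
    t2_ratio=(1.47, 0.17),
    lesion_dt1=(130.0, 20.0),
    n_lesions=(2, 2),
    slice_span=(2, 2),  # small foci on exactly two contiguous slices
    pattern_menu=(
        PatternMenuEntry(0.6, (0.60, 1.0), 270.0, 40.0, 35.0, 5.0),
        PatternMenuEntry(0.4, (0.60, 1.0), 180.0, 40.0, 35.0, 5.0),
    ),
    edema_prob=0.0,
    edema_dt2=(0.0, 0.0),
    lge_prob=0.0,
    lesion_free_fraction=1.0 / 7.0,  # one of seven subjects carries no lesion
    ef=(72.0, 6.0),
    troponin_median_iqr=(0.48, 0.19, 1.29),
    days_from_symptoms=(3.0, 2.0, 5.0),
    target_mean_t1=(947.0, 27.0),
    target_t2_ratio=(1.47, 0.17),
    target_extent=(1.9, 1.6, 2.1),
)

DEFAULT_PRESETS: Dict[str, GroupPreset] = {
    "control": CONTROL_PRESET,
    "I": GROUP_I_PRESET,
    "II": GROUP_II_PRESET,
    "III": GROUP_III_PRESET,
}

#: baseline signal levels for non-myocardial tissue, in a.u. (and ms for T1)
_T1_BLOOD, _T1_BACKGROUND = 1600.0, 350.0
_T2_MUSCLE_LEVEL, _T2_MUSCLE_SD = 200.0, 8.0
_LGE_MYO, _LGE_LESION_GAIN, _LGE_BLOOD, _LGE_MUSCLE, _LGE_BG = 20.0, 45.0, 100.0, 25.0, 10.0


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject: the acceptance oracle."""

    subject_id: str
    group: str
    seed: int
    lesions: List[LesionSpec]
    injury_masks: List[np.ndarray]  # per slice, modality-independent injured tissue
    true_extent_pct: float

    def has_lesion(self) -> bool:
        return len(self.lesions) > 0


@dataclass
class CohortTruth:
    """Ground truth for a cohort."""

    subjects: List[SubjectTruth]

    def by_id(self, subject_id: str) -> SubjectTruth:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "seed": s.seed,
                    "n_lesions": len(s.lesions),
                    "true_extent_pct": s.true_extent_pct,
                }
                for s in self.subjects
            ]
        )


def _lognormal_params(median: float, q1: float, q3: float) -> Tuple[float, float]:
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2 * 0.674489750196)
    return mu, sigma


def _sample_lesions(
    preset: GroupPreset,
    geo: GeometryConfig,
    rng: np.random.Generator,
    lesion_dt1: Optional[Tuple[float, float]] = None,
) -> List[LesionSpec]:
    if preset.n_lesions[1] == 0 or not preset.pattern_menu:
        return []
    dt1_mean, dt1_sd = lesion_dt1 if lesion_dt1 is not None else preset.lesion_dt1
    n = int(rng.integers(preset.n_lesions[0], preset.n_lesions[1] + 1))
    weights = np.array([e.weight for e in preset.pattern_menu], dtype=float)
    weights /= weights.sum()
    lesions: List[LesionSpec] = []
    any_lge = False
    for k in range(n):
        entry = preset.pattern_menu[int(rng.choice(len(weights), p=weights))]
        span = int(rng.integers(preset.slice_span[0], preset.slice_span[1] + 1))
        span = min(span, geo.n_slices)
        start = int(rng.integers(0, geo.n_slices - span + 1))
        width = float(np.clip(rng.normal(entry.width_mean_deg, entry.width_sd_deg), 15.0, 170.0))
        angle = float((entry.center_angle_deg + rng.normal(0.0, entry.angle_jitter_deg)) % 360.0)
        d_t1 = float(max(rng.normal(dt1_mean, dt1_sd), 5.0))
        d_t2 = 0.0
        if rng.random() < preset.edema_prob:
            d_t2 = float(max(rng.normal(*preset.edema_dt2), 0.0))
        lge = bool(rng.random() < preset.lge_prob)
        lesions.append(
            LesionSpec(
                slices=tuple(range(start, start + span)),
                center_angle_deg=angle,
                width_deg=width,
                band=entry.band,
                d_t1=d_t1,
                d_t2=d_t2,
                lge=lge,
            )
        )
        any_lge = any_lge or lge
    if preset.lge_prob > 0 and not any_lge and lesions:
        lesions[0] = dataclasses.replace(lesions[0], lge=True)
    return lesions


def synthesize_subject(
    preset: GroupPreset,
    geo: GeometryConfig = GeometryConfig(),
    seed: int = 0,
    subject_id: Optional[str] = None,
    lesion_free: Optional[bool] = None,
    lesions: Optional[Sequence[LesionSpec]] = None,
) -> Tuple[SubjectStudy, SubjectTruth]:
    """Generate one subject deterministically from ``(preset, geo, seed)``.

    ``lesion_free`` forces an empty lesion set (used by the cohort builder to
    realize the preset's lesion-free fraction deterministically); ``lesions``
    overrides sampling with explicit specs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subject_id = subject_id or f"{preset.name}-{seed}"

    mild = bool(rng.random() < preset.mild_fraction)
    if lesions is not None:
        lesion_list = list(lesions)
    elif lesion_free:
        lesion_list = []
    else:
        lesion_list = _sample_lesions(
            preset, geo, rng, lesion_dt1=preset.mild_lesion_dt1 if mild else None
        )

    base_params = preset.mild_base_t1 if mild else preset.base_t1
    base_t1 = float(rng.normal(*base_params))
    base_ratio = float(max(rng.normal(*preset.t2_ratio), 0.2))
    muscle_level = float(rng.normal(_T2_MUSCLE_LEVEL, _T2_MUSCLE_SD))

    shape = (geo.grid, geo.grid)
    muscle = geo.muscle_mask()
    slices: List[StudySlice] = []
    injury_masks: List[np.ndarray] = []
    total_myo = 0
    total_injured = 0

    for k in range(geo.n_slices):
        geometry = build_ring_geometry(
            shape, geo.center, geo.endo_radius_mm, geo.epi_radius_mm,
            geo.pixel_spacing, slice_position(k, geo.n_slices), muscle_mask=muscle,
        )
        myo = geometry.myo_mask
        rows, cols = np.indices(shape)
        radius = np.hypot((rows - geo.center[0]) * geo.pixel_spacing[0],
                          (cols - geo.center[1]) * geo.pixel_spacing[1])
        blood = radius < geo.endo_radius_mm

        d_t1 = np.zeros(shape)
        d_t2 = np.zeros(shape)
        lge_mask = np.zeros(shape, dtype=bool)
        injured = np.zeros(shape, dtype=bool)
        for spec in lesion_list:
            if k not in spec.slices:
                continue
            lm = spec.mask(geometry, geo.pixel_spacing)
            if not lm.any():
                raise ValueError(f"lesion spec {spec} falls outside the myocardium on slice {k}")
            # overlapping lesions take the strongest offset rather than summing
            d_t1 = np.where(lm, np.maximum(d_t1, spec.d_t1), d_t1)
            d_t2 = np.where(lm, np.maximum(d_t2, spec.d_t2), d_t2)
            if spec.lge:
                lge_mask |= lm
            injured |= lm
        injury_masks.append(injured)
        total_myo += int(myo.sum())
        total_injured += int(injured.sum())

        t1 = np.full(shape, _T1_BACKGROUND)
        t1[muscle] = 900.0
        t1[blood] = _T1_BLOOD
        t1[myo] = base_t1 + d_t1[myo]
        if preset.noise_sd["T1"] > 0:
            t1 = t1 + rng.normal(0.0, preset.noise_sd["T1"], shape)
        t1[myo] = np.maximum(t1[myo], 1.0)

        t2 = np.full(shape, 0.25 * muscle_level)
        t2[blood] = 0.3 * muscle_level
        t2[muscle] = muscle_level
        t2[myo] = muscle_level * (base_ratio + d_t2[myo])
        if preset.noise_sd["T2W"] > 0:
            t2 = t2 + rng.normal(0.0, preset.noise_sd["T2W"], shape)

        lge = np.full(shape, _LGE_BG)
        lge[blood] = _LGE_BLOOD
        lge[muscle] = _LGE_MUSCLE
        lge[myo] = _LGE_MYO
        lge[lge_mask] = _LGE_MYO + _LGE_LESION_GAIN
        if preset.noise_sd["LGE"] > 0:
            lge = lge + rng.normal(0.0, preset.noise_sd["LGE"], shape)

        maps = {
            "T1": ParametricMap(t1, geo.pixel_spacing, k, geo.slice_thickness, "T1"),
            "T2W": ParametricMap(t2, geo.pixel_spacing, k, geo.slice_thickness, "T2W"),
            "LGE": ParametricMap(lge, geo.pixel_spacing, k, geo.slice_thickness, "LGE"),
        }
        slices.append(StudySlice(index=k, maps=maps, geometry=geometry))

    # qc flags sampled at the configured exclusion rates
    qc_rows = []
    reason_p = (0.5, 0.2, 0.15, 0.15)
    for sl in slices:
        for seg in sl.geometry.segment_ids:
            for mod in MODALITIES:
                excl = rng.random() < preset.qc_exclusion.get(mod, 0.0)
                reason = QC_REASONS[int(rng.choice(4, p=reason_p))] if excl else ""
                qc_rows.append((sl.index, seg, mod, not excl, reason))
    qc = QCTable(pd.DataFrame(qc_rows, columns=list(QCTable.COLUMNS)))

    metadata: Dict[str, object] = {
        "ef_pct": float(rng.normal(*preset.ef)),
        "lge_evaluable": bool(rng.random() < preset.lge_evaluable_fraction),
    }
    if preset.troponin_median_iqr is not None:
        mu, sigma = _lognormal_params(*preset.troponin_median_iqr)
        metadata["troponin_ug_l"] = float(np.exp(rng.normal(mu, sigma)))
    mu_d, sd_q1, sd_q3 = preset.days_from_symptoms
    metadata["days_from_symptoms"] = int(max(round(rng.normal(mu_d, (sd_q3 - sd_q1) / 1.349)), 0))

    study = SubjectStudy(subject_id=subject_id, group=preset.name, slices=slices, qc=qc,
                         metadata=metadata)
    truth = SubjectTruth(
        subject_id=subject_id,
        group=preset.name,
        seed=seed,
        lesions=lesion_list,
        injury_masks=injury_masks,
        true_extent_pct=100.0 * total_injured / total_myo,
    )
    return study, truth


def subject_seed(master_seed: int, group: str, k: int) -> int:
    """Counter-based per-subject seed, stable under cohort extension.

    Keyed by (master seed, group, within-group index), so enlarging one group
    never reshuffles the subjects of another.
    """
    ss = np.random.SeedSequence([int(master_seed), GROUPS.index(group), int(k)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def synthesize_cohort(
    group_sizes: Optional[Mapping[str, int]] = None,
    presets: Optional[Mapping[str, GroupPreset]] = None,
    master_seed: int = 0,
    geo: GeometryConfig = GeometryConfig(),
) -> Tuple[List[SubjectStudy], CohortTruth]:
    """Generate a full cohort (default 50 controls, 41/12/7 patients)."""
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    presets = dict(presets or DEFAULT_PRESETS)
    for g, n in group_sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group name {g!r}")
        if n < 0:
            raise ValueError("group sizes must be >= 0")

    studies: List[SubjectStudy] = []
    truths: List[SubjectTruth] = []
    for g in GROUPS:
        n = group_sizes.get(g, 0)
        if n == 0:
            continue
        preset = presets[g]
        n_free = int(round(n * preset.lesion_free_fraction))
        for k in range(n):
            seed = subject_seed(master_seed, g, k)
            lesion_free = k >= n - n_free  # last subjects of the group carry no lesion
            study, truth = synthesize_subject(
                preset, geo, seed,
                subject_id=f"{g}-{k:03d}",
                lesion_free=lesion_free,
            )
            studies.append(study)
            truths.append(truth)
    return studies, CohortTruth(truths)


def calibration_report(
    studies: Sequence[SubjectStudy],
    truth: CohortTruth,
    presets: Optional[Mapping[str, GroupPreset]] = None,
    tolerances: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Realized vs target statistics per group, with pass/fail flags.

    Columns: group, quantity, target, realized, tolerance, ok. Targets come
    from the presets (which in turn encode the published group statistics).
    """
    from .quantify import global_t2_ratio, subject_mean_t1

    presets = dict(presets or DEFAULT_PRESETS)
    tolerances = dict(tolerances or {"mean_t1_ms": 10.0, "t2_ratio": 0.06, "extent_pct": 6.0})

    per_subject = []
    for s in studies:
        per_subject.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "mean_t1": subject_mean_t1(s),
                "t2_ratio": global_t2_ratio(s),
                "true_extent": truth.by_id(s.subject_id).true_extent_pct,
            }
        )
    df = pd.DataFrame(per_subject)

    rows = []
    for g, sub in df.groupby("group"):
        preset = presets[g]
        checks = [
            ("mean_t1_ms", preset.target_mean_t1[0], float(sub.mean_t1.mean())),
            ("mean_t1_sd_ms", preset.target_mean_t1[1], float(sub.mean_t1.std(ddof=1)) if len(sub) > 1 else 0.0),
            ("t2_ratio", preset.target_t2_ratio[0], float(sub.t2_ratio.mean())),
            ("true_extent_pct", preset.target_extent[0], float(sub.true_extent.median())),
        ]
        for quantity, target, realized in checks:
            tol_key = (
                "mean_t1_ms" if quantity.startswith("mean_t1")
                else "extent_pct" if quantity == "true_extent_pct"
                else quantity
            )
            tol = tolerances.get(tol_key, np.inf)
            rows.append(
                {
                    "group": g,
                    "quantity": quantity,
                    "target": target,
                    "realized": realized,
                    "tolerance": tol,
                    "ok": bool(abs(realized - target) <= tol),
                }
            )
    return pd.DataFrame(rows)
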