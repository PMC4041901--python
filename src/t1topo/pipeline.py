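"""End-to-end orchestration: phantom -> detection -> quantification -> diagnostics.

``run_all`` generates (or consumes) a cohort, applies the three tissue
criteria to every subject, quantifies segmental extents, and assembles the
report bundle: per-subject results, a tissue-characteristics summary
(group-wise, with weighted all-patients consistency rows), a
diagnostic-performance table for the single criteria and all printed
combinations, AUCs with DeLong comparisons, the generator calibration report
and a reproducibility manifest (config hash + seeds + versions).

Subject-level decisions: the T1 criterion confirms low-extent subjects on at
least two contiguous slices (the rule used for small focal injury); T2W edema
is positive on a global SI ratio at/above 2.0 or any retained regional
component; LGE is positive on any retained component and is only evaluable
where the subject carries an evaluable LGE study.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__, detection, quantify
from .model import MODALITIES, SubjectStudy, write_study
from .phantom import (
    DEFAULT_GROUP_SIZES,
    DEFAULT_PRESETS,
    CohortTruth,
    GeometryConfig,
    calibration_report,
    synthesize_cohort,
)

logger = logging.getLogger(__name__)

#: printed combination rows: label -> (constituent criteria, k)
TABLE2_COMBINATIONS: Dict[str, Tuple[List[str], int]] = {
    "t2_and_lge": (["t2w", "lge"], 2),
    "t2_or_lge": (["t2w", "lge"], 1),
    "t1_and_lge": (["t1", "lge"], 2),
    "t1_or_lge": (["t1", "lge"], 1),
    "any1_of_t1_t2_lge": (["t1", "t2w", "lge"], 1),
    "any2_of_t1_t2_lge": (["t1", "t2w", "lge"], 2),
    "all3_t1_t2_lge": (["t1", "t2w", "lge"], 3),
    "t1_and_t2": (["t1", "t2w"], 2),
    "t1_or_t2": (["t1", "t2w"], 1),
}


@dataclass
class RunConfig:
    """Pipeline configuration; serializes to/from a single YAML/JSON mapping."""

    group_sizes: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    master_seed: int = 0
    t1_threshold_ms: float = 990.0
    t1_inclusive: bool = True  # ">=" (Table reading); False gives strict ">"
    t2_ratio_cut: float = 2.0
    sd_multiplier: float = 2.0
    min_area_mm2: float = 40.0
    connectivity: int = 8
    confirm_slices: int = 2  # contiguous-slice confirmation for low-extent subjects
    low_extent_cutoff_pct: float = 10.0
    ladder: Tuple[float, ...] = (990.0, 1030.0, 1070.0, 1110.0, 1150.0, 1200.0)
    qc_mode: str = "exclude"  # or "include-all" (artifact re-inclusion analysis)
    lge_evaluable_only: bool = True  # LGE metrics on the evaluable control subset
    out_dir: Optional[str] = None
    write_cohort: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.qc_mode not in ("exclude", "include-all"):
            raise ValueError("qc_mode must be 'exclude' or 'include-all'")
        if self.min_area_mm2 < 0 or self.t1_threshold_ms <= 0:
            raise ValueError("thresholds out of range")

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["ladder"] = list(self.ladder)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "ladder" in d:
            d["ladder"] = tuple(d["ladder"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SubjectResult:
    """Per-subject analysis outputs."""

    subject_id: str
    group: str
    mean_t1: float
    t2_ratio: float
    extents: Dict[str, float]  # modality -> subject extent %
    decisions: Dict[str, Optional[bool]]  # criterion -> decision (None = not evaluable)
    extent_rows: pd.DataFrame
    lesions: Dict[str, detection.LesionMask]


def analyze_subject(study: SubjectStudy, config: RunConfig) -> SubjectResult:
    """Apply all three criteria to one subject and quantify extents."""
    qc_mode = config.qc_mode

    lm_t1 = detection.detect_t1_injury(
        study, threshold_ms=config.t1_threshold_ms, min_area_mm2=config.min_area_mm2,
        connectivity=config.connectivity, inclusive=config.t1_inclusive, qc_mode=qc_mode,
    )
    lm_t2 = detection.detect_t2_edema(
        study, min_area_mm2=config.min_area_mm2, ratio_cut=config.t2_ratio_cut,
        sd_multiplier=config.sd_multiplier, connectivity=config.connectivity, qc_mode=qc_mode,
    )
    lm_lge = detection.detect_lge(
        study, min_area_mm2=config.min_area_mm2, sd_multiplier=config.sd_multiplier,
        connectivity=config.connectivity, qc_mode=qc_mode,
    )

    rows = pd.concat(
        [quantify.segment_extent(study, lm, qc_mode=qc_mode) for lm in (lm_t1, lm_t2, lm_lge)],
        ignore_index=True,
    )
    extents = {
        mod: quantify.subject_extent(rows[rows.modality == mod])
        for mod in MODALITIES
    }

    # T1 decision: low-extent subjects must confirm on contiguous slices
    low_extent = not np.isfinite(extents["T1"]) or extents["T1"] < config.low_extent_cutoff_pct
    confirm = config.confirm_slices if low_extent else 0
    t1_positive = detection.subject_positive(lm_t1, confirm_slices=confirm).positive

    ratio = quantify.global_t2_ratio(study, qc_mode=qc_mode)
    t2_positive = (ratio >= config.t2_ratio_cut) or detection.subject_positive(lm_t2).positive

    lge_evaluable = bool(study.metadata.get("lge_evaluable", True)) or not config.lge_evaluable_only
    lge_positive: Optional[bool] = (
        detection.subject_positive(lm_lge).positive if lge_evaluable else None
    )

    return SubjectResult(
        subject_id=study.subject_id,
        group=study.group,
        mean_t1=quantify.subject_mean_t1(study, qc_mode=qc_mode),
        t2_ratio=ratio,
        extents=extents,
        decisions={"t1": t1_positive, "t2w": t2_positive, "lge": lge_positive},
        extent_rows=rows,
        lesions={"T1": lm_t1, "T2W": lm_t2, "LGE": lm_lge},
    )


def _per_subject_frame(results: Sequence[SubjectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "is_patient": r.group != "control",
                "mean_t1_ms": r.mean_t1,
                "t2_ratio": r.t2_ratio,
                "extent_t1_pct": r.extents["T1"],
                "extent_t2w_pct": r.extents["T2W"],
                "extent_lge_pct": r.extents["LGE"],
                "t1": r.decisions["t1"],
                "t2w": r.decisions["t2w"],
                "lge": r.decisions["lge"],
            }
            for r in results
        ]
    ).set_index("subject_id")


def run_all(
    config: RunConfig,
    studies: Optional[Sequence[SubjectStudy]] = None,
    truth: Optional[CohortTruth] = None,
    geo: GeometryConfig = GeometryConfig(),
) -> Dict[str, object]:
    """Run the full pipeline; returns the report bundle as a dict of tables.

    Keys: ``per_subject``, ``extent``, ``summary``, ``table2``, ``roc``,
    ``calibration`` (when the phantom generated the cohort), ``manifest``.
    Deterministic for a fixed config (seeds included).
    """
    if studies is None:
        studies, truth = synthesize_cohort(
            config.group_sizes, DEFAULT_PRESETS, config.master_seed, geo
        )

    results: List[SubjectResult] = []
    for study in studies:
        try:
            results.append(analyze_subject(study, config))
        except Exception as exc:  # noqa: BLE001 - annotate stage and subject
            raise RuntimeError(
                f"detection/quantification stage failed for subject {study.subject_id}"
            ) from exc

    per_subject = _per_subject_frame(results)
    extent = pd.concat([r.extent_rows for r in results], ignore_index=True)
    truthvec = per_subject["is_patient"]

    summary = quantify.cohort_summary(
        per_subject.reset_index()[
            ["group", "mean_t1_ms", "t2_ratio", "extent_t1_pct", "extent_t2w_pct", "extent_lge_pct"]
        ]
    )

    decisions = per_subject[["t1", "t2w", "lge"]].astype("object")
    n_pat = int(truthvec.sum())
    n_ctl = int((~truthvec).sum())
    if n_pat and n_ctl:
        from .diagnostics import criteria_table, delong_compare, roc_auc

        table2 = criteria_table(decisions, truthvec, TABLE2_COMBINATIONS)
        scores = {
            "t1": per_subject.mean_t1_ms,
            "t2w": per_subject.t2_ratio,
            "lge": per_subject.extent_lge_pct,
        }
        roc_rows = []
        for name, s in scores.items():
            roc_rows.append({"criterion": name, "auc": roc_auc(s, truthvec)})
        roc = pd.DataFrame(roc_rows)
        auc_a, auc_b, z, p = delong_compare(
            per_subject.mean_t1_ms, per_subject.t2_ratio, truthvec
        )
        delong = {"t1_vs_t2w": {"auc_t1": auc_a, "auc_t2w": auc_b, "z": z, "p": p}}
        auc_a, auc_b, z, p = delong_compare(
            per_subject.mean_t1_ms, per_subject.extent_lge_pct, truthvec
        )
        delong["t1_vs_lge"] = {"auc_t1": auc_a, "auc_lge": auc_b, "z": z, "p": p}
    else:
        logger.warning("degenerate cohort (missing patients or controls); "
                       "diagnostic metrics reported missing")
        table2 = pd.DataFrame()
        roc = pd.DataFrame()
        delong = {}

    bundle: Dict[str, object] = {
        "per_subject": per_subject,
        "extent": extent,
        "summary": summary,
        "table2": table2,
        "roc": roc,
        "delong": delong,
        "results": results,
        "manifest": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "t1topo_version": __version__,
            "numpy_version": np.__version__,
        },
    }
    if truth is not None:
        bundle["truth"] = truth
        bundle["calibration"] = calibration_report(studies, truth)

    if config.out_dir:
        _write_bundle(bundle, studies, config)
    return bundle


def _write_bundle(bundle: Dict[str, object], studies: Sequence[SubjectStudy],
                  config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["per_subject"].to_csv(out / "per_subject.csv")
    bundle["extent"].to_csv(out / "extent.csv", index=False)
    bundle["summary"].to_csv(out / "summary.csv", index=False)
    if len(bundle["table2"]):
        bundle["table2"].to_csv(out / "table2.csv", index=False)
    if len(bundle["roc"]):
        bundle["roc"].to_csv(out / "roc.csv", index=False)
    if "calibration" in bundle:
        bundle["calibration"].to_csv(out / "calibration_report.csv", index=False)
        bundle["truth"].to_frame().to_csv(out / "truth.csv", index=False)
    manifest = dict(bundle["manifest"])
    manifest["delong"] = bundle["delong"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    if config.write_cohort:
        for study in studies:
            write_study(study, out / "cohort" / study.subject_id)


def sensitivity_specificity(bundle: Dict[str, object], criterion: str = "t1"
                            ) -> Tuple[float, float]:
    """Convenience accessor for a criterion row of the diagnostics table."""
    t2 = bundle["table2"]
    row = t2[t2.criterion == criterion].iloc[0]
    return float(row.sensitivity), float(row.specificity)
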