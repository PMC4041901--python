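"""Segmental and per-subject quantification of myocardial injury.

The extent of injury for a subject and modality is the percentage of
abnormal myocardium computed per AHA segment and then averaged, unweighted,
over the subject's qc-included segments. Per-subject scalar markers are the
mean myocardial T1 over included myocardium (pixel-level mean) and the global
T2 SI ratio (pooled myocardial mean over pooled skeletal-muscle mean across
slices). Cohort summaries report group-wise mean +/- SD and median (IQR),
plus size-weighted cross-group means for consistency checks of the printed
all-patients column.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detection import LesionMask
from .model import SubjectStudy

logger = logging.getLogger(__name__)

EXTENT_COLUMNS = ("subject_id", "modality", "slice", "segment", "extent_pct", "included")


def segment_extent(
    study: SubjectStudy,
    lesions: LesionMask,
    qc_mode: str = "exclude",
) -> pd.DataFrame:
    """Per-(slice, segment) percentage of abnormal pixels for one modality.

    Rows carry an ``included`` flag mirroring the qc table (all true under
    ``qc_mode='include-all'``); excluded rows never enter aggregates.
    """
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    rows = []
    for sl, mask in zip(study.slices, lesions.slices):
        for seg in sl.geometry.segment_ids:
            seg_mask = sl.geometry.segment_mask(seg)
            n_seg = int(seg_mask.sum())
            if n_seg == 0:
                raise ValueError(f"slice {sl.index} segment {seg} has zero pixels (geometry bug)")
            pct = 100.0 * int((mask & seg_mask).sum()) / n_seg
            rows.append(
                (study.subject_id, lesions.modality, sl.index, seg, pct,
                 qc.is_included(sl.index, seg, lesions.modality))
            )
    return pd.DataFrame(rows, columns=list(EXTENT_COLUMNS))


def subject_extent(rows: pd.DataFrame) -> float:
    """Unweighted mean of included segment percentages; NaN if none included."""
    included = rows[rows.included]
    if len(included) == 0:
        logger.warning("all segments excluded; subject extent is missing")
        return float("nan")
    return float(included.extent_pct.mean())


def subject_mean_t1(study: SubjectStudy, qc_mode: str = "exclude",
                    per_segment: bool = False) -> float:
    """Mean myocardial T1 (ms) over qc-included myocardium across slices.

    Default is a pixel-level mean; ``per_segment=True`` averages segment means
    instead.
    """
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    if per_segment:
        means = [
            study.slices[k].maps["T1"].pixels[sl.geometry.segment_mask(seg)].mean()
            for k, sl in enumerate(study.slices)
            for seg in sl.geometry.segment_ids
            if qc.is_included(sl.index, seg, "T1")
        ]
        if not means:
            raise ValueError("no qc-included myocardial segments on the T1 maps")
        return float(np.mean(means))
    vals = []
    for sl in study.slices:
        mask = qc.included_mask(sl, "T1")
        if mask.any():
            vals.append(sl.maps["T1"].pixels[mask])
    if not vals:
        raise ValueError("no qc-included myocardial pixels on the T1 maps")
    return float(np.concatenate(vals).mean())


def global_t2_ratio(study: SubjectStudy, qc_mode: str = "exclude") -> float:
    """Global myocardial T2 SI ratio: pooled myocardial mean / pooled muscle mean."""
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    myo_vals, muscle_vals = [], []
    for sl in study.slices:
        px = sl.maps["T2W"].pixels
        mask = qc.included_mask(sl, "T2W")
        if mask.any():
            myo_vals.append(px[mask])
        if sl.geometry.muscle_mask.any():
            muscle_vals.append(px[sl.geometry.muscle_mask])
    if not muscle_vals:
        raise ValueError("no skeletal-muscle pixels in the study")
    if not myo_vals:
        raise ValueError("no qc-included myocardial pixels on the T2W maps")
    return float(np.concatenate(myo_vals).mean() / np.concatenate(muscle_vals).mean())


def size_weighted_mean(means: Sequence[float], sizes: Sequence[int]) -> float:
    """Size-weighted average of subgroup means (printed-table consistency)."""
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if means.shape != sizes.shape or sizes.sum() <= 0:
        raise ValueError("means and sizes must align and sizes must sum > 0")
    return float((means * sizes).sum() / sizes.sum())


def cohort_summary(per_subject: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Group-wise summary of per-subject quantities.

    ``per_subject`` holds one row per subject with a ``group`` column plus
    numeric columns. For each numeric column the summary reports n, mean, sd,
    median, q1, q3 per group, and a ``weighted_mean`` row over the patient
    groups (I, II, III) for consistency checks against a printed all-patients
    column.
    """
    numeric = [c for c in per_subject.columns if c != group_col
               and pd.api.types.is_numeric_dtype(per_subject[c])]
    rows = []
    for g, sub in per_subject.groupby(group_col):
        if len(sub) == 0:
            logger.warning("empty group %s omitted from summary", g)
            continue
        for col in numeric:
            vals = sub[col].dropna()
            rows.append({
                "group": g, "quantity": col, "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "median": float(vals.median()) if len(vals) else np.nan,
                "q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
            })
    summary = pd.DataFrame(rows)

    patients = summary[summary.group.isin(["I", "II", "III"])]
    for col in numeric:
        sub = patients[patients.quantity == col]
        if len(sub) and sub.n.sum() > 0:
            rows.append({
                "group": "all-patients(weighted)", "quantity": col,
                "n": int(sub.n.sum()),
                "mean": size_weighted_mean(sub["mean"].to_list(), sub.n.to_list()),
                "sd": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan,
            })
    return pd.DataFrame(rows)
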