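"""Threshold-based tissue-characterization criteria with area filtering.

Three detection criteria operate on qc-included myocardium:

- native T1: pixels with T1 at or above 990 ms (comparison operator
  configurable to strict ``>``, matching both printed readings of the cut);
- dark-blood T2W edema: pixel SI / slice skeletal-muscle mean >= 2.0, or
  pixel SI >= remote mean + 2.0 x remote SD;
- LGE: pixel SI >= remote mean + 2.0 x remote SD.

Candidate pixels only count as abnormal within a contiguous component of at
least 40 mm^2 (in-plane, 8-connected by default), which suppresses noise
speckle. The remote reference is chosen algorithmically as a surrogate for
the expert's "least affected" region: among qc-included segments free of LGE,
drop abnormally dark segments, then take the one with the lowest mean SI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .model import HeartGeometry, ParametricMap, StudySlice, SubjectStudy

logger = logging.getLogger(__name__)

T1_THRESHOLD_MS = 990.0
T2_RATIO_CUT = 2.0
SD_MULTIPLIER = 2.0
MIN_AREA_MM2 = 40.0


class NoRemoteReferenceError(RuntimeError):
    """No qc-included, LGE-free, non-dark segment is available as a reference."""


@dataclass(frozen=True)
class Component:
    """One retained connected component of a lesion mask."""

    id: int
    slice_index: int
    n_pixels: int
    area_mm2: float
    centroid: Tuple[float, float]


@dataclass
class LesionMask:
    """Thresholded, area-filtered binary injury map for one subject/modality."""

    modality: str
    threshold: str  # human-readable descriptor, e.g. "T1>=990ms"
    min_area_mm2: float
    slices: List[np.ndarray]  # boolean grid per slice
    components: List[Component] = field(default_factory=list)

    @property
    def n_abnormal_pixels(self) -> int:
        return int(sum(m.sum() for m in self.slices))

    def slices_with_components(self) -> List[int]:
        return sorted({c.slice_index for c in self.components})

    def is_empty(self) -> bool:
        return not self.components


@dataclass(frozen=True)
class RemoteROI:
    """Reference region statistics for the 2-SD criteria on one slice."""

    slice_index: int
    segment_ids: Tuple[int, ...]
    mean: float
    sd: float
    modality: str


@dataclass(frozen=True)
class CriterionResult:
    """Subject-level decision for one modality."""

    modality: str
    positive: bool
    rule: str
    component_slices: Tuple[int, ...]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def filter_contiguous(
    mask: np.ndarray,
    pixel_spacing: Tuple[float, float],
    min_area_mm2: float = MIN_AREA_MM2,
    connectivity: int = 8,
    slice_index: int = 0,
) -> Tuple[np.ndarray, List[Component]]:
    """Retain only connected components covering at least ``min_area_mm2``.

    The component inventory of the retained set is returned alongside the
    filtered mask. The operation never adds pixels and is idempotent.
    """
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    pixel_area = pixel_spacing[0] * pixel_spacing[1]
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    out = np.zeros_like(mask)
    components: List[Component] = []
    if n == 0:
        return out, components
    counts = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    cid = 0
    for lab in range(1, n + 1):
        area = counts[lab] * pixel_area
        if area >= min_area_mm2:
            cid += 1
            out |= labels == lab
            components.append(
                Component(
                    id=cid,
                    slice_index=slice_index,
                    n_pixels=int(counts[lab]),
                    area_mm2=float(area),
                    centroid=tuple(float(c) for c in centroids[lab - 1]),
                )
            )
    return out, components


def _assemble(
    modality: str,
    threshold: str,
    min_area_mm2: float,
    candidates: Sequence[np.ndarray],
    spacing: Tuple[float, float],
    connectivity: int,
) -> LesionMask:
    slices: List[np.ndarray] = []
    components: List[Component] = []
    for k, cand in enumerate(candidates):
        filtered, comps = filter_contiguous(cand, spacing, min_area_mm2, connectivity, slice_index=k)
        slices.append(filtered)
        components.extend(comps)
    # re-number across slices
    components = [replace(c, id=i + 1) for i, c in enumerate(components)]
    return LesionMask(modality, threshold, min_area_mm2, slices, components)


def detect_t1_injury(
    study: SubjectStudy,
    threshold_ms: float = T1_THRESHOLD_MS,
    min_area_mm2: float = MIN_AREA_MM2,
    connectivity: int = 8,
    inclusive: bool = True,
    qc_mode: str = "exclude",
) -> LesionMask:
    """T1 injury mask: myocardial pixels at/above ``threshold_ms``, area-filtered.

    ``inclusive`` selects ``>=`` (default) vs strict ``>``; qc-excluded
    segments are removed from the searchable myocardium unless
    ``qc_mode='include-all'``.
    """
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    candidates = []
    for sl in study.slices:
        pm = sl.maps["T1"]
        if pm.modality != "T1":
            raise ValueError("detect_t1_injury requires a T1 map")
        searchable = qc.included_mask(sl, "T1")
        hot = pm.pixels >= threshold_ms if inclusive else pm.pixels > threshold_ms
        candidates.append(hot & searchable)
    op = ">=" if inclusive else ">"
    return _assemble("T1", f"T1{op}{threshold_ms:g}ms", min_area_mm2,
                     candidates, study.spacing("T1"), connectivity)


def compute_t2_ratio(
    t2_pixels: np.ndarray,
    myo_subset: np.ndarray,
    muscle_mask: np.ndarray,
) -> float:
    """Mean myocardial SI over ``myo_subset`` divided by mean skeletal-muscle SI."""
    if not muscle_mask.any():
        raise ValueError("empty skeletal-muscle mask")
    if not myo_subset.any():
        raise ValueError("empty myocardial subset")
    return float(t2_pixels[myo_subset].mean() / t2_pixels[muscle_mask].mean())


def select_remote_roi(
    sl: StudySlice,
    modality: str,
    qc,
    prior_lge: Optional[np.ndarray] = None,
    dark_sd_multiplier: float = 2.0,
) -> RemoteROI:
    """Algorithmic surrogate for the expert remote-reference choice.

    Among qc-included segments with no overlap with the (prior) LGE mask,
    segments whose mean SI falls below the slice myocardial median minus
    ``dark_sd_multiplier`` robust SDs are excluded as abnormally dark; of the
    rest the segment with the lowest mean SI is chosen, ties broken by lowest
    segment id.
    """
    pixels = sl.maps[modality].pixels
    geometry = sl.geometry
    myo_vals = pixels[geometry.myo_mask]
    med = float(np.median(myo_vals))
    robust_sd = 1.4826 * float(np.median(np.abs(myo_vals - med)))
    dark_cut = med - dark_sd_multiplier * robust_sd

    candidates = []
    for seg in geometry.segment_ids:
        if not qc.is_included(sl.index, seg, modality):
            continue
        seg_mask = geometry.segment_mask(seg)
        if prior_lge is not None and (seg_mask & prior_lge).any():
            continue
        mean = float(pixels[seg_mask].mean())
        if mean < dark_cut:
            continue
        candidates.append((mean, seg))
    if not candidates:
        raise NoRemoteReferenceError(
            f"slice {sl.index}: no eligible remote reference segment for {modality}"
        )
    mean, seg = min(candidates)  # lowest mean, ties -> lowest segment id
    seg_mask = geometry.segment_mask(seg)
    roi = RemoteROI(
        slice_index=sl.index,
        segment_ids=(seg,),
        mean=mean,
        sd=float(pixels[seg_mask].std(ddof=0)),
        modality=modality,
    )
    logger.debug("remote ROI %s slice %d: segment %d mean %.1f sd %.1f",
                 modality, sl.index, seg, roi.mean, roi.sd)
    return roi


def detect_t2_edema(
    study: SubjectStudy,
    remotes: Optional[Sequence[Optional[RemoteROI]]] = None,
    min_area_mm2: float = MIN_AREA_MM2,
    ratio_cut: float = T2_RATIO_CUT,
    sd_multiplier: float = SD_MULTIPLIER,
    connectivity: int = 8,
    qc_mode: str = "exclude",
) -> LesionMask:
    """Edema mask on the T2W images.

    A pixel is a candidate when its SI over the slice skeletal-muscle mean
    reaches ``ratio_cut``, or when it reaches remote mean + ``sd_multiplier``
    x remote SD. A missing remote for a slice degrades that slice to the
    ratio-only branch (logged); a zero remote SD degenerates the SD branch to
    a mean comparison (warned).
    """
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    if remotes is None:
        remotes = default_remotes(study, "T2W", qc)
    candidates = []
    for sl, remote in zip(study.slices, remotes):
        pm = sl.maps["T2W"]
        searchable = qc.included_mask(sl, "T2W")
        muscle = sl.geometry.muscle_mask
        if not muscle.any():
            raise ValueError(f"slice {sl.index}: empty skeletal-muscle mask")
        muscle_mean = pm.pixels[muscle].mean()
        cand = (pm.pixels / muscle_mean >= ratio_cut)
        if remote is not None:
            if remote.sd == 0:
                if np.ptp(pm.pixels[searchable]) > 0:
                    logger.warning("slice %d: remote SD is zero; SD criterion degenerates "
                                   "to a mean comparison", sl.index)
                # strict comparison so a perfectly uniform slice stays negative
                cand = cand | (pm.pixels > remote.mean)
            else:
                cand = cand | (pm.pixels >= remote.mean + sd_multiplier * remote.sd)
        else:
            logger.info("slice %d: no remote reference; T2 criterion uses the "
                        "ratio-only branch", sl.index)
        candidates.append(cand & searchable)
    return _assemble("T2W", f"T2ratio>={ratio_cut:g}|remote+{sd_multiplier:g}SD",
                     min_area_mm2, candidates, study.spacing("T2W"), connectivity)


def detect_lge(
    study: SubjectStudy,
    remotes: Optional[Sequence[Optional[RemoteROI]]] = None,
    min_area_mm2: float = MIN_AREA_MM2,
    sd_multiplier: float = SD_MULTIPLIER,
    connectivity: int = 8,
    qc_mode: str = "exclude",
) -> LesionMask:
    """LGE mask: SI at/above remote mean + ``sd_multiplier`` x remote SD."""
    qc = study.qc if qc_mode == "exclude" else study.qc.with_all_included()
    if remotes is None:
        remotes = _lge_remotes_two_pass(study, qc, min_area_mm2, sd_multiplier, connectivity)
    candidates = []
    for sl, remote in zip(study.slices, remotes):
        pm = sl.maps["LGE"]
        searchable = qc.included_mask(sl, "LGE")
        if remote is None:
            logger.info("slice %d: no remote reference for LGE; slice skipped", sl.index)
            candidates.append(np.zeros_like(searchable))
            continue
        if remote.sd == 0:
            cand = pm.pixels > remote.mean  # strict: uniform nulled myocardium stays negative
        else:
            cand = pm.pixels >= remote.mean + sd_multiplier * remote.sd
        candidates.append(cand & searchable)
    return _assemble("LGE", f"LGE>=remote+{sd_multiplier:g}SD", min_area_mm2,
                     candidates, study.spacing("LGE"), connectivity)


def default_remotes(
    study: SubjectStudy,
    modality: str,
    qc=None,
    prior_lge_slices: Optional[Sequence[np.ndarray]] = None,
) -> List[Optional[RemoteROI]]:
    """Per-slice remote references, ``None`` where no segment is eligible."""
    qc = qc if qc is not None else study.qc
    out: List[Optional[RemoteROI]] = []
    for k, sl in enumerate(study.slices):
        prior = prior_lge_slices[k] if prior_lge_slices is not None else None
        try:
            out.append(select_remote_roi(sl, modality, qc, prior_lge=prior))
        except NoRemoteReferenceError:
            out.append(None)
    return out


def _lge_remotes_two_pass(study, qc, min_area_mm2, sd_multiplier, connectivity):
    """First pass with no LGE prior; second pass excludes detected LGE segments."""
    first = default_remotes(study, "LGE", qc)
    pass1 = detect_lge(study, remotes=first, min_area_mm2=min_area_mm2,
                       sd_multiplier=sd_multiplier, connectivity=connectivity,
                       qc_mode="exclude" if qc is study.qc else "include-all")
    return default_remotes(study, "LGE", qc, prior_lge_slices=pass1.slices)


def subject_positive(
    lesions: LesionMask,
    confirm_slices: int = 0,
    confirm_planes: int = 0,
) -> CriterionResult:
    """Subject-level positivity for one modality.

    Default rule: positive when any retained component exists. With
    ``confirm_slices=2``, retained components must appear on at least two
    contiguous slices. Orthogonal-plane confirmation is not supported on
    short-axis-only studies.
    """
    if confirm_planes:
        raise NotImplementedError("orthogonal-plane confirmation is unsupported "
                                  "(short-axis-only studies)")
    if not lesions.slices:
        raise ValueError("empty study: lesion mask holds no slices")
    present = lesions.slices_with_components()
    if confirm_slices >= 2:
        run = best = 1 if present else 0
        for a, b in zip(present, present[1:]):
            run = run + 1 if b - a == 1 else 1
            best = max(best, run)
        ok = best >= confirm_slices
        rule = f"components on >= {confirm_slices} contiguous slices"
    else:
        ok = bool(present)
        rule = "any retained component"
    return CriterionResult(
        modality=lesions.modality,
        positive=ok,
        rule=rule,
        component_slices=tuple(present),
    )
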