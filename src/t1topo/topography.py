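"""Incremental-threshold topographic maps and lesion pattern classification.

Applying a strictly increasing ladder of T1 thresholds (anchored at the
validated 990 ms) to the same map yields a nested family of area-filtered
lesion masks: the lower thresholds show the full footprint of injury, the
higher ones isolate the hottest core, typically a lateral-wall subepicardial
or midwall sector — the non-ischemic pattern. Each retained component is
classified by transmural layer (subendocardial / midwall / subepicardial
terciles of wall depth) and by the LV walls it involves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detection import Component, LesionMask, detect_t1_injury
from .model import SEGMENT_WALLS, WALL_NAMES, HeartGeometry, SubjectStudy

#: default ladder: anchored at the validated 990 ms and the illustrative
#: 1200 ms; intermediate steps evenly spaced, presentation-only.
DEFAULT_LADDER = (990.0, 1030.0, 1070.0, 1110.0, 1150.0, 1200.0)

LAYERS = ("subendocardial", "midwall", "subepicardial")


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly increasing list of at least two T1 thresholds (ms)."""

    thresholds: Tuple[float, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if len(t) < 2:
            raise ValueError("ladder needs at least two thresholds")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"ladder must be strictly increasing, got {t}")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class PatternEntry:
    """Layer/wall classification of one lesion component."""

    component_id: int
    slice_index: int
    layer_fractions: Dict[str, float]
    wall_pixels: Dict[str, int]
    dominant_layer: str
    dominant_wall: str
    subendocardial_only: bool  # ischemic-pattern suspicion flag


def incremental_masks(
    study: SubjectStudy,
    ladder: ThresholdLadder = ThresholdLadder(),
    min_area_mm2: float = 40.0,
    connectivity: int = 8,
    qc_mode: str = "exclude",
) -> List[LesionMask]:
    """One area-filtered T1 lesion mask per ladder threshold, nested."""
    masks = [
        detect_t1_injury(study, threshold_ms=t, min_area_mm2=min_area_mm2,
                         connectivity=connectivity, qc_mode=qc_mode)
        for t in ladder
    ]
    for lo, hi in zip(masks, masks[1:]):
        for a, b in zip(lo.slices, hi.slices):
            if np.any(b & ~a):
                raise AssertionError("ladder nesting violated after area filtering")
    return masks


def classify_pattern(
    component_mask: np.ndarray,
    geometry: HeartGeometry,
    component: Optional[Component] = None,
) -> PatternEntry:
    """Classify one component by transmural layer terciles and wall involvement.

    Layer fractions partition the component at transmural depths 1/3 and 2/3;
    the dominant layer is the argmax, ties resolved toward the more
    epicardial layer. A component confined to the subendocardial tercile is
    flagged as an ischemic-pattern suspect.
    """
    inside = component_mask & geometry.myo_mask
    n = int(inside.sum())
    if n == 0:
        raise ValueError("empty component")
    tm = geometry.transmural[inside]
    fractions = {
        "subendocardial": float((tm < 1.0 / 3.0).sum() / n),
        "midwall": float(((tm >= 1.0 / 3.0) & (tm < 2.0 / 3.0)).sum() / n),
        "subepicardial": float((tm >= 2.0 / 3.0).sum() / n),
    }
    # argmax with ties toward the more epicardial layer
    dominant_layer = max(LAYERS, key=lambda l: (fractions[l], LAYERS.index(l)))

    wall_pixels: Dict[str, int] = {}
    segs = geometry.segments[inside]
    for seg in np.unique(segs):
        wall = SEGMENT_WALLS[int(seg)]
        wall_pixels[wall] = wall_pixels.get(wall, 0) + int((segs == seg).sum())
    dominant_wall = max(WALL_NAMES, key=lambda w: (wall_pixels.get(w, 0), -WALL_NAMES.index(w)))

    return PatternEntry(
        component_id=component.id if component else 0,
        slice_index=component.slice_index if component else -1,
        layer_fractions=fractions,
        wall_pixels=wall_pixels,
        dominant_layer=dominant_layer,
        dominant_wall=dominant_wall,
        subendocardial_only=fractions["subendocardial"] >= 1.0 - 1e-12,
    )


def pattern_report(study: SubjectStudy, lesions: LesionMask) -> pd.DataFrame:
    """Classify every retained component of a subject's lesion mask."""
    from scipy import ndimage

    rows = []
    for sl, mask in zip(study.slices, lesions.slices):
        labels, nlab = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
        for lab in range(1, nlab + 1):
            comp_mask = labels == lab
            comp = next(
                (c for c in lesions.components
                 if c.slice_index == sl.index
                 and comp_mask[int(round(c.centroid[0])), int(round(c.centroid[1]))]),
                None,
            )
            entry = classify_pattern(comp_mask, sl.geometry, comp)
            rows.append({
                "subject_id": study.subject_id,
                "slice": sl.index,
                "component_id": entry.component_id,
                "n_pixels": int(comp_mask.sum()),
                **{f"frac_{l}": entry.layer_fractions[l] for l in LAYERS},
                "dominant_layer": entry.dominant_layer,
                "dominant_wall": entry.dominant_wall,
                "subendocardial_only": entry.subendocardial_only,
                "walls": ";".join(sorted(entry.wall_pixels)),
            })
    return pd.DataFrame(rows)


def overlay_array(
    pixels: np.ndarray,
    lesion_mask: np.ndarray,
    reference_mask: Optional[np.ndarray] = None,
    window: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """RGB overlay: grayscale base, red lesion pixels, green reference contour.

    Returns a uint8 HxWx3 array; deterministic for fixed inputs.
    """
    if lesion_mask.shape != pixels.shape:
        raise ValueError("lesion mask and image shapes differ")
    lo, hi = window if window else (float(pixels.min()), float(pixels.max()))
    if hi <= lo:
        hi = lo + 1.0
    gray = np.clip((pixels - lo) / (hi - lo), 0, 1)
    rgb = np.repeat((gray[..., None] * 255).astype(np.uint8), 3, axis=2)
    rgb[lesion_mask] = (255, 0, 0)
    if reference_mask is not None:
        if reference_mask.shape != pixels.shape:
            raise ValueError("reference mask and image shapes differ")
        from scipy import ndimage
        contour = reference_mask & ~ndimage.binary_erosion(reference_mask)
        rgb[contour] = (0, 255, 0)
    return rgb


def render_overlay(
    pixels: np.ndarray,
    lesion_mask: np.ndarray,
    out_path: Path | str,
    reference_mask: Optional[np.ndarray] = None,
    title: str = "",
    window: Optional[Tuple[float, float]] = None,
) -> Path:
    """Write one annotated overlay panel as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = overlay_array(pixels, lesion_mask, reference_mask, window)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=10)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, bbox_inches="tight", metadata={"Software": "t1topo"})
    plt.close(fig)
    return out_path


def render_ladder(
    study: SubjectStudy,
    ladder: ThresholdLadder,
    slice_index: int,
    out_dir: Path | str,
    qc_mode: str = "exclude",
    min_area_mm2: float = 40.0,
    reference_mask: Optional[np.ndarray] = None,
) -> List[Path]:
    """One overlay panel per ladder threshold for a chosen slice."""
    out_dir = Path(out_dir)
    masks = incremental_masks(study, ladder, min_area_mm2=min_area_mm2, qc_mode=qc_mode)
    pixels = study.slices[slice_index].maps["T1"].pixels
    paths = []
    for t, lm in zip(ladder, masks):
        path = out_dir / f"{study.subject_id}_slice{slice_index}_t1ge{int(t)}.png"
        render_overlay(pixels, lm.slices[slice_index], path,
                       reference_mask=reference_mask,
                       title=f"T1 >= {t:g} ms", window=(600.0, 1400.0))
        paths.append(path)
    return paths
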