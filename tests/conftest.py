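"""Shared fixtures: compact geometries, zero-noise presets, a small cohort."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from t1topo import detection, model, phantom, pipeline
from t1topo.model import MODALITIES, ParametricMap, QCTable, StudySlice, SubjectStudy
from t1topo.phantom import (
    CONTROL_PRESET,
    GROUP_I_PRESET,
    GeometryConfig,
    LesionSpec,
    synthesize_cohort,
    synthesize_subject,
)

NO_NOISE = {"T1": 0.0, "T2W": 0.0, "LGE": 0.0}
NO_QC = {"T1": 0.0, "T2W": 0.0, "LGE": 0.0}


@pytest.fixture(scope="session")
def small_geo() -> GeometryConfig:
    """64x64 grid, 5 slices: fast to generate, still a realistic ring."""
    return GeometryConfig(
        grid=64,
        pixel_spacing=(1.5, 1.5),
        n_slices=5,
        center=(32.0, 32.0),
        epi_radius_mm=28.0,
        wall_thickness_mm=9.0,
        muscle_rows=(52, 60),
        muscle_cols=(16, 48),
    )


@pytest.fixture(scope="session")
def clean_control_preset():
    """Control preset with zero noise and no qc exclusions."""
    return dataclasses.replace(CONTROL_PRESET, noise_sd=NO_NOISE, qc_exclusion=NO_QC)


@pytest.fixture(scope="session")
def clean_patient_preset():
    """Patient-like preset with zero noise/qc, for explicit-lesion constructions."""
    return dataclasses.replace(
        GROUP_I_PRESET, noise_sd=NO_NOISE, qc_exclusion=NO_QC, mild_fraction=0.0
    )


@pytest.fixture(scope="session")
def lateral_lesion() -> LesionSpec:
    """Subepicardial lateral-wall lesion spanning three contiguous slices."""
    return LesionSpec(
        slices=(1, 2, 3), center_angle_deg=270.0, width_deg=80.0,
        band=(0.6, 1.0), d_t1=150.0, d_t2=0.4, lge=True,
    )


@pytest.fixture(scope="session")
def clean_lesion_subject(clean_patient_preset, small_geo, lateral_lesion):
    """Zero-noise subject with one known lesion, plus its ground truth."""
    return synthesize_subject(
        clean_patient_preset, small_geo, seed=5, lesions=[lateral_lesion]
    )


@pytest.fixture(scope="session")
def noisy_subject(small_geo):
    """One default-noise Group-I-like subject on the small grid."""
    return synthesize_subject(GROUP_I_PRESET, small_geo, seed=17)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down default cohort (full-size grid) for cohort-level tests."""
    return synthesize_cohort(
        {"control": 6, "I": 8, "II": 3, "III": 2}, master_seed=42
    )


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    """Full pipeline output on the scaled-down cohort."""
    studies, truth = small_cohort
    config = pipeline.RunConfig(
        group_sizes={"control": 6, "I": 8, "II": 3, "III": 2}, master_seed=42
    )
    return pipeline.run_all(config, studies=studies, truth=truth)


def make_study(
    geo: GeometryConfig,
    t1_value: float = 946.0,
    t2_myo: float = 312.0,
    t2_muscle: float = 200.0,
    lge_value: float = 20.0,
    group: str = "control",
) -> SubjectStudy:
    """Hand-built uniform study for constructed detection examples."""
    muscle = geo.muscle_mask()
    slices = []
    for k in range(geo.n_slices):
        geometry = model.build_ring_geometry(
            (geo.grid, geo.grid), geo.center, geo.endo_radius_mm, geo.epi_radius_mm,
            geo.pixel_spacing, model.slice_position(k, geo.n_slices), muscle_mask=muscle,
        )
        t1 = np.full((geo.grid, geo.grid), 350.0)
        t1[geometry.myo_mask] = t1_value
        t2 = np.full((geo.grid, geo.grid), 0.25 * t2_muscle)
        t2[muscle] = t2_muscle
        t2[geometry.myo_mask] = t2_myo
        lge = np.full((geo.grid, geo.grid), 10.0)
        lge[muscle] = 25.0
        lge[geometry.myo_mask] = lge_value
        maps = {
            "T1": ParametricMap(t1, geo.pixel_spacing, k, geo.slice_thickness, "T1"),
            "T2W": ParametricMap(t2, geo.pixel_spacing, k, geo.slice_thickness, "T2W"),
            "LGE": ParametricMap(lge, geo.pixel_spacing, k, geo.slice_thickness, "LGE"),
        }
        slices.append(StudySlice(index=k, maps=maps, geometry=geometry))
    return SubjectStudy(
        subject_id="constructed", group=group, slices=slices,
        qc=QCTable.all_included(slices),
    )
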