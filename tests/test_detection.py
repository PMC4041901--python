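"""Detection criteria: area filter vs flood-fill oracle, thresholds, remote ROI."""

import dataclasses

import numpy as np
import pytest

from t1topo import detection
from t1topo.detection import (
    NoRemoteReferenceError,
    RemoteROI,
    compute_t2_ratio,
    detect_lge,
    detect_t1_injury,
    detect_t2_edema,
    filter_contiguous,
    select_remote_roi,
    subject_positive,
)
from t1topo.phantom import LesionSpec, synthesize_subject

from conftest import make_study
from oracles import filter_components_oracle


def _component_set(mask, filtered_mask, connectivity):
    from oracles import flood_fill_components

    return frozenset(frozenset(c) for c in flood_fill_components(filtered_mask, connectivity))


class TestFilterContiguous:
    def test_empty_mask_stays_empty(self):
        out, comps = filter_contiguous(np.zeros((32, 32), bool), (2.0, 2.0), 40.0)
        assert not out.any() and comps == []

    def test_ten_pixels_at_stir_spacing_retained_nine_removed(self):
        """At 2.0 x 2.0 mm the 40 mm^2 rule corresponds to 10 adjacent pixels."""
        mask = np.zeros((32, 32), bool)
        mask[5, 2:12] = True  # 10-pixel line = 40 mm^2
        mask[20, 2:11] = True  # 9-pixel line = 36 mm^2
        out, comps = filter_contiguous(mask, (2.0, 2.0), 40.0)
        assert out[5, 2:12].all() and not out[20].any()
        assert len(comps) == 1 and comps[0].n_pixels == 10
        assert comps[0].area_mm2 == pytest.approx(40.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            mask = rng.random((64, 64)) < rng.uniform(0.15, 0.5)
            out, comps = filter_contiguous(mask, (1.5, 1.5), 40.0, connectivity)
            expected = filter_components_oracle(mask, (1.5, 1.5), 40.0, connectivity)
            assert _component_set(mask, out, connectivity) == expected
            assert sum(c.n_pixels for c in comps) == int(out.sum())

    def test_contraction_and_idempotence(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            mask = rng.random((48, 48)) < 0.35
            once, _ = filter_contiguous(mask, (1.0, 1.0), 20.0)
            twice, _ = filter_contiguous(once, (1.0, 1.0), 20.0)
            assert not np.any(once & ~mask)  # never adds pixels
            assert np.array_equal(once, twice)

    def test_eight_connectivity_retains_at_least_four(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            mask = rng.random((48, 48)) < 0.3
            out4, _ = filter_contiguous(mask, (1.0, 1.0), 15.0, connectivity=4)
            out8, _ = filter_contiguous(mask, (1.0, 1.0), 15.0, connectivity=8)
            assert not np.any(out4 & ~out8)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            filter_contiguous(np.zeros((20, 20), bool), (1.0, 1.0), -1.0)


class TestT1Criterion:
    def test_uniform_normal_map_yields_empty_mask(self, small_geo):
        study = make_study(small_geo, t1_value=946.0)
        assert detect_t1_injury(study).is_empty()

    def test_threshold_nesting(self, noisy_subject):
        study, _ = noisy_subject
        low = detect_t1_injury(study, threshold_ms=990.0)
        high = detect_t1_injury(study, threshold_ms=1200.0)
        for a, b in zip(low.slices, high.slices):
            assert not np.any(b & ~a)

    def test_zero_noise_lesion_recovered_exactly(self, clean_lesion_subject):
        study, truth = clean_lesion_subject
        lm = detect_t1_injury(study)
        det = np.stack(lm.slices)
        tru = np.stack(truth.injury_masks)
        assert np.array_equal(det, tru)  # Dice overlap 1.0

    def test_noisy_recovery_dice_above_080(self, small_geo):
        """Default pixel noise: Dice >= 0.8 for a 100 ms, >= 80 mm^2 lesion.

        Normal baseline isolates lesion recovery from global T1 elevation.
        """
        from t1topo.phantom import CONTROL_PRESET

        from conftest import NO_QC

        preset = dataclasses.replace(CONTROL_PRESET, qc_exclusion=NO_QC)
        spec = LesionSpec(slices=(1, 2, 3), center_angle_deg=270.0, width_deg=80.0,
                          band=(0.5, 1.0), d_t1=100.0, d_t2=0.0, lge=False)
        study, truth = synthesize_subject(preset, small_geo, seed=29, lesions=[spec])
        lm = detect_t1_injury(study)
        det = np.stack(lm.slices)
        tru = np.stack(truth.injury_masks)
        dice = 2 * (det & tru).sum() / (det.sum() + tru.sum())
        assert dice >= 0.8

    def test_inclusive_flag_controls_boundary(self, small_geo):
        study = make_study(small_geo, t1_value=990.0)
        assert not detect_t1_injury(study, inclusive=True).is_empty()
        assert detect_t1_injury(study, inclusive=False).is_empty()


class TestT2Ratio:
    def test_equal_signal_gives_ratio_one(self):
        px = np.full((32, 32), 100.0)
        myo = np.zeros((32, 32), bool)
        myo[5:10, 5:10] = True
        muscle = np.zeros((32, 32), bool)
        muscle[20:25, 5:10] = True
        assert compute_t2_ratio(px, myo, muscle) == pytest.approx(1.0)

    def test_constructed_arithmetic(self):
        px = np.zeros((32, 32))
        myo = np.zeros((32, 32), bool)
        myo[2:6, 2:6] = True
        muscle = np.zeros((32, 32), bool)
        muscle[20:24, 2:6] = True
        px[myo] = 312.0
        px[muscle] = 200.0
        assert compute_t2_ratio(px, myo, muscle) == pytest.approx(1.56)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(50, 400, (32, 32))
        myo = np.zeros((32, 32), bool)
        myo[4:12, 4:12] = True
        muscle = np.zeros((32, 32), bool)
        muscle[20:28, 4:12] = True
        assert compute_t2_ratio(2 * px, myo, muscle) == pytest.approx(
            compute_t2_ratio(px, myo, muscle)
        )

    def test_empty_muscle_mask_rejected(self):
        with pytest.raises(ValueError, match="muscle"):
            compute_t2_ratio(np.ones((32, 32)), np.ones((32, 32), bool),
                             np.zeros((32, 32), bool))


class TestT2Edema:
    def test_uniform_myocardium_below_cut_is_negative(self, small_geo):
        study = make_study(small_geo, t2_myo=312.0, t2_muscle=200.0)  # ratio 1.56
        assert detect_t2_edema(study).is_empty()

    def test_two_sd_branch_detects_moderate_elevation(self, small_geo):
        study = make_study(small_geo, t2_myo=200.0, t2_muscle=200.0)
        sl = study.slices[2]
        px = sl.maps["T2W"].pixels
        region = sl.geometry.segment_mask(11)  # inferolateral mid segment
        px[region] = 225.0  # remote mean 200, SD 10 -> threshold 220
        remotes = [
            RemoteROI(k, (1,), 200.0, 10.0, "T2W") for k in range(study.n_slices)
        ]
        lm = detect_t2_edema(study, remotes=remotes)
        assert lm.slices[2][region].all()
        assert not any(lm.slices[k].any() for k in (0, 1, 3, 4))

    def test_phantom_group_i_extent_exceeds_control(self, small_bundle):
        ps = small_bundle["per_subject"]
        assert ps.query("group == 'I'").extent_t2w_pct.median() > 0.0
        assert ps.query("group == 'control'").extent_t2w_pct.max() == pytest.approx(0.0)


class TestLge:
    def test_two_sd_rule_on_constructed_values(self, small_geo):
        study = make_study(small_geo, lge_value=10.0)
        sl = study.slices[1]
        region = sl.geometry.segment_mask(8)
        sl.maps["LGE"].pixels[region] = 50.0
        remotes = [RemoteROI(k, (1,), 10.0, 5.0, "LGE") for k in range(study.n_slices)]
        lm = detect_lge(study, remotes=remotes)
        assert lm.slices[1][region].all()

    def test_uniform_nulled_myocardium_is_negative(self, small_geo):
        study = make_study(small_geo, lge_value=20.0)
        assert detect_lge(study).is_empty()

    def test_zero_noise_enhancing_lesion_equals_truth(self, clean_lesion_subject):
        study, truth = clean_lesion_subject
        lm = detect_lge(study)
        assert np.array_equal(np.stack(lm.slices), np.stack(truth.injury_masks))


class TestRemoteRoi:
    def test_uniform_slice_ties_break_to_lowest_segment_id(self, small_geo):
        study = make_study(small_geo)
        roi = select_remote_roi(study.slices[0], "T2W", study.qc)
        assert roi.segment_ids == (1,)

    def test_elevated_segment_never_chosen(self, small_geo):
        study = make_study(small_geo)
        sl = study.slices[2]
        hot = 9
        sl.maps["T2W"].pixels[sl.geometry.segment_mask(hot)] = 999.0
        roi = select_remote_roi(sl, "T2W", study.qc)
        assert hot not in roi.segment_ids

    def test_artifactually_dark_segment_excluded(self, small_geo):
        study = make_study(small_geo)
        sl = study.slices[2]
        # make the slice noisy enough for a meaningful robust SD, then null one segment
        rng = np.random.default_rng(0)
        px = sl.maps["T2W"].pixels
        px[sl.geometry.myo_mask] += rng.normal(0, 5.0, sl.geometry.myo_mask.sum())
        dark = 10
        px[sl.geometry.segment_mask(dark)] = 0.0
        roi = select_remote_roi(sl, "T2W", study.qc)
        assert dark not in roi.segment_ids

    def test_no_eligible_segment_raises(self, small_geo):
        study = make_study(small_geo)
        sl = study.slices[0]
        with pytest.raises(NoRemoteReferenceError):
            select_remote_roi(sl, "LGE", study.qc, prior_lge=sl.geometry.myo_mask)


class TestSubjectPositivity:
    def _mask_with_components(self, small_geo, slices):
        study = make_study(small_geo)
        lm = detect_t1_injury(study)  # empty everywhere
        for k in slices:
            region = study.slices[k].geometry.segment_mask(
                study.slices[k].geometry.segment_ids[0]
            )
            lm.slices[k] |= region
            lm.components.append(
                detection.Component(id=len(lm.components) + 1, slice_index=k,
                                    n_pixels=int(region.sum()),
                                    area_mm2=float(region.sum() * 2.25),
                                    centroid=(0.0, 0.0))
            )
        return lm

    def test_no_components_is_negative(self, small_geo):
        lm = self._mask_with_components(small_geo, [])
        assert not subject_positive(lm).positive

    def test_contiguous_slice_confirmation(self, small_geo):
        adjacent = self._mask_with_components(small_geo, [3, 4])
        gapped = self._mask_with_components(small_geo, [1, 3])
        assert subject_positive(adjacent, confirm_slices=2).positive
        assert not subject_positive(gapped, confirm_slices=2).positive
        assert subject_positive(gapped).positive  # default rule: any component

    def test_orthogonal_plane_confirmation_unsupported(self, small_geo):
        lm = self._mask_with_components(small_geo, [2])
        with pytest.raises(NotImplementedError, match="unsupported"):
            subject_positive(lm, confirm_planes=2)

    def test_empty_study_rejected(self):
        lm = detection.LesionMask("T1", "T1>=990ms", 40.0, slices=[])
        with pytest.raises(ValueError, match="empty study"):
            subject_positive(lm)

    def test_group_iii_positives_match_lesion_bearing_truth(self, small_bundle):
        ps = small_bundle["per_subject"]
        truth = small_bundle["truth"]
        g3 = ps[ps.group == "III"]
        expected = sum(truth.by_id(sid).has_lesion() for sid in g3.index)
        assert int(g3.t1.sum()) == expected
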