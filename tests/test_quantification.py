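"""Lesion-definition rules, region assignment and volume arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmlpipe.quantification import (
    BMLCriteria,
    BMLMeasurement,
    apply_bml_criteria,
    assign_region,
    central_block,
    compute_measurement,
    index_compartment,
    volume_change,
)
from bmlpipe.segmentation import BoneMask, LesionCandidate, MRVolume

SPACING = (0.357, 0.511, 3.0)


def make_candidate(voxels, dists):
    vox = np.asarray(voxels, dtype=int)
    d = np.asarray(dists, dtype=float)
    return LesionCandidate(
        voxels=vox, voxel_dists_mm=d,
        slice_span=int(np.unique(vox[:, 2]).size),
        min_surface_dist_mm=float(d.min()),
        centroid_mm=tuple(vox.mean(axis=0) * np.array(SPACING)))


def column(z_indices, dist=0.0, x=5, y=5):
    vox = [(x, y, z) for z in z_indices]
    return make_candidate(vox, [dist] * len(vox))


CRIT = BMLCriteria()


class TestCriteria:
    def test_distance_cap(self):
        far = column([0, 1], dist=12.0)
        near = column([0, 1], dist=10.0)
        kept = apply_bml_criteria([far, near], CRIT, slice_count=24)
        # "no more than 10 mm" is inclusive
        assert len(kept) == 1 and kept[0].min_surface_dist_mm == 10.0

    def test_single_slice_removed(self):
        assert apply_bml_criteria([column([1])], CRIT, 24) == []

    def test_central_block_deletion_and_translation(self):
        inside = column([8, 9, 10])              # wholly inside block 7..15
        outside = column([17, 18])
        kept = apply_bml_criteria([inside, outside], CRIT, 24)
        assert len(kept) == 1
        assert kept[0].voxels[:, 2].tolist() == [17, 18]

    def test_span_recomputed_after_deletion(self):
        # spans slices 15,16 but slice 15 is excluded -> span 1 -> removed
        straddling = column([15, 16])
        assert apply_bml_criteria([straddling], CRIT, 24) == []

    def test_even_slice_count_block_toward_zero(self):
        assert list(central_block(24)) == list(range(7, 16))
        assert list(central_block(25)) == list(range(8, 17))

    @given(st.lists(
        st.tuples(st.lists(st.integers(0, 23), min_size=1, max_size=8,
                           unique=True),
                  st.floats(0.0, 20.0)),
        max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_contractive_and_idempotent(self, blobs):
        cands = [column(sorted(zs), dist=d) for zs, d in blobs]
        once = apply_bml_criteria(cands, CRIT, 24)
        assert len(once) <= len(cands)
        twice = apply_bml_criteria(once, CRIT, 24)
        assert len(twice) == len(once)
        for a, b in zip(once, twice):
            assert np.array_equal(a.voxels, b.voxels)
            assert a.slice_span == b.slice_span

    def test_no_retained_voxel_in_central_block(self):
        cands = [column([5, 6, 7, 8]), column([14, 15, 16, 17])]
        for kept in apply_bml_criteria(cands, CRIT, 24):
            assert not np.isin(kept.voxels[:, 2],
                               list(central_block(24))).any()


class TestRegions:
    def _bones(self):
        shape = (10, 10, 10)
        femur = np.zeros(shape, bool)
        femur[:, :4, :] = True
        tibia = np.zeros(shape, bool)
        tibia[:, 6:, :] = True
        return BoneMask(masks={"femur": femur, "tibia": tibia},
                        articular_masks={"femur": np.zeros(shape, bool),
                                         "tibia": np.zeros(shape, bool)},
                        split_z_mm=13.5)  # z index 4.5 at dz=3

    def test_sides_and_tie_goes_medial(self):
        bones = self._bones()
        medial = column([3, 4], x=5, y=7)       # centroid z=10.5mm <= split
        lateral = column([5, 6], x=5, y=7)      # centroid z=16.5mm
        on_split = make_candidate([(5, 7, 4), (5, 7, 5)], [0, 0])
        assert assign_region(medial, bones) == "medial tibia"
        assert assign_region(lateral, bones) == "lateral tibia"
        assert assign_region(on_split, bones) == "medial tibia"

    def test_straddle_and_outside_errors(self):
        bones = self._bones()
        straddle = make_candidate([(5, 3, 2), (5, 7, 2)], [0, 0])
        outside = make_candidate([(5, 5, 2)], [0])
        with pytest.raises(ValueError, match="2 bones"):
            assign_region(straddle, bones)
        with pytest.raises(ValueError, match="0 bones"):
            assign_region(outside, bones)


class TestMeasurement:
    def test_printed_spacing_arithmetic(self):
        vol = MRVolume(np.zeros((20, 20, 20)), SPACING)
        vox = [(x, y, z) for x in range(10) for y in range(10)
               for z in range(10)]
        cand = make_candidate(vox, [0.0] * 1000)
        cand.region = "medial tibia"
        meas = compute_measurement([cand], vol)
        assert meas.total_cm3 == pytest.approx(0.547281, abs=1e-6)

    def test_empty_and_additive(self):
        vol = MRVolume(np.zeros((8, 8, 8)), SPACING)
        empty = compute_measurement([], vol)
        assert empty.total_cm3 == 0.0
        a = column([0, 1])
        a.region = "medial femur"
        b = column([5, 6])
        b.region = "lateral tibia"
        meas = compute_measurement([a, b], vol)
        assert meas.total_cm3 == pytest.approx(
            meas.region_volumes_cm3["medial femur"]
            + meas.region_volumes_cm3["lateral tibia"])

    def test_unassigned_region_rejected(self):
        vol = MRVolume(np.zeros((8, 8, 8)), SPACING)
        with pytest.raises(ValueError, match="region"):
            compute_measurement([column([0, 1])], vol)


class TestIndexCompartment:
    MEAS = BMLMeasurement("k1", "baseline", {
        "medial femur": 1.0, "medial tibia": 0.5,
        "lateral femur": 0.25, "lateral tibia": 0.25})

    def test_greater_side_selected(self):
        assert index_compartment(self.MEAS, 2, 0) == pytest.approx(1.5)
        assert index_compartment(self.MEAS, 0, 2) == pytest.approx(0.5)

    def test_tie_goes_medial(self):
        assert index_compartment(self.MEAS, 1, 1) == pytest.approx(1.5)

    def test_zero_case_and_bad_grade(self):
        zero = BMLMeasurement("k1", "baseline")
        assert index_compartment(zero, 0, 0) == 0.0
        with pytest.raises(ValueError, match="grade"):
            index_compartment(self.MEAS, 4, 0)


class TestChange:
    def test_identity_and_subtraction(self):
        base = BMLMeasurement("k1", "b", {
            "medial femur": 1.0, "medial tibia": 0.5,
            "lateral femur": 0.25, "lateral tibia": 0.25})
        same = BMLMeasurement("k1", "f", dict(base.region_volumes_cm3))
        assert volume_change(base, same)["total"] == 0.0
        smaller = BMLMeasurement("k1", "f", {
            "medial femur": 0.5, "medial tibia": 0.5,
            "lateral femur": 0.25, "lateral tibia": 0.25})
        assert volume_change(base, smaller)["total"] == pytest.approx(-0.5)

    def test_knee_mismatch(self):
        a = BMLMeasurement("k1", "b")
        b = BMLMeasurement("k2", "f")
        with pytest.raises(ValueError, match="mismatch"):
            volume_change(a, b)
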