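"""Angular partition structure, landmarks and slice-level assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvhquant.aha import (
    APEX,
    LEVELS,
    LandmarkSet,
    assign_slice_levels,
    build_partition,
    detect_landmarks,
    region_of,
)

LM = LandmarkSet((48.0, 48.0), 0.0, 120.0)


def test_49_mode_region_counts(partition49):
    by_level = {lvl: partition49.bins_for(lvl) for lvl in list(LEVELS) + [APEX]}
    assert [len(by_level[l]) for l in ("basal", "mid", "apical", APEX)] == [18, 18, 12, 1]
    assert len(partition49.bins) == 49
    assert sorted(partition49.region_ids) == list(range(1, 50))


def test_49_mode_bin_widths(partition49):
    for b in partition49.bins:
        if b.level == APEX:
            continue
        want = 20.0 if b.level in ("basal", "mid") else 30.0
        assert b.end_deg - b.start_deg == pytest.approx(want)


def test_17_mode_structure(partition17):
    assert len(partition17.bins) == 17
    for b in partition17.bins:
        if b.level == APEX:
            continue
        want = 60.0 if b.level in ("basal", "mid") else 90.0
        assert b.end_deg - b.start_deg == pytest.approx(want)
    assert len(partition17.bins_for("basal")) == 6
    assert len(partition17.bins_for("apical")) == 4


def test_bins_tile_each_level_exactly(partition49, partition17):
    for part in (partition49, partition17):
        for lvl in LEVELS:
            bins = sorted(part.bins_for(lvl), key=lambda b: b.start_deg)
            assert bins[0].start_deg == 0.0
            for a, b in zip(bins, bins[1:]):
                assert a.end_deg == pytest.approx(b.start_deg)
            assert bins[-1].end_deg == pytest.approx(360.0)


def test_sub_segments_nest_inside_parent_segments(partition49, partition17):
    for b49 in partition49.bins:
        parent = [b for b in partition17.bins if b.segment_id == b49.segment_id]
        assert len(parent) == 1
        p = parent[0]
        assert p.start_deg - 1e-9 <= b49.start_deg and b49.end_deg <= p.end_deg + 1e-9


def test_region_of_boundary_and_wraparound(partition49):
    # half-open rule: a boundary angle belongs to the bin it starts
    first = region_of(0.0, "basal", partition49)
    b = partition49.bin_by_id(first)
    assert b.start_deg == 0.0
    last = region_of(359.9, "basal", partition49)
    assert partition49.bin_by_id(last).end_deg == pytest.approx(360.0)
    # any angle maps to the single apex region
    assert region_of(123.4, APEX, partition49) == 49


def test_region_of_17_parent_matches_49(partition49, partition17):
    for ang in np.arange(0.0, 360.0, 7.3):
        for lvl in LEVELS:
            rid49 = region_of(ang, lvl, partition49)
            rid17 = region_of(ang, lvl, partition17)
            assert partition49.bin_by_id(rid49).segment_id == rid17


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(0.0, 360.0))
def test_rotation_equivariance(delta):
    lm = LandmarkSet((48.0, 48.0), delta, delta + 120.0)
    part = build_partition(lm, list(LEVELS) + [APEX], 49)
    base = build_partition(LM, list(LEVELS) + [APEX], 49)
    for b, b0 in zip(part.bins, base.bins):
        assert b.start_deg == pytest.approx(b0.start_deg)  # relative bins unchanged
    for rid in (1, 20, 40):
        s, w = part.absolute_span(rid)
        s0, w0 = base.absolute_span(rid)
        wrapped = (((s - s0) - delta) + 180.0) % 360.0 - 180.0
        assert wrapped == pytest.approx(0.0, abs=1e-9)
        assert w == pytest.approx(w0)


def test_invalid_mode_and_identical_insertions_rejected():
    with pytest.raises(ValueError):
        build_partition(LM, list(LEVELS), mode=20)
    with pytest.raises(ValueError):
        LandmarkSet((0.0, 0.0), 10.0, 370.0)


def test_detect_landmarks_centroid_on_phantom(uniform_phantom):
    stack, truth = uniform_phantom
    mid_idx = stack.level_labels.index("mid")
    lm = detect_landmarks(truth.masks[mid_idx], insertion_angles=(0.0, 120.0))
    assert lm.lv_center[0] == pytest.approx(truth.landmarks.lv_center[0], abs=0.5)
    assert lm.lv_center[1] == pytest.approx(truth.landmarks.lv_center[1], abs=0.5)


def test_detect_landmarks_override_verbatim():
    override = LandmarkSet((1.0, 2.0), 33.0, 211.0)
    assert detect_landmarks(np.zeros((4, 4)), override=override) is override


def test_detect_landmarks_ellipse_centroid_matches_pixel_average():
    rows, cols = np.mgrid[0:64, 0:64]
    cavity = ((rows - 30.0) / 8.0) ** 2 + ((cols - 25.0) / 12.0) ** 2 <= 1.0
    ring = ((rows - 30.0) / 14.0) ** 2 + ((cols - 25.0) / 18.0) ** 2 <= 1.0
    mask = ring & ~cavity
    lm = detect_landmarks(mask, insertion_angles=(0.0, 120.0))
    rr, cc = np.nonzero(cavity)
    assert lm.lv_center == pytest.approx((rr.mean(), cc.mean()), abs=1e-9)


def test_detect_landmarks_requires_cavity_or_override():
    with pytest.raises(ValueError):
        detect_landmarks(np.ones((8, 8)))


def test_detect_landmarks_rv_heuristic_recovers_contact_arc():
    rows, cols = np.mgrid[0:96, 0:96]
    r = np.hypot(rows - 48, cols - 48)
    lv = (r >= 12) & (r <= 20)
    ang = np.degrees(np.arctan2(-(rows - 48), cols - 48)) % 360.0
    rv = (r > 20) & (r <= 30) & (ang >= 40.0) & (ang <= 160.0)
    lm = detect_landmarks(lv, rv_mask=rv)
    assert lm.anterior_rv_insertion == pytest.approx(160.0, abs=4.0)
    assert lm.inferior_rv_insertion == pytest.approx(40.0, abs=4.0)


def test_assign_slice_levels_thirds_and_apex():
    labels = assign_slice_levels(10, has_cavity=[True] * 9 + [False])
    assert labels == ["basal"] * 3 + ["mid"] * 3 + ["apical"] * 3 + [APEX]


def test_assign_slice_levels_tie_goes_basal():
    labels = assign_slice_levels(10, has_cavity=[True] * 10)
    assert labels == ["basal"] * 4 + ["mid"] * 3 + ["apical"] * 3


def test_assign_slice_levels_explicit_passthrough_and_minimum():
    explicit = ["basal", "mid", APEX]
    assert assign_slice_levels(3, explicit=explicit) == explicit
    with pytest.raises(ValueError):
        assign_slice_levels(2, has_cavity=[True, True])
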