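"""Radial wall-thickness measurement against analytic and brute-force oracles."""

import numpy as np
import pytest

from lvhquant.aha import APEX, LEVELS, LandmarkSet, build_partition
from lvhquant.contours import ContourSet, SliceContours, circle_polygon
from lvhquant.phantom import generate_phantom
from lvhquant.thickness import mae, ray_thickness, regional_thickness
from tests.conftest import small_spec

CENTER = (64.0, 64.0)


def annulus_contours(r_endo=20.0, r_epi=30.0, level="mid"):
    return SliceContours(
        epi=circle_polygon(CENTER, r_epi),
        endo=circle_polygon(CENTER, r_endo),
        level=level,
    )


@pytest.mark.parametrize("angle", [0.0, 17.0, 90.0, 181.5, 359.0])
def test_annulus_thickness_is_radius_difference(angle):
    sc = annulus_contours()
    t = ray_thickness(sc, CENTER, angle, (1.0, 1.0))
    assert t == pytest.approx(10.0, abs=2e-3)


def test_isotropic_spacing_scales_thickness():
    sc = annulus_contours()
    t = ray_thickness(sc, CENTER, 45.0, (1.25, 1.25))
    assert t == pytest.approx(12.5, abs=3e-3)


def brute_force_ray_thickness(sc, center, angle, spacing):
    """Exhaustive ray/segment intersection, solved per polygon edge."""
    s = np.asarray(spacing, float)
    c = np.asarray(center, float) * s
    a = np.deg2rad(angle)
    d = np.array([-np.sin(a), np.cos(a)])

    def crossings(poly):
        pts = poly * s[None, :]
        out = []
        for p0, p1 in zip(pts, np.roll(pts, -1, axis=0)):
            e = p1 - p0
            denom = d[0] * (-e[1]) - d[1] * (-e[0])
            if abs(denom) < 1e-14:
                continue
            rhs = p0 - c
            t = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / denom
            u = (d[0] * rhs[1] - d[1] * rhs[0]) / denom
            if t >= 0 and -1e-12 <= u <= 1 + 1e-12:
                out.append(t)
        return sorted(out)

    de = crossings(sc.endo)
    dp = crossings(sc.epi)
    if not de or not dp:
        return None
    beyond = [x for x in dp if x >= de[0] - 1e-9]
    return beyond[0] - de[0] if beyond else None


def test_ray_thickness_matches_brute_force_on_elliptical_epi():
    ang = np.deg2rad(np.arange(0.0, 360.0, 1.0))
    epi = np.column_stack([CENTER[0] - 34.0 * np.sin(ang), CENTER[1] + 27.0 * np.cos(ang)])
    sc = SliceContours(epi=epi, endo=circle_polygon(CENTER, 15.0), level="mid")
    for angle in np.arange(0.0, 360.0, 23.7):
        got = ray_thickness(sc, CENTER, angle, (1.0, 1.0))
        want = brute_force_ray_thickness(sc, CENTER, angle, (1.0, 1.0))
        assert got == pytest.approx(want, abs=1e-6)


def make_partition(center=CENTER, anchor=0.0):
    lm = LandmarkSet(center, anchor, anchor + 120.0)
    return lm, build_partition(lm, list(LEVELS) + [APEX], 49)


def test_regional_uniform_annulus_all_regions_10mm():
    lm, part = make_partition()
    slices = [annulus_contours(level=lvl) for lvl in LEVELS]
    slices.append(SliceContours(epi=circle_polygon(CENTER, 5.0), endo=None, level=APEX))
    report = regional_thickness(ContourSet(slices, (1.0, 1.0)), part, lm, step=1.0)
    for b in part.bins:
        if b.level == APEX:
            continue
        assert report.mean_rwt[b.region_id] == pytest.approx(10.0, abs=5e-3)
        assert len(report.samples[b.region_id]) == int(b.end_deg - b.start_deg)


def test_regional_recovery_on_focal_phantom(focal_phantom):
    _, truth = focal_phantom
    report = regional_thickness(truth.contours, truth.partition, truth.landmarks)
    tol = 0.5 * truth.contours.spacing[0]
    for rid, want in truth.rwt_truth.items():
        b = truth.partition.bin_by_id(rid)
        if b.level == APEX:
            continue
        assert report.mean_rwt[rid] == pytest.approx(want, abs=tol)


def test_sample_angles_fall_inside_their_bins(focal_phantom):
    _, truth = focal_phantom
    report = regional_thickness(truth.contours, truth.partition, truth.landmarks, step=5.0)
    for rid, pairs in report.samples.items():
        b = truth.partition.bin_by_id(rid)
        if b.level == APEX:
            continue
        for ang, _ in pairs:
            rel = (ang - truth.partition.anchor_deg) % 360.0
            assert b.start_deg - 1e-9 <= rel < b.end_deg


def test_duplicate_slices_do_not_change_the_report():
    lm, part = make_partition()
    one = [annulus_contours(level="basal")]
    two = one + [annulus_contours(level="basal")]
    r1 = regional_thickness(ContourSet(one, (1.0, 1.0)), part, lm)
    r2 = regional_thickness(ContourSet(two, (1.0, 1.0)), part, lm)
    for rid in r1.mean_rwt:
        assert r1.mean_rwt[rid] == pytest.approx(r2.mean_rwt[rid], abs=1e-12)


def test_step_must_divide_bin_width():
    lm, part = make_partition()
    with pytest.raises(ValueError):
        regional_thickness(ContourSet([annulus_contours(level="basal")], (1.0, 1.0)),
                           part, lm, step=7.0)


def test_rotation_invariance_of_regional_means(focal_phantom):
    _, truth = focal_phantom
    delta = 36.0
    spec = small_spec(seed=12, rv_insertion_angles=(delta, delta + 120.0),
                      thickness_profile={
                          "basal": lambda a: np.where((np.asarray(a) - delta) % 360.0 < 20.0, 26.0, 10.0),
                          "mid": 10.0, "apical": 10.0})
    _, rotated = generate_phantom(spec)
    base = regional_thickness(truth.contours, truth.partition, truth.landmarks)
    rot = regional_thickness(rotated.contours, rotated.partition, rotated.landmarks)
    for rid in base.mean_rwt:
        if truth.partition.bin_by_id(rid).level == APEX:
            continue
        assert rot.mean_rwt[rid] == pytest.approx(base.mean_rwt[rid], abs=1e-6)


def test_scale_equivariance(focal_phantom):
    _, truth = focal_phantom
    base = regional_thickness(truth.contours, truth.partition, truth.landmarks)
    k = 2.0
    scaled = ContourSet(truth.contours.slices,
                        (truth.contours.spacing[0] * k, truth.contours.spacing[1] * k))
    rep_k = regional_thickness(scaled, truth.partition, truth.landmarks)
    for rid in base.mean_rwt:
        assert rep_k.mean_rwt[rid] == pytest.approx(k * base.mean_rwt[rid], rel=1e-9)


def test_refinement_convergence(uniform_phantom):
    _, truth = uniform_phantom
    coarse = regional_thickness(truth.contours, truth.partition, truth.landmarks, step=2.0)
    fine = regional_thickness(truth.contours, truth.partition, truth.landmarks, step=1.0)
    for rid in coarse.mean_rwt:
        assert abs(coarse.mean_rwt[rid] - fine.mean_rwt[rid]) < 0.1


def test_mae_examples_and_oracle():
    assert mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert mae([1.0, 2.0, 3.0], [2.0, 2.0, 5.0]) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    y, yh = rng.normal(size=100), rng.normal(size=100)
    oracle = sum(abs(a - b) for a, b in zip(y, yh)) / 100.0
    assert mae(y, yh) == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])
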