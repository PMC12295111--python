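"""Segmentation surface: DSC/HD metrics, contour extraction, U-Net contract."""

import warnings

import numpy as np
import pytest

from lvhquant.contours import circle_polygon
from lvhquant.segmentation import (
    SegTrainConfig,
    UNetSpec,
    build_unet,
    dsc,
    hausdorff,
    masks_to_contours,
    train_segmenter,
)


def test_dsc_identity_disjoint_and_shift():
    a = np.zeros((40, 40), bool)
    a[5:15, 5:15] = True
    assert dsc(a, a) == 100.0
    b = np.zeros_like(a)
    b[25:35, 25:35] = True
    assert dsc(a, b) == 0.0
    shifted = np.roll(a, 5, axis=1)  # half-overlap square
    assert dsc(a, shifted) == pytest.approx(50.0)
    assert dsc(shifted, a) == pytest.approx(50.0)  # symmetric
    assert dsc(np.zeros((4, 4)), np.zeros((4, 4))) == 100.0


def test_hausdorff_identity_and_concentric_circles():
    c = circle_polygon((50, 50), 20.0)
    assert hausdorff(c, c) == pytest.approx(0.0, abs=1e-12)
    c2 = circle_polygon((50, 50), 23.0)
    assert hausdorff(c, c2, (1.0, 1.0)) == pytest.approx(3.0, abs=1e-2)
    assert hausdorff(c, c2, (2.0, 2.0)) == pytest.approx(6.0, abs=2e-2)


def shapely_hd_oracle(a, b):
    """Independent point-to-segment oracle via shapely distances."""
    from shapely.geometry import LinearRing, Point

    ra, rb = LinearRing(a), LinearRing(b)
    d_ab = max(Point(p).distance(rb) for p in a)
    d_ba = max(Point(p).distance(ra) for p in b)
    return max(d_ab, d_ba)


def test_hausdorff_matches_brute_force_on_random_polygons():
    rng = np.random.default_rng(4)
    for _ in range(10):
        a = rng.uniform(0, 100, size=(20, 2))
        b = rng.uniform(0, 100, size=(20, 2))
        assert hausdorff(a, b) == pytest.approx(shapely_hd_oracle(a, b), abs=1e-9)


def test_hausdorff_metric_properties_spot_check():
    rng = np.random.default_rng(5)
    a, b, c = (rng.uniform(0, 50, size=(12, 2)) for _ in range(3))
    assert hausdorff(a, b) == pytest.approx(hausdorff(b, a), abs=1e-12)
    assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9
    with pytest.raises(ValueError):
        hausdorff(a, np.empty((0, 2)))


def annulus_mask(shape=(64, 64), center=(32, 32), r_in=20.0, r_out=30.0):
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    r = np.hypot(rows - center[0], cols - center[1])
    return (r >= r_in) & (r <= r_out)


def test_masks_to_contours_recovers_annulus_radii():
    mask = annulus_mask(shape=(80, 80), center=(40, 40))
    sc = masks_to_contours(mask, (1.0, 1.0))
    r_epi = np.hypot(sc.epi[:, 0] - 40, sc.epi[:, 1] - 40)
    r_endo = np.hypot(sc.endo[:, 0] - 40, sc.endo[:, 1] - 40)
    assert abs(r_epi.mean() - 30.0) < 1.0
    assert abs(r_endo.mean() - 20.0) < 1.0


def test_masks_to_contours_drops_salt_blob_with_warning():
    mask = annulus_mask(shape=(80, 80), center=(40, 40)).astype(np.uint8)
    mask[2:4, 2:4] = 1  # spurious 2-px blob
    with pytest.warns(UserWarning, match="largest"):
        sc = masks_to_contours(mask, (1.0, 1.0))
    assert sc.epi[:, 0].min() > 5  # blob did not become the epicardium


def test_masks_to_contours_apex_and_missing_cavity():
    rows, cols = np.mgrid[:40, :40]
    disc = np.hypot(rows - 20, cols - 20) <= 10
    sc = masks_to_contours(disc, (1.0, 1.0), level="apex")
    assert sc.endo is None
    with pytest.raises(ValueError, match="cavity"):
        masks_to_contours(disc, (1.0, 1.0), level="mid")


@pytest.mark.parametrize("depth,size", [(4, 32), (3, 32), (5, 32)])
def test_unet_output_size_equals_input_size(depth, size):
    net = build_unet(UNetSpec(depth=depth, base_filters=2), seed=0)
    out = net.forward(np.zeros((1, 1, size, size)))
    assert out.shape == (1, 2, size, size)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)  # per-pixel softmax


def test_unet_parameter_count_increases_with_depth():
    counts = [build_unet(UNetSpec(depth=d, base_filters=4)).n_parameters for d in (3, 4, 5)]
    assert counts[0] < counts[1] < counts[2]


def test_unet_spec_rejects_bad_depth():
    with pytest.raises(ValueError):
        UNetSpec(depth=2)


def _tiny_cases(n=6, size=32, seed=0):
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        rows, cols = np.mgrid[:size, :size]
        r = np.hypot(rows - size / 2, cols - size / 2)
        r_in = rng.uniform(4, 6)
        mask = (r >= r_in) & (r <= r_in + rng.uniform(3, 6))
        img = np.where(mask, 0.5, np.where(r < r_in, 0.9, 0.05))
        cases.append((img + rng.normal(0, 0.01, img.shape), mask.astype(float)))
    return cases


def test_train_segmenter_history_contract_and_determinism():
    cases = _tiny_cases()
    cfg = SegTrainConfig(epochs=1, seed=3)
    spec = UNetSpec(depth=3, base_filters=2)
    _, h1 = train_segmenter(cases, cfg, spec)
    assert len(h1) == 1
    assert {"epoch", "train_dice", "val_dice", "loss"} <= set(h1.columns)
    cfg2 = SegTrainConfig(epochs=2, seed=3)
    _, h2 = train_segmenter(cases, cfg2, spec)
    _, h3 = train_segmenter(cases, cfg2, spec)
    np.testing.assert_allclose(h2.loss.values, h3.loss.values, rtol=0, atol=0)


def test_train_segmenter_rejects_empty():
    with pytest.raises(ValueError):
        train_segmenter([], SegTrainConfig())
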