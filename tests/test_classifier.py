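"""Classifier architecture trace, sub-segment encoding and training harness."""

import numpy as np
import pytest

from lvhquant.classifier import (
    ClassifierSpec,
    ClassifierTrainConfig,
    build_classifier,
    encode_subsegment,
    hyperparameter_grid,
    shape_trace,
    stratified_split,
    train_classifier,
)

FULL = ClassifierSpec()


def test_reference_trace_output_shapes():
    rows = {r.index: r for r in shape_trace(FULL)}
    assert rows[1].output_shape == (256, 256, 3)
    assert rows[2].output_shape == (256, 256, 32)
    assert rows[5].output_shape == (128, 128, 32)
    assert rows[6].output_shape == (130, 130, 64)
    assert rows[9].output_shape == (65, 65, 64)
    assert rows[10].output_shape == (67, 67, 128)
    assert rows[13].output_shape == (33, 33, 128)
    assert rows[14].output_shape == (35, 35, 256)
    assert rows[17].output_shape == (17, 17, 256)
    assert rows[18].output_shape == (19, 19, 512)
    assert rows[21].output_shape == (9, 9, 512)
    assert rows[22].output_shape == (128,)
    assert rows[24].output_shape == (16,)
    assert rows[25].output_shape == (4,)


def test_reference_trace_parameter_counts():
    rows = {r.name: r for r in shape_trace(FULL)}
    assert rows["conv1"].parameters == 896
    assert rows["conv2"].parameters == 18496
    assert rows["conv3"].parameters == 73856
    assert rows["conv4"].parameters == 295168
    # (3*3*256 + 1) * 512 by the standard formula
    assert rows["conv5"].parameters == 1180160
    assert [rows[f"batchnorm{i}"].parameters for i in range(1, 6)] == [64, 128, 256, 512, 1024]
    assert rows["dense1"].parameters == 5308544
    assert rows["dense2"].parameters == 2064


def test_trace_rejects_collapsing_input():
    with pytest.raises(ValueError, match="collapses"):
        shape_trace(ClassifierSpec(input_size=1))


def test_built_network_matches_trace_parameter_total():
    spec = FULL.scaled(input_size=64, width_factor=0.125)
    net, trace = build_classifier(spec, seed=0)
    # batch-norm running stats are not trainable; trace counts match params
    assert net.n_parameters == sum(r.parameters for r in trace)
    logits = net.forward(np.zeros((2, 3, 64, 64)))
    assert logits.shape == (2, 4)


def test_max_pool_variant_builds_and_runs():
    spec = ClassifierSpec(input_size=32, filters=(4, 8, 8, 8, 8), pooling="max")
    net, _ = build_classifier(spec, seed=0)
    assert net.forward(np.zeros((1, 3, 32, 32))).shape == (1, 4)


def _phantom_with_truth():
    from tests.conftest import small_spec
    from lvhquant.phantom import generate_phantom

    return generate_phantom(small_spec(seed=21))


def test_encode_subsegment_disjoint_regions_disjoint_support():
    stack, truth = _phantom_with_truth()
    sl = stack.level_labels.index("basal")
    sc = truth.contours.slices[sl]
    x1 = encode_subsegment(stack.slices[sl], truth.partition, 1, sc, truth.landmarks, out_size=96)
    x5 = encode_subsegment(stack.slices[sl], truth.partition, 5, sc, truth.landmarks, out_size=96)
    assert x1.shape == (3, 96, 96)
    assert not np.any((x1[0] > 0) & (x5[0] > 0))
    np.testing.assert_array_equal(x1[0], x1[1])  # replicated channels


def test_encode_subsegment_union_covers_myocardium_only():
    stack, truth = _phantom_with_truth()
    sl = stack.level_labels.index("mid")
    sc = truth.contours.slices[sl]
    union = np.zeros((96, 96), bool)
    for b in truth.partition.bins_for("mid"):
        x = encode_subsegment(stack.slices[sl], truth.partition, b.region_id, sc,
                              truth.landmarks, out_size=96)
        union |= x[0] > 0
    rows, cols = np.mgrid[:96, :96]
    r_mm = np.hypot(rows - 48, cols - 48) * 1.25
    inside_wall = (r_mm > 21.5) & (r_mm < 28.5)  # interior of the 20-30 mm wall
    assert np.all(union[inside_wall])
    outside = r_mm < 18.0
    assert not np.any(union[outside])


def test_encode_subsegment_resizes_and_rejects_empty():
    stack, truth = _phantom_with_truth()
    sl = stack.level_labels.index("basal")
    sc = truth.contours.slices[sl]
    x = encode_subsegment(stack.slices[sl], truth.partition, 2, sc, truth.landmarks, out_size=64)
    assert x.shape == (3, 64, 64)
    blank = np.zeros_like(stack.slices[sl])
    from lvhquant.contours import SliceContours, circle_polygon

    tiny = SliceContours(epi=circle_polygon((1.0, 1.0), 0.5), endo=None, level="apex")
    with pytest.raises(ValueError, match="no myocardial"):
        encode_subsegment(blank, truth.partition, 49, tiny, truth.landmarks, out_size=64)


def test_stratified_split_deterministic_and_covers_classes():
    labels = [0] * 20 + [1] * 10 + [2] * 6 + [3] * 4
    a = stratified_split(labels, seed=5)
    b = stratified_split(labels, seed=5)
    assert a == b
    train, val, test = a
    assert sorted(train + val + test) == list(range(40))
    for c in range(4):
        assert any(labels[i] == c for i in train)


def test_stratified_split_keeps_rare_classes_in_training():
    # a singleton class must land in the training split, never only in
    # validation or test (the at-least-one allocation rule)
    labels = [0] * 30 + [1]
    train, _, _ = stratified_split(labels, seed=0)
    assert 30 in train


def _toy_dataset(n_per_class=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for c in range(4):
        for _ in range(n_per_class):
            x = np.zeros((3, size, size))
            x[:, : (c + 1) * 3, :] = 0.5 + rng.normal(0, 0.02, (3, (c + 1) * 3, size))
            data.append((x, c))
    return data


def test_train_classifier_history_and_seed_determinism():
    ds = _toy_dataset()
    spec = ClassifierSpec(input_size=16, filters=(4, 4, 4, 4, 4), dense=(16, 8))
    cfg = ClassifierTrainConfig(epochs=2, seed=1)
    _, h1, split1 = train_classifier(ds, cfg, spec)
    _, h2, split2 = train_classifier(ds, cfg, spec)
    assert split1 == split2
    assert len(h1) == 2
    np.testing.assert_allclose(h1.val_loss.values, h2.val_loss.values, atol=0)
    assert {"epoch", "train_accuracy", "val_loss", "val_accuracy"} <= set(h1.columns)


def test_train_classifier_rejects_empty_and_bad_config():
    with pytest.raises(ValueError):
        train_classifier([], ClassifierTrainConfig())
    with pytest.raises(ValueError):
        ClassifierTrainConfig(optimizer="adagrad")
    with pytest.raises(ValueError):
        ClassifierTrainConfig(split=(0.8, 0.1, 0.2))


def test_hyperparameter_grid_one_row_per_combination():
    ds = _toy_dataset(n_per_class=3)
    spec = ClassifierSpec(input_size=16, filters=(2, 2, 2, 2, 2), dense=(8, 8))
    grid = hyperparameter_grid(ds, optimizers=("adam", "adamax"), learning_rates=(1e-3,),
                               batch_sizes=(4,), epochs_list=(1,), spec=spec)
    assert len(grid) == 2
    assert set(grid.optimizer) == {"adam", "adamax"}
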