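"""Network construction, reference operations, and training behaviour.

The vectorised convolution layer is checked against the literal nested-sum
definition; shape propagation is checked against the published per-layer
output sizes; training is exercised on tiny synthetic cohorts.
"""

import math

import numpy as np
import pytest

import neurodct as nd
from neurodct import cnn
from neurodct.cnn import (
    ArchitectureError,
    ArchitectureSpec,
    ConvBlockSpec,
    Conv3D,
    TrainConfig,
    build_model,
    conv3d_reference,
    elu,
    output_shape,
)
from neurodct.cohort import ClassLabel, CohortSpec, Split, generate_cohort
from neurodct.preprocessing import to_model_input
from neurodct.ranking import Task

TASK_CLASSES = Task.AD_NCSPECT_PD.classes


def tiny_cohort(effect_size, n_per_class, seed=13, shape=(16, 16, 16)):
    spec = CohortSpec(
        n_per_class=n_per_class, effect_size=effect_size, noise_sd=0.5, seed=seed, shape=shape
    )
    records = [r for r in generate_cohort(spec) if r.label in TASK_CLASSES]
    return [r.with_volume(to_model_input(r.volume, "spatial")) for r in records]


def split_tiny(records, n_train):
    train, val = [], []
    for lab in TASK_CLASSES:
        rs = [r for r in records if r.label is lab]
        train += [r.with_split(Split.TRAIN) for r in rs[:n_train]]
        val += rs[n_train:]
    return train, val


# -- ELU --------------------------------------------------------------------

def test_elu_matches_closed_form_on_grid():
    xs = np.concatenate([np.linspace(-10, 10, 999), [0.0]])
    for alpha in (0.5, 1.0, 2.0):
        expected = np.array(
            [x if x >= 0 else alpha * (math.exp(x) - 1) for x in xs]
        )
        np.testing.assert_allclose(elu(xs, alpha), expected, atol=1e-12)
    assert elu(0.0, 3.0) == 0.0
    assert elu(2.5, 1.0) == 2.5
    assert elu(-1.0, 1.0) == pytest.approx(math.exp(-1) - 1, abs=1e-9)


# -- convolution reference --------------------------------------------------

def test_conv_reference_trivial_kernels(rng):
    x = rng.normal(size=(3, 3, 3))
    assert conv3d_reference(x, np.zeros((3, 3, 3)), bias=0.0) == 0.0
    voxel = rng.normal(size=(1, 1, 1))
    assert conv3d_reference(voxel, np.ones((1, 1, 1))) == pytest.approx(voxel[0, 0, 0])


def test_conv_layer_matches_nested_sum_oracle(rng):
    """Vectorised same-padded conv equals the literal nested-sum definition
    at every valid position, on >= 20 random instances."""
    checked = 0
    for trial in range(20):
        c_in = int(rng.integers(1, 3))
        d, h, w = (int(rng.integers(4, 7)) for _ in range(3))
        layer = Conv3D(c_in, 11, (3, 3, 3), np.random.default_rng(trial))
        x = rng.normal(size=(1, c_in, d, h, w)).astype(np.float32)
        y = layer.forward(x, train=False)
        xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1), (1, 1)))
        j = int(rng.integers(11))
        for a, b, c in [
            (int(rng.integers(d)), int(rng.integers(h)), int(rng.integers(w)))
            for _ in range(3)
        ]:
            window = xp[:, a : a + 3, b : b + 3, c : c + 3]
            expected = conv3d_reference(window, layer.w[j], layer.b[j])
            assert abs(y[0, j, a, b, c] - expected) < 1e-5
            checked += 1
    assert checked >= 20


def test_conv_reference_rejects_mismatched_window():
    with pytest.raises(ArchitectureError):
        conv3d_reference(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


# -- shape propagation ------------------------------------------------------

def test_pool_sequence_for_published_input():
    assert output_shape((79, 95, 69)) == [
        (40, 48, 35),
        (20, 24, 18),
        (10, 12, 9),
        (5, 6, 5),
        (3, 3, 3),
    ]


def test_pool_sequence_power_of_two():
    assert output_shape((64, 64, 64))[-1] == (2, 2, 2)


def test_degenerate_input_shape_rejected():
    with pytest.raises(ArchitectureError):
        ArchitectureSpec(input_shape=(0, 16, 16))


def test_conv_block_contract_is_fixed():
    with pytest.raises(ArchitectureError):
        ConvBlockSpec(filters=7)
    with pytest.raises(ArchitectureError):
        ConvBlockSpec(kernel=(5, 5, 5))


# -- model construction -----------------------------------------------------

def test_model_layer_shapes_match_architecture_table():
    model = build_model(ArchitectureSpec())
    shapes = dict()
    pooled = [s for name, s in model.layer_output_shapes() if name == "maxpool"]
    assert pooled == [
        (11, 40, 48, 35),
        (11, 20, 24, 18),
        (11, 10, 12, 9),
        (11, 5, 6, 5),
        (11, 3, 3, 3),
    ]
    fc = [s for name, s in model.layer_output_shapes() if name.startswith("fc")]
    assert fc == [(300,), (100,), (3,)]


def test_first_conv_block_parameter_count():
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)))
    conv1 = model.layers[0]
    assert conv1.w.size + conv1.b.size == 3 * 3 * 3 * 1 * 11 + 11  # == 308


def test_softmax_outputs_normalized(rng):
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=1)
    x = rng.normal(size=(3, 1, 16, 16, 16)).astype(np.float32)
    p = model.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(p >= 0)


# -- training ---------------------------------------------------------------

def test_training_smoke_two_subjects():
    records = tiny_cohort(effect_size=2.5, n_per_class=1)[:2]
    records = [r.with_split(Split.TRAIN) for r in records]
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=0)
    log = cnn.train(model, records, [], TrainConfig(max_epochs=1, seed=0), TASK_CLASSES)
    assert len(log) == 1
    assert np.isfinite(log[0]["loss"])


def test_training_rejects_empty_or_foreign_labels():
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)))
    with pytest.raises(ValueError):
        cnn.train(model, [], [], TrainConfig(max_epochs=1), TASK_CLASSES)
    stray = [
        r for r in tiny_cohort(1.0, 1) if r.label is ClassLabel.NC_SPECT
    ][0].with_split(Split.TRAIN)
    with pytest.raises(ValueError):
        cnn.train(model, [stray], [], TrainConfig(max_epochs=1), Task.AD_NCPET_PD.classes)


def test_memorization_toy_gives_diagonal_confusion():
    records = [r.with_split(Split.TRAIN) for r in tiny_cohort(2.5, 2, seed=29)]
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=2)
    cnn.train(model, records, [], TrainConfig(max_epochs=20, seed=2), TASK_CLASSES)
    cnn.finalize_batchnorm(model, records)
    cm = cnn.predict(model, records, TASK_CLASSES)
    assert cm.n == len(records)
    assert np.trace(cm.counts) == cm.n


def test_high_separation_validation_accuracy():
    # effect ten times the voxel noise s.d.: clearly separable
    train, val = split_tiny(tiny_cohort(5.0, 9, seed=31), 6)
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=3)
    cnn.train(model, train, val, TrainConfig(max_epochs=30, seed=3), TASK_CLASSES)
    cnn.finalize_batchnorm(model, train)
    cm = cnn.predict(model, val, TASK_CLASSES)
    assert np.trace(cm.counts) / cm.n > 0.9


def test_null_cohort_validation_accuracy_at_chance():
    train, val = split_tiny(tiny_cohort(0.0, 14, seed=37), 6)
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=4)
    log = cnn.train(model, train, val, TrainConfig(max_epochs=30, seed=4), TASK_CLASSES)
    n = len(val)
    half = 2.5758 * math.sqrt((1 / 3) * (2 / 3) / n)
    assert 1 / 3 - half <= log[-1]["val_accuracy"] <= 1 / 3 + half


def test_training_is_reproducible():
    records = [r.with_split(Split.TRAIN) for r in tiny_cohort(2.5, 2, seed=41)]
    cms = []
    for _ in range(2):
        model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=5)
        cnn.train(model, records, [], TrainConfig(max_epochs=2, seed=5), TASK_CLASSES)
        cms.append(cnn.predict(model, records, TASK_CLASSES).counts)
    np.testing.assert_array_equal(cms[0], cms[1])


def test_predict_counts_single_record():
    records = [r.with_split(Split.TRAIN) for r in tiny_cohort(2.5, 2, seed=43)]
    model = build_model(ArchitectureSpec(input_shape=(16, 16, 16)), seed=6)
    cnn.train(model, records, [], TrainConfig(max_epochs=20, seed=6), TASK_CLASSES)
    cnn.finalize_batchnorm(model, records)
    ad = [r for r in records if r.label is ClassLabel.AD][:1]
    cm = cnn.predict(model, ad, TASK_CLASSES)
    assert cm.n == 1
    assert cm.counts[0, 0] == 1  # AD predicted AD
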