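"""Loss, schedule, slab sampling, splitting and the training loop."""

import numpy as np
import pytest

from adreseg.network import NetConfig, SegmentationNetwork
from adreseg.trainer import (
    TrainConfig,
    TrainingCase,
    dice_loss,
    lr_at_epoch,
    sample_slab,
    sample_slab_biased,
    soft_dice,
    split_cases,
    train,
)


# ---------------------------------------------------------------------
# dice loss
# ---------------------------------------------------------------------

def test_perfect_overlap_has_negligible_loss(rng):
    target = (rng.random((20, 20, 10)) > 0.9).astype(np.float32)
    assert dice_loss(target, target) <= 1e-4


def test_perfect_complement_has_maximal_loss(rng):
    target = (rng.random((20, 20, 10)) > 0.5).astype(np.float32)
    assert dice_loss(1.0 - target, target) >= 1 - 1e-4


def test_uniform_half_prediction_closed_form():
    # fraction f = 0.01 over 1e5 voxels: 1 - (2*0.5*f)/(0.5 + f) = 1 - 0.01/0.51
    m = 100_000
    target = np.zeros(m, np.float32)
    target[: m // 100] = 1.0
    pred = np.full(m, 0.5, np.float32)
    assert dice_loss(pred, target) == pytest.approx(1 - 0.01 / 0.51, abs=1e-4)


def test_dice_loss_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((2, 2)), np.zeros((2, 3)))


def test_loss_and_soft_dice_are_complementary(rng):
    pred = rng.random((8, 8, 8)).astype(np.float32)
    target = (rng.random((8, 8, 8)) > 0.8).astype(np.float32)
    assert dice_loss(pred, target) + soft_dice(pred, target) == pytest.approx(1.0)


# ---------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------

def test_schedule_hits_printed_endpoints_exactly():
    cfg = TrainConfig()
    assert lr_at_epoch(0, cfg) == pytest.approx(2e-4, rel=1e-12)
    assert lr_at_epoch(999, cfg) == pytest.approx(4e-7, rel=1e-12)


def test_schedule_is_strictly_decreasing():
    cfg = TrainConfig()
    lrs = [lr_at_epoch(e, cfg) for e in range(0, 1000, 7)] + [lr_at_epoch(999, cfg)]
    assert all(a > b for a, b in zip(lrs, lrs[1:]))


def test_log_schedule_closed_form_at_midpoint():
    cfg = TrainConfig()
    expected = 2e-4 * (4e-7 / 2e-4) ** (500 / 999)
    assert lr_at_epoch(500, cfg) == pytest.approx(expected, rel=1e-12)
    # geometric midpoint of the endpoints at the fractional center
    assert lr_at_epoch(499.5, cfg) == pytest.approx(np.sqrt(2e-4 * 4e-7), rel=1e-9)


@pytest.mark.parametrize("schedule", ["linear", "cosine"])
def test_alternative_schedules_share_endpoints(schedule):
    cfg = TrainConfig(schedule=schedule)
    assert lr_at_epoch(0, cfg) == pytest.approx(2e-4)
    assert lr_at_epoch(999, cfg) == pytest.approx(4e-7)


def test_warmup_ramps_then_decays():
    cfg = TrainConfig(epochs=100, warmup_epochs=10, lr_initial=1e-2, lr_final=1e-3)
    ramp = [lr_at_epoch(e, cfg) for e in range(10)]
    assert all(a < b for a, b in zip(ramp, ramp[1:]))
    assert ramp[-1] == pytest.approx(1e-2)
    assert lr_at_epoch(99, cfg) == pytest.approx(1e-3)


def test_schedule_rejects_out_of_range_epoch():
    with pytest.raises(ValueError):
        lr_at_epoch(-1, TrainConfig())
    with pytest.raises(ValueError):
        lr_at_epoch(1000, TrainConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr_final=1.0, lr_initial=1e-4)
    with pytest.raises(ValueError):
        TrainConfig(slab_depth=30)
    with pytest.raises(ValueError):
        TrainConfig(train_fraction=1.0)
    with pytest.raises(ValueError):
        TrainConfig(schedule="step")
    with pytest.raises(ValueError):
        TrainConfig(fg_slab_bias=2.0)


# ---------------------------------------------------------------------
# slab sampling
# ---------------------------------------------------------------------

def test_slab_start_ranges_and_depth(rng):
    img = np.arange(4 * 4 * 60, dtype=np.float32).reshape(4, 4, 60)
    msk = np.zeros_like(img)
    starts = set()
    for _ in range(200):
        s_img, s_msk = sample_slab(img, msk, 32, rng)
        assert s_img.shape[2] == 32
        start = int(s_img[0, 0, 0] % 60)
        starts.add(start)
    assert starts <= set(range(0, 29))
    assert len(starts) > 10  # actually random


def test_slab_single_position_when_depth_matches(rng):
    img = np.arange(2 * 2 * 32, dtype=np.float32).reshape(2, 2, 32)
    s_img, _ = sample_slab(img, np.zeros_like(img), 32, rng)
    np.testing.assert_array_equal(s_img, img)


def test_short_volume_is_symmetrically_padded(rng):
    img = np.ones((4, 4, 20), np.float32)
    msk = np.ones((4, 4, 20), np.float32)
    s_img, s_msk = sample_slab(img, msk, 32, rng)
    assert s_img.shape[2] == 32
    assert np.all(s_img[:, :, :6] == 0) and np.all(s_img[:, :, 26:] == 0)
    assert np.all(s_msk[:, :, :6] == 0) and np.all(s_msk[:, :, 26:] == 0)
    assert np.all(s_img[:, :, 6:26] == 1)


def test_biased_sampler_always_hits_foreground_at_full_bias(rng):
    img = np.zeros((4, 4, 64), np.float32)
    msk = np.zeros((4, 4, 64), np.float32)
    msk[:, :, 40:44] = 1
    for _ in range(50):
        _, s_msk = sample_slab_biased(img, msk, 16, rng, fg_prob=1.0)
        assert s_msk.sum() > 0


def test_biased_sampler_at_zero_matches_uniform_contract(rng):
    img = np.zeros((2, 2, 40), np.float32)
    msk = np.zeros_like(img)
    s_img, _ = sample_slab_biased(img, msk, 16, rng, fg_prob=0.0)
    assert s_img.shape[2] == 16


# ---------------------------------------------------------------------
# case splitting
# ---------------------------------------------------------------------

def test_split_is_a_shuffled_partition():
    cases = list(range(10))
    tr, te = split_cases(cases, 0.8, seed=4)
    assert len(tr) == 8 and len(te) == 2
    assert sorted(tr + te) == cases
    assert set(tr).isdisjoint(te)


def test_split_is_deterministic_given_seed():
    cases = list(range(25))
    assert split_cases(cases, 0.8, 9) == split_cases(cases, 0.8, 9)
    assert split_cases(cases, 0.8, 9) != split_cases(cases, 0.8, 10)


def test_split_rejects_too_few_cases():
    with pytest.raises(ValueError):
        split_cases([1], 0.8, 0)


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

def _toy_cases(n=3, seed=0):
    """Bright-cube segmentation targets on a 32^3 grid."""
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        img = rng.normal(0.4, 0.05, (32, 32, 32)).astype(np.float32)
        msk = np.zeros((32, 32, 32), np.float32)
        x, y, z = rng.integers(6, 18, 3)
        msk[x : x + 8, y : y + 8, z : z + 8] = 1
        img[msk == 1] += 0.25
        cases.append(TrainingCase(np.clip(img, 0, 1), msk))
    return cases


TOY_NET = dict(
    input_size=(32, 32, 32), stem_channels=8, stage_channels=(16, 32, 64, 128), dropout=0.1
)


def _toy_cfg(**overrides):
    kwargs = dict(
        epochs=8, batch_size=2, lr_initial=5e-3, lr_final=1e-3,
        slab_depth=32, seed=1000, fg_slab_bias=0.5, adam_beta2=0.99,
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def test_training_descends_on_toy_problem():
    cases = _toy_cases()
    net = SegmentationNetwork(NetConfig(**TOY_NET), seed=1000)
    state = train(net, cases, _toy_cfg())
    assert state.losses[-1] < state.losses[0]
    assert state.steps == 8 * 2  # 3 cases -> 2 batches per epoch
    assert len(state.losses) == 8


def test_training_is_deterministic_under_fixed_seed():
    cases = _toy_cases()
    s1 = train(SegmentationNetwork(NetConfig(**TOY_NET), seed=1000), cases, _toy_cfg(epochs=3))
    s2 = train(SegmentationNetwork(NetConfig(**TOY_NET), seed=1000), cases, _toy_cfg(epochs=3))
    assert s1.losses == s2.losses


def test_max_steps_caps_updates():
    cases = _toy_cases()
    net = SegmentationNetwork(NetConfig(**TOY_NET), seed=0)
    state = train(net, cases, _toy_cfg(epochs=8), max_steps=3)
    assert state.steps == 3


def test_training_rejects_empty_case_list():
    net = SegmentationNetwork(NetConfig(**TOY_NET), seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(net, [], _toy_cfg())
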