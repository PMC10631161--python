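"""Overlap and surface metrics against exact counting and brute-force oracles."""

import numpy as np
import pytest

from adreseg.metrics import asd, dice, evaluate_case, hausdorff, iou, mae, surface_voxels


# ---------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------

def brute_directed_max(a, b):
    return max(min(np.linalg.norm(p - q) for q in b) for p in a)


def brute_directed_mean(a, b):
    return float(np.mean([min(np.linalg.norm(p - q) for q in b) for p in a]))


def brute_surface(mask):
    m = np.asarray(mask, bool)
    pts = []
    for idx in np.argwhere(m):
        x, y, z = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + d[0], y + d[1], z + d[2]
            if not (0 <= nx < m.shape[0] and 0 <= ny < m.shape[1] and 0 <= nz < m.shape[2]):
                pts.append(idx)
                break
            if not m[nx, ny, nz]:
                pts.append(idx)
                break
    return np.array(pts, float) if pts else np.empty((0, 3))


# ---------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------

def test_dice_direct_arithmetic():
    x = np.zeros((4, 4, 1), bool)
    y = np.zeros((4, 4, 1), bool)
    x.flat[:4] = True  # |X| = 4
    y.flat[1:7] = True  # |Y| = 6, |X n Y| = 3
    assert dice(x, y) == pytest.approx(0.6)
    assert iou(x, y) == pytest.approx(3 / 7)


def test_identity_and_disjoint_masks(rng):
    x = rng.random((6, 6, 6)) > 0.6
    assert dice(x, x) == 1.0 and iou(x, x) == 1.0
    y = ~x
    assert dice(x, y) == 0.0 and iou(x, y) == 0.0


def test_empty_masks_agree_perfectly():
    z = np.zeros((3, 3, 3), bool)
    assert dice(z, z) == 1.0
    assert iou(z, z) == 1.0
    assert mae(z, z) == 0.0


def test_dice_iou_identity_on_random_pairs(rng):
    for _ in range(100):
        x = rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)
        y = rng.random((8, 8, 8)) > rng.uniform(0.3, 0.9)
        j = iou(x, y)
        assert dice(x, y) == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_mae_counts_mislabeled_fraction():
    x = np.zeros((10, 10, 10), bool)
    y = x.copy()
    y[0, 0, 0] = True
    assert mae(x, y) == pytest.approx(0.001)
    assert mae(x, ~x) == 1.0


def test_grid_mismatch_is_rejected():
    with pytest.raises(ValueError, match="grid"):
        dice(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


# ---------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------

def test_single_voxel_is_its_own_surface():
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    s = surface_voxels(m)
    np.testing.assert_array_equal(s, [[2, 2, 2]])


def test_cube_surface_excludes_only_center():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    assert len(surface_voxels(m)) == 26


def test_thin_sheet_is_all_surface():
    m = np.zeros((6, 6, 3), bool)
    m[:, :, 1] = True
    assert len(surface_voxels(m)) == 36


def test_surface_coordinates_scale_with_spacing():
    m = np.zeros((4, 4, 4), bool)
    m[1, 2, 3] = True
    s = surface_voxels(m, spacing=(2.0, 0.5, 1.0))
    np.testing.assert_allclose(s, [[2.0, 1.0, 3.0]])


def test_empty_mask_has_empty_surface():
    assert surface_voxels(np.zeros((3, 3, 3), bool)).shape == (0, 3)


# ---------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------

def test_hausdorff_euclidean_example():
    assert hausdorff(np.array([[0, 0, 0]]), np.array([[3, 4, 0]])) == pytest.approx(5.0)


def test_hausdorff_is_asymmetric_in_its_directed_parts():
    a = np.array([[0.0, 0.0, 0.0]])
    b = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
    assert brute_directed_max(a, b) == 0.0
    assert brute_directed_max(b, a) == 10.0
    assert hausdorff(a, b) == pytest.approx(10.0)


def test_identical_point_sets_have_zero_distances():
    pts = np.array([[0, 0, 0], [1, 2, 3.0]])
    assert hausdorff(pts, pts) == 0.0
    assert asd(pts, pts) == 0.0


def test_asd_is_directed_as_defined():
    x = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
    y = np.array([[0.0, 0.0, 0.0]])
    assert asd(x, y) == pytest.approx(1.0)  # (0 + 2)/2
    assert asd(y, x) == pytest.approx(0.0)
    assert asd(x, y, symmetric=True) == pytest.approx(0.5)


def test_empty_point_sets_are_rejected():
    pts = np.array([[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="empty"):
        hausdorff(np.empty((0, 3)), pts)
    with pytest.raises(ValueError, match="empty"):
        asd(pts, np.empty((0, 3)))


# ---------------------------------------------------------------------
# per-case evaluation
# ---------------------------------------------------------------------

def test_identical_masks_give_perfect_metrics(rng):
    m = rng.random((10, 10, 10)) > 0.8
    cm = evaluate_case(m, m)
    assert (cm.dsc, cm.iou, cm.hausdorff, cm.asd, cm.mae) == (1.0, 1.0, 0.0, 0.0, 0.0)


def test_surface_metrics_scale_linearly_with_spacing(rng):
    pred = rng.random((12, 12, 12)) > 0.85
    truth = rng.random((12, 12, 12)) > 0.85
    a = evaluate_case(pred, truth, spacing=(1, 1, 1))
    b = evaluate_case(pred, truth, spacing=(2, 2, 2))
    assert b.hausdorff == pytest.approx(2 * a.hausdorff)
    assert b.asd == pytest.approx(2 * a.asd)


def test_empty_truth_flags_surface_metrics_undefined(rng):
    pred = rng.random((6, 6, 6)) > 0.7
    truth = np.zeros((6, 6, 6), bool)
    cm = evaluate_case(pred, truth)
    assert not cm.surface_defined
    assert np.isnan(cm.hausdorff) and np.isnan(cm.asd)
    assert 0 <= cm.mae <= 1


def test_all_metrics_match_brute_force_oracle(rng):
    """Randomized cross-validation of every metric on small masks."""
    for trial in range(50):
        shape = tuple(rng.integers(4, 17, 3))
        p_fg = rng.uniform(0.05, 0.5)
        pred = rng.random(shape) < p_fg
        truth = rng.random(shape) < p_fg
        if not pred.any() or not truth.any():
            continue
        spacing = tuple(rng.uniform(0.5, 3.0, 3))
        cm = evaluate_case(pred, truth, spacing=spacing)

        inter = np.logical_and(pred, truth).sum()
        assert cm.dsc == pytest.approx(2 * inter / (pred.sum() + truth.sum()), abs=1e-12)
        assert cm.iou == pytest.approx(inter / np.logical_or(pred, truth).sum(), abs=1e-12)
        assert cm.mae == pytest.approx(np.mean(pred != truth), abs=1e-12)

        sp = brute_surface(pred) * spacing
        st = brute_surface(truth) * spacing
        h_ref = max(brute_directed_max(sp, st), brute_directed_max(st, sp))
        asd_ref = brute_directed_mean(sp, st)
        assert cm.hausdorff == pytest.approx(h_ref, abs=1e-9)
        assert cm.asd == pytest.approx(asd_ref, abs=1e-9)
        assert cm.hausdorff >= cm.asd - 1e-12  # H(A,B) >= directed mean A->B
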