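"""Whole-volume inference: slab tiling, stitching, thresholding, heat maps.

The network consumes fixed-depth slabs, so a whole case is tiled along z
with stride ``slab_depth - overlap``; the final slab is end-aligned rather
than zero-padded, so no synthetic slices enter the network, and voxels
predicted more than once are averaged.  Volumes shorter than one slab are
symmetrically zero-padded and the prediction cropped back.
"""

from __future__ import annotations

import numpy as np

from .volio import Mask, Volume

__all__ = ["predict_volume", "binarize", "export_heatmap", "slab_starts"]


def slab_starts(depth: int, slab_depth: int, overlap: int = 0) -> list[int]:
    """Start indices of the z tiling, final slab end-aligned."""
    if overlap < 0 or overlap >= slab_depth:
        raise ValueError("overlap must satisfy 0 <= overlap < slab_depth")
    stride = slab_depth - overlap
    starts = list(range(0, max(depth - slab_depth, 0) + 1, stride))
    if starts[-1] + slab_depth < depth:
        starts.append(depth - slab_depth)
    return starts


def predict_volume(model, vol, slab_depth: int = 32, overlap: int = 0):
    """Slab-wise foreground probability for a whole preprocessed volume.

    ``vol`` may be a :class:`~adreseg.volio.Volume` (returned type matches)
    or a plain (X, Y, Z) array of normalized intensities.
    """
    is_volume = isinstance(vol, Volume)
    data = vol.data if is_volume else np.asarray(vol)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    X, Y, D = data.shape
    if X % 16 or Y % 16:
        raise ValueError(
            f"in-plane dims ({X}, {Y}) must be divisible by 16; pad or crop the volume"
        )
    if slab_depth % 16:
        raise ValueError("slab_depth must be divisible by 16")

    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    try:
        if D < slab_depth:
            lo = (slab_depth - D) // 2
            padded = np.pad(data, ((0, 0), (0, 0), (lo, slab_depth - D - lo)))
            out = _forward(model, padded)[:, :, lo : lo + D]
        else:
            acc = np.zeros(data.shape, np.float64)
            cnt = np.zeros(D, np.float64)
            for s in slab_starts(D, slab_depth, overlap):
                acc[:, :, s : s + slab_depth] += _forward(model, data[:, :, s : s + slab_depth])
                cnt[s : s + slab_depth] += 1
            out = (acc / cnt[None, None, :]).astype(np.float32)
    finally:
        if was_training and hasattr(model, "train"):
            model.train()
    if is_volume:
        return Volume(out, vol.spacing, "normalized")
    return out


def _forward(model, slab: np.ndarray) -> np.ndarray:
    x = slab[None, None].astype(np.float32)
    pred = model.forward(x) if hasattr(model, "forward") else model(x)
    arr = pred.numpy() if hasattr(pred, "numpy") else np.asarray(pred)
    return arr[0, 0]


def binarize(prob, threshold: float = 0.5):
    """Foreground where probability strictly exceeds the threshold (ties go
    to background, the majority class)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    is_volume = isinstance(prob, Volume)
    data = prob.data if is_volume else np.asarray(prob)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    out = (data > threshold).astype(np.uint8)
    if is_volume:
        return Mask(out, prob.spacing)
    return out


def export_heatmap(prob, slice_index: int, path) -> None:
    """Write one axial slice of the probability volume as a PNG with a
    red-high colormap."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = prob.data if isinstance(prob, Volume) else np.asarray(prob)
    if not 0 <= slice_index < data.shape[2]:
        raise IndexError(f"slice {slice_index} outside [0, {data.shape[2] - 1}]")
    plt.imsave(str(path), data[:, :, slice_index].T, cmap="jet", vmin=0.0, vmax=1.0)
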