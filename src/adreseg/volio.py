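"""NIfTI volume I/O and CT preprocessing.

Preprocessing mirrors the protocol used for contrast-enhanced abdominal CT
in this task: intensities are windowed at level 40 / width 300 HU (so kept
to [-110, 190]), the in-plane grid is downsampled to half size with cubic
interpolation, the z axis is resampled to 1 mm slice spacing, and the
windowed range is min-max mapped onto [0, 1].  Masks take the same
geometric path with nearest-neighbour interpolation and are never
windowed or normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "Mask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "apply_window",
    "resample_volume",
    "resampled_shape",
    "normalize_volume",
    "preprocess",
    "preprocess_mask",
]


@dataclass
class Volume:
    """A 3D image on an (x, y, z) voxel grid with per-axis spacing in mm.

    ``domain`` records whether values are on the calibrated CT scale ("HU")
    or min-max normalized to [0, 1] ("normalized").
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    domain: str = "HU"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.domain not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity domain {self.domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Mask:
    """A binary 3D grid aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path, domain: str = "HU") -> Volume:
    """Read a 3D NIfTI-1 image; header spacing is authoritative."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, np.float32), spacing, domain)


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask((np.asarray(data) > 0.5).astype(np.uint8), spacing)


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------

def apply_window(vol: Volume, level: float = 40.0, width: float = 300.0) -> Volume:
    """Clip HU values to [level - width/2, level + width/2]."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if vol.domain != "HU":
        raise ValueError("windowing expects HU input")
    lo, hi = level - width / 2.0, level + width / 2.0
    return Volume(np.clip(vol.data, lo, hi), vol.spacing, "HU")


def resampled_shape(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    inplane_factor: float = 0.5,
    target_z_spacing_mm: float = 1.0,
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Output grid and spacing of :func:`resample_volume`.

    In-plane dims scale by the factor (n_out = round(n * f), spacing / f);
    the z axis follows the grid-point convention
    n_out = round((n_in - 1) * s_in / s_out) + 1.
    """
    nx, ny, nz = shape
    sx, sy, sz = spacing
    ox = int(round(nx * inplane_factor))
    oy = int(round(ny * inplane_factor))
    oz = int(round((nz - 1) * sz / target_z_spacing_mm)) + 1
    return (ox, oy, oz), (sx / inplane_factor, sy / inplane_factor, target_z_spacing_mm)


def _resample(data: np.ndarray, out_shape, order: int) -> np.ndarray:
    zoom = [o / n for o, n in zip(out_shape, data.shape)]
    out = ndimage.zoom(np.asarray(data, np.float32), zoom, order=order, grid_mode=False, mode="nearest")
    assert out.shape == tuple(out_shape)
    return out


def resample_volume(
    vol: Volume | Mask,
    inplane_factor: float = 0.5,
    target_z_spacing_mm: float = 1.0,
):
    """Downsample in-plane and resample z to a fixed slice spacing.

    Cubic spline interpolation for images, nearest neighbour for masks
    (so masks stay binary).  Returns the same type it was given.
    """
    out_shape, out_spacing = resampled_shape(
        vol.data.shape, vol.spacing, inplane_factor, target_z_spacing_mm
    )
    if min(out_shape) < 8:
        raise ValueError(f"resampled dimension too small: {out_shape}")
    if isinstance(vol, Mask):
        data = _resample(vol.data, out_shape, order=0)
        return Mask((data > 0.5).astype(np.uint8), out_spacing)
    data = _resample(vol.data, out_shape, order=3)
    return Volume(data, out_spacing, vol.domain)


def normalize_volume(vol: Volume, level: float = 40.0, width: float = 300.0) -> Volume:
    """Min-max map the window bounds onto [0, 1].

    Normalizing against the fixed window (not per-volume extrema) keeps
    intensities comparable across cases.
    """
    if vol.domain != "HU":
        raise ValueError("volume already normalized")
    lo, hi = level - width / 2.0, level + width / 2.0
    if np.ptp(vol.data) == 0:
        # degenerate but well-defined: fixed bounds do not depend on the data
        logger.warning("constant volume passed to normalization")
    data = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    return Volume(data.astype(np.float32), vol.spacing, "normalized")


def preprocess(
    vol: Volume,
    level: float = 40.0,
    width: float = 300.0,
    inplane_factor: float = 0.5,
    target_z_spacing_mm: float = 1.0,
) -> Volume:
    """Window -> resample -> normalize, in that order."""
    out = apply_window(vol, level, width)
    out = resample_volume(out, inplane_factor, target_z_spacing_mm)
    return normalize_volume(out, level, width)


def preprocess_mask(
    mask: Mask,
    inplane_factor: float = 0.5,
    target_z_spacing_mm: float = 1.0,
) -> Mask:
    """Companion path for masks: geometric resampling only."""
    return resample_volume(mask, inplane_factor, target_z_spacing_mm)
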