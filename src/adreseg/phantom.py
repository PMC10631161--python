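"""Synthetic abdominal-CT phantoms with adrenal-style tumors.

The generator emulates the salient properties of the clinical cohort this
pipeline targets: soft-tissue-range intensities that survive a 40/300 HU
window, one or two ellipsoidal tumors per case (bilateral cases placed
mirror-symmetrically near the upper poles of two kidney-like organs),
tumor long axis of at least 10 mm, a mean tumor volume fraction around
0.267% of the scan, blurred tumor contours, heterogeneous tumor interiors
and a variable number of axial slices per case.  Ground truth is the
analytic (unblurred) ellipsoid interior, so every downstream stage can be
tested against a known answer.

Default intensity model (the clinical source gives none): background
~40 HU with 12 HU voxel noise, kidney-like organs ~100 HU, tumors
~70 +/- 15 HU with the heterogeneity field smoothed at 2 mm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, distance_matrix

from .volio import Mask, Volume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "OrganSpec",
    "make_phantom",
    "make_cohort",
    "cohort_stats",
    "write_cohort",
    "MIN_LONG_AXIS_MM",
    "DEFAULT_BILATERAL_FRACTION",
    "DEFAULT_VOLUME_FRACTION",
]

MIN_LONG_AXIS_MM = 10.0
#: cohort ratio 49 bilateral of 182 patients
DEFAULT_BILATERAL_FRACTION = 49.0 / 182.0
#: mean tumor volume fraction of a whole scan
DEFAULT_VOLUME_FRACTION = 0.00267


@dataclass(frozen=True)
class OrganSpec:
    """A kidney-like ellipsoid: center (mm), semi-axes (mm), intensity (HU)."""

    center_mm: tuple[float, float, float]
    axes_mm: tuple[float, float, float]
    hu: float = 100.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: tuple[int, int, int]
    spacing: tuple[float, float, float]
    background_hu: float = 40.0
    noise_sd: float = 12.0
    n_tumors: int = 1
    tumor_centers_mm: tuple[tuple[float, float, float], ...] = ()
    tumor_axes_mm: tuple[tuple[float, float, float], ...] = ()
    tumor_hu_mean: float = 70.0
    tumor_hu_sd: float = 15.0
    edge_blur_sigma_mm: float = 1.5
    heterogeneity_scale_mm: float = 2.0
    organs: tuple[OrganSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.grid_size) or any(s <= 0 for s in self.spacing):
            raise ValueError("grid_size and spacing must be strictly positive")
        if self.n_tumors not in (1, 2):
            raise ValueError("n_tumors must be 1 or 2")
        if len(self.tumor_axes_mm) != self.n_tumors or len(self.tumor_centers_mm) != self.n_tumors:
            raise ValueError("need one center and one axes triple per tumor")
        if self.edge_blur_sigma_mm < 0:
            raise ValueError("edge_blur_sigma_mm must be >= 0")
        extent = [n * s for n, s in zip(self.grid_size, self.spacing)]
        for ctr, axes in zip(self.tumor_centers_mm, self.tumor_axes_mm):
            if 2.0 * max(axes) < MIN_LONG_AXIS_MM:
                raise ValueError(
                    f"tumor long axis {2 * max(axes):.1f} mm below the {MIN_LONG_AXIS_MM} mm minimum"
                )
            for c, a, e in zip(ctr, axes, extent):
                if c - a < 0 or c + a > e:
                    raise ValueError(
                        f"tumor (center {ctr}, axes {axes}) extends outside the {extent} mm grid"
                    )
        if self.n_tumors == 2:
            (c1, a1), (c2, a2) = zip(self.tumor_centers_mm, self.tumor_axes_mm)
            # conservative overlap guard for axis-aligned ellipsoids
            gap = np.linalg.norm(np.subtract(c1, c2))
            if gap < max(a1) + max(a2):
                raise ValueError("tumors overlap")

    @property
    def long_axes_mm(self) -> tuple[float, ...]:
        return tuple(2.0 * max(a) for a in self.tumor_axes_mm)


@dataclass
class PhantomCase:
    image: Volume
    mask: Mask
    spec: PhantomSpec
    case_id: str = ""

    @property
    def tumor_fraction(self) -> float:
        return float(self.mask.data.mean())


# ---------------------------------------------------------------------
# single-case generation
# ---------------------------------------------------------------------

def _ellipsoid_interior(coords, center_mm, axes_mm) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center_mm
    ax, ay, az = axes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _smooth_field(rng, shape, spacing, scale_mm) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field smoothed at ``scale_mm``."""
    f = rng.standard_normal(shape).astype(np.float32)
    sigma_vox = [scale_mm / s for s in spacing]
    f = ndimage.gaussian_filter(f, sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom: organs and tumors composited over background,
    boundary-blurred, heterogeneous inside the tumor, plus voxel noise.

    Deterministic given ``spec.seed``; the mask is the analytic ellipsoid
    interior before any blurring.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_size
    sx, sy, sz = spec.spacing
    coords = np.meshgrid(
        (np.arange(nx) + 0.5) * sx,
        (np.arange(ny) + 0.5) * sy,
        (np.arange(nz) + 0.5) * sz,
        indexing="ij",
    )
    mean_img = np.full(spec.grid_size, spec.background_hu, np.float32)
    for organ in spec.organs:
        inside = _ellipsoid_interior(coords, organ.center_mm, organ.axes_mm)
        mean_img[inside] = organ.hu

    mask = np.zeros(spec.grid_size, np.uint8)
    for ctr, axes in zip(spec.tumor_centers_mm, spec.tumor_axes_mm):
        inside = _ellipsoid_interior(coords, ctr, axes)
        mean_img[inside] = spec.tumor_hu_mean
        mask[inside] = 1

    if spec.tumor_hu_sd > 0 and mask.any():
        hetero = _smooth_field(rng, spec.grid_size, spec.spacing, spec.heterogeneity_scale_mm)
        mean_img[mask == 1] += spec.tumor_hu_sd * hetero[mask == 1]

    if spec.edge_blur_sigma_mm > 0:
        mean_img = ndimage.gaussian_filter(
            mean_img, [spec.edge_blur_sigma_mm / s for s in spec.spacing]
        )

    img = mean_img
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(spec.grid_size).astype(np.float32)

    return PhantomCase(
        image=Volume(img.astype(np.float32), spec.spacing, "HU"),
        mask=Mask(mask, spec.spacing),
        spec=spec,
    )


# ---------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------

#: default per-case grid: 96 x 96 in-plane at 1.25 mm, 40-100 slices at 2 mm —
#: a cropped abdominal field of view whose volume puts a 0.267% tumor at a
#: clinically plausible ~2.4 cm long axis
DEFAULT_GRID_XY = 96
DEFAULT_SPACING = (1.25, 1.25, 2.0)
DEFAULT_SLICE_RANGE = (40, 100)


def _sample_axes(rng, target_vol_mm3: float) -> tuple[float, float, float]:
    """Semi-axes of an axis-aligned ellipsoid with the given volume and
    mild random anisotropy; the largest axis is kept >= 5 mm."""
    ratios = rng.uniform(0.6, 1.0, size=2)
    # solve a*b*c = 3V/(4pi) with b = r1*a, c = r2*a
    abc = 3.0 * target_vol_mm3 / (4.0 * np.pi)
    a = (abc / (ratios[0] * ratios[1])) ** (1.0 / 3.0)
    axes = np.array([a, a * ratios[0], a * ratios[1]])
    if axes.max() < MIN_LONG_AXIS_MM / 2.0:
        axes *= (MIN_LONG_AXIS_MM / 2.0) / axes.max()
    return tuple(float(v) for v in np.sort(axes)[::-1])


def make_cohort(
    n_cases: int,
    bilateral_fraction: float = DEFAULT_BILATERAL_FRACTION,
    volume_fraction_target: float = DEFAULT_VOLUME_FRACTION,
    seed: int = 1000,
    grid_xy: int = DEFAULT_GRID_XY,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    slice_range: tuple[int, int] = DEFAULT_SLICE_RANGE,
) -> list[PhantomCase]:
    """Generate a cohort of phantoms matching the study-level statistics.

    The expected share of bilateral (two-tumor) cases is
    ``bilateral_fraction`` and the expected per-case tumor voxel fraction is
    ``volume_fraction_target``; slice count varies uniformly over
    ``slice_range``.  Each case draws from its own RNG stream derived from
    ``(seed, case index)`` so cohorts are reproducible case by case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0 <= bilateral_fraction <= 1:
        raise ValueError("bilateral_fraction must lie in [0, 1]")
    if not 0 < volume_fraction_target < 0.05:
        raise ValueError("volume_fraction_target must lie in (0, 0.05)")

    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng([seed, i])
        nz = int(rng.integers(slice_range[0], slice_range[1] + 1))
        grid = (grid_xy, grid_xy, nz)
        extent = np.array(grid) * np.array(spacing)
        grid_vol_mm3 = float(np.prod(extent))

        bilateral = rng.random() < bilateral_fraction
        n_tumors = 2 if bilateral else 1
        # lognormal volume jitter with unit mean keeps the expected fraction on target
        jitter = float(np.exp(rng.normal(-0.5 * 0.3 ** 2, 0.3)))
        total_vol = volume_fraction_target * grid_vol_mm3 * jitter
        per_tumor_vol = total_vol / n_tumors

        # organs: two kidney-like ellipsoids flanking the mid-sagittal plane
        mid_x = extent[0] / 2.0
        organ_dx = extent[0] * 0.28
        organ_axes = (
            min(25.0, extent[0] * 0.16),
            min(18.0, extent[1] * 0.14),
            min(35.0, extent[2] * 0.30),
        )
        organ_y = extent[1] * 0.55
        organ_z = extent[2] * 0.5
        organs = (
            OrganSpec((mid_x - organ_dx, organ_y, organ_z), organ_axes),
            OrganSpec((mid_x + organ_dx, organ_y, organ_z), organ_axes),
        )

        axes = _sample_axes(rng, per_tumor_vol)
        # place near an organ's upper pole, mirrored about mid-sagittal if bilateral
        side = 1 if rng.random() < 0.5 else -1
        margin = np.array(axes) + np.array(spacing)
        pole_z = organ_z + organ_axes[2] * 0.7
        center = np.array([mid_x + side * organ_dx, organ_y * 0.8, pole_z])
        center += rng.normal(0, 2.0, size=3)
        center = np.clip(center, margin, extent - margin)
        centers = [tuple(float(v) for v in center)]
        tumor_axes = [axes]
        if bilateral:
            mirrored = center.copy()
            mirrored[0] = extent[0] - center[0]
            mirrored = np.clip(mirrored, margin, extent - margin)
            centers.append(tuple(float(v) for v in mirrored))
            tumor_axes.append(axes)

        spec = PhantomSpec(
            grid_size=grid,
            spacing=spacing,
            n_tumors=n_tumors,
            tumor_centers_mm=tuple(centers),
            tumor_axes_mm=tuple(tumor_axes),
            seed=int(rng.integers(0, 2 ** 31)),
            organs=organs,
        )
        case = make_phantom(spec)
        case.case_id = f"case_{i:04d}"
        cases.append(case)
    return cases


# ---------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------

def _component_long_axis_mm(mask: np.ndarray, spacing) -> list[float]:
    """Maximum Feret diameter (mm) of each 26-connected component."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    out = []
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab).astype(np.float64) * np.asarray(spacing)
        if len(pts) == 1:
            out.append(0.0)
            continue
        if len(pts) > 16:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # degenerate (planar) component
                pass
        d = distance_matrix(pts, pts)
        out.append(float(d.max()))
    return out


def cohort_stats(cases: list[PhantomCase]) -> dict:
    """Per-case tumor fraction, long axis and laterality, with means."""
    if not cases:
        raise ValueError("empty cohort")
    fractions, long_axes, n_tumors = [], [], []
    for c in cases:
        fractions.append(c.tumor_fraction)
        axes = _component_long_axis_mm(c.mask.data, c.mask.spacing)
        long_axes.append(max(axes) if axes else 0.0)
        n_tumors.append(len(axes))
    n_tumors = np.array(n_tumors)
    return {
        "n_cases": len(cases),
        "tumor_fraction": np.array(fractions),
        "long_axis_mm": np.array(long_axes),
        "n_tumors": n_tumors,
        "mean_tumor_fraction": float(np.mean(fractions)),
        "mean_long_axis_mm": float(np.mean(long_axes)),
        "bilateral_fraction": float(np.mean(n_tumors == 2)),
    }


def write_cohort(cases: list[PhantomCase], out_dir) -> Path:
    """Write ``case_####.nii.gz`` / ``case_####_mask.nii.gz`` plus a CSV
    manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["case_id", "n_tumors", "tumor_fraction", "long_axis_mm", "seed"])
        for i, c in enumerate(cases):
            cid = c.case_id or f"case_{i:04d}"
            write_volume(c.image, out / f"{cid}.nii.gz")
            write_mask(c.mask, out / f"{cid}_mask.nii.gz")
            wr.writerow(
                [
                    cid,
                    c.spec.n_tumors,
                    f"{c.tumor_fraction:.6f}",
                    f"{max(c.spec.long_axes_mm):.2f}",
                    c.spec.seed,
                ]
            )
    return manifest
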