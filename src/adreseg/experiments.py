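"""Scaled-down end-to-end experiments on synthetic phantoms.

The clinical protocol this pipeline mirrors trained for 1000 epochs on
182 CT cases across four GPUs; these experiments keep every pipeline
stage but shrink the problem so a run completes in minutes on one CPU
core.  Three experiments are defined:

* :func:`overfit_sanity` — can the network, Dice loss and optimizer
  memorize a handful of cases?  Uses four phantoms with large,
  sharp-edged tumors rendered directly at the network grid, so the
  memorization target is not information-limited and the result isolates
  the optimization machinery.
* :func:`generalization_smoke` — the full pipeline (phantom cohort with
  the study-condition defaults -> preprocessing -> training -> slab
  stitching -> metrics) on held-out cases.
* :func:`ablation_smoke` — the component/depth ablation harness end to
  end at toy scale.

Short-horizon runs use a learning-rate schedule rescaled for a few
hundred steps (warmup to 1e-2, log decay to 2e-3, Adam beta2 0.99); the
clinical 2e-4 -> 4e-7 schedule is tuned for a thousand-epoch horizon and
barely moves a short run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infer import binarize, predict_volume
from .metrics import evaluate_case
from .network import NetConfig, SegmentationNetwork
from .phantom import OrganSpec, PhantomCase, PhantomSpec, make_cohort, make_phantom
from .stats import run_ablation
from .trainer import TrainConfig, TrainingCase, soft_dice, split_cases, train
from .volio import preprocess, preprocess_mask

__all__ = [
    "preprocess_cases",
    "tiny_net_config",
    "tiny_train_config",
    "overfit_phantoms",
    "overfit_sanity",
    "generalization_smoke",
    "ablation_smoke",
    "ExperimentResult",
]

#: phantom grid for the generalization experiment: 128x128 in-plane at
#: 1.25 mm (preprocesses to 64x64) and 1 mm slices (z resampling is identity)
EXP_GRID_XY = 128
EXP_SPACING = (1.25, 1.25, 1.0)
EXP_SLICES = (32, 64)
EXP_SLAB = 16


def preprocess_cases(cases: list[PhantomCase], inplane_factor: float = 0.5) -> list[TrainingCase]:
    """Window/resample/normalize phantom cases into training pairs."""
    out = []
    for c in cases:
        img = preprocess(c.image, inplane_factor=inplane_factor,
                         target_z_spacing_mm=1.0)
        msk = preprocess_mask(c.mask, inplane_factor=inplane_factor,
                              target_z_spacing_mm=1.0)
        out.append(TrainingCase(img.data, msk.data, case_id=c.case_id))
    return out


def tiny_net_config(in_plane: int = 64, slab_depth: int = EXP_SLAB, **overrides) -> NetConfig:
    """Stem-8 model for the reduced experiments (bottleneck C'=128)."""
    kwargs = dict(
        input_size=(in_plane, in_plane, slab_depth),
        stem_channels=8,
        stage_channels=(16, 32, 64, 128),
        n_transformer_layers=4,
        n_heads=8,
    )
    kwargs.update(overrides)
    return NetConfig(**kwargs)


def tiny_train_config(epochs: int, seed: int = 1000, **overrides) -> TrainConfig:
    """Short-horizon training schedule for the reduced experiments."""
    kwargs = dict(
        epochs=epochs,
        batch_size=2,
        lr_initial=1e-2,
        lr_final=2e-3,
        weight_decay=1e-5,
        slab_depth=EXP_SLAB,
        seed=seed,
        schedule="log",
        warmup_epochs=max(1, epochs // 10),
        fg_slab_bias=0.5,
        adam_beta2=0.99,
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


@dataclass
class ExperimentResult:
    train_soft_dice: float
    test_metrics: pd.DataFrame | None
    steps: int
    final_loss: float

    @property
    def mean_test_dsc(self) -> float:
        return float(self.test_metrics["dsc"].mean())


def _whole_volume_soft_dice(
    net: SegmentationNetwork, cases: list[TrainingCase], slab: int, overlap: int = 8
) -> float:
    vals = []
    for c in cases:
        prob = predict_volume(net, c.image, slab_depth=slab, overlap=overlap)
        vals.append(soft_dice(prob, c.mask))
    return float(np.mean(vals))


# ---------------------------------------------------------------------
# overfit sanity
# ---------------------------------------------------------------------

def overfit_phantoms(seed: int = 1000, n_cases: int = 4) -> list[PhantomCase]:
    """Phantoms for the memorization check: large adrenal-style tumors with
    crisp margins (edge blur 0.5 mm, noise 4 HU), rendered directly on the
    64x64 network grid; every fourth case is bilateral."""
    grid = (64, 64, 32)
    spacing = (2.5, 2.5, 1.0)
    extent = np.array(grid) * np.array(spacing)
    organs = (
        OrganSpec((extent[0] * 0.22, extent[1] * 0.55, extent[2] * 0.5), (25, 18, 10)),
        OrganSpec((extent[0] * 0.78, extent[1] * 0.55, extent[2] * 0.5), (25, 18, 10)),
    )
    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng([seed, i])
        bilateral = i % 4 == 3
        base = (13.0, 11.0, 8.0) if bilateral else (18.0, 15.0, 8.0)
        axes = tuple(float(a) for a in np.array(base) * rng.uniform(0.92, 1.08, 3))
        c1 = (extent[0] * 0.25, extent[1] * 0.42, extent[2] * 0.5)
        centers = [c1] + ([(extent[0] * 0.75, c1[1], c1[2])] if bilateral else [])
        spec = PhantomSpec(
            grid_size=grid,
            spacing=spacing,
            n_tumors=len(centers),
            tumor_centers_mm=tuple(centers),
            tumor_axes_mm=tuple([axes] * len(centers)),
            seed=int(rng.integers(0, 2 ** 31)),
            organs=organs,
            edge_blur_sigma_mm=0.5,
            noise_sd=4.0,
        )
        case = make_phantom(spec)
        case.case_id = f"overfit_{i}"
        cases.append(case)
    return cases


def overfit_sanity(seed: int = 1000, n_cases: int = 4, max_steps: int = 300) -> ExperimentResult:
    """Overfit the tiny model on a handful of phantoms.

    A functioning network, loss and optimizer should drive the train-set
    whole-volume soft Dice above 0.95 within ``max_steps`` optimizer
    updates.  Preprocessing is the intensity path only (factor-1.0
    resampling): the phantoms already live on the network grid.
    """
    cohort = overfit_phantoms(seed, n_cases)
    cases = []
    for c in cohort:
        img = preprocess(c.image, inplane_factor=1.0, target_z_spacing_mm=c.image.spacing[2])
        msk = preprocess_mask(c.mask, inplane_factor=1.0, target_z_spacing_mm=c.mask.spacing[2])
        cases.append(TrainingCase(img.data, msk.data, case_id=c.case_id))
    steps_per_epoch = max(1, int(np.ceil(n_cases / 2)))
    cfg = tiny_train_config(epochs=max(1, max_steps // steps_per_epoch), seed=seed, warmup_epochs=15)
    net = SegmentationNetwork(tiny_net_config(dropout=0.0), seed=seed)
    state = train(net, cases, cfg, max_steps=max_steps)
    net.eval()
    sd = _whole_volume_soft_dice(net, cases, cfg.slab_depth)
    return ExperimentResult(sd, None, state.steps, state.losses[-1])


# ---------------------------------------------------------------------
# generalization smoke
# ---------------------------------------------------------------------

def generalization_smoke(
    seed: int = 1000, n_cases: int = 25, epochs: int = 45
) -> ExperimentResult:
    """Full pipeline on the study-condition cohort defaults: 25 phantoms,
    80/20 case split (20 train / 5 test), training, slab-stitching
    inference and the five metrics on held-out cases."""
    cohort = make_cohort(
        n_cases, seed=seed, grid_xy=EXP_GRID_XY, spacing=EXP_SPACING, slice_range=EXP_SLICES
    )
    cases = preprocess_cases(cohort)
    train_cases, test_cases = split_cases(cases, 0.8, seed)
    cfg = tiny_train_config(epochs=epochs, seed=seed)
    net = SegmentationNetwork(tiny_net_config(), seed=seed)
    state = train(net, train_cases, cfg, stop_loss=0.03)
    net.eval()
    rows = []
    spacing = (2.5, 2.5, 1.0)  # post-preprocessing voxel size of the phantom grid
    for c in test_cases:
        prob = predict_volume(net, c.image, slab_depth=cfg.slab_depth, overlap=8)
        pred = binarize(prob)
        rows.append(evaluate_case(pred, c.mask, spacing=spacing, case_id=c.case_id).as_dict())
    sd = _whole_volume_soft_dice(net, train_cases, cfg.slab_depth)
    return ExperimentResult(sd, pd.DataFrame(rows), state.steps, state.losses[-1])


# ---------------------------------------------------------------------
# ablation smoke
# ---------------------------------------------------------------------

def ablation_smoke(seed: int = 1000, n_cases: int = 5, epochs: int = 6):
    """Component and transformer-depth ablation tables at toy scale.

    Uses 32x32x32 slabs (token dim 8) so every transformer depth in the
    grid trains in seconds; returns (component table, depth table).
    """
    cohort = make_cohort(
        n_cases, seed=seed, grid_xy=64, spacing=EXP_SPACING, slice_range=(36, 44)
    )
    cases = preprocess_cases(cohort)
    train_cases, test_cases = split_cases(cases, 0.8, seed)
    base = tiny_net_config(in_plane=32, slab_depth=32)
    cfg = tiny_train_config(epochs=epochs, seed=seed, slab_depth=32, warmup_epochs=1)
    return run_ablation(
        train_cases, test_cases, base, cfg, spacing=(2.5, 2.5, 1.0)
    )
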