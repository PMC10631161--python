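"""Method comparison statistics and the ablation harness.

Two segmentation methods are compared metric-by-metric with Levene's test
for homogeneity of variance followed by Student's t (pooled variance when
Levene does not reject at alpha, Welch's correction otherwise).  Levene's
statistic uses mean centering (the original form).  Box summaries use
linearly interpolated quartiles and Tukey 1.5*IQR whiskers.

The ablation harness retrains the network with components switched off
(skip connections, transformer bottleneck, transformer depth) under an
identical training configuration and seed, and tabulates the five mean
test metrics per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "ComparisonResult",
    "BoxSummary",
    "levene_test",
    "t_test",
    "box_summary",
    "compare_methods",
    "run_ablation",
    "COMPONENT_GRID",
    "DEPTH_GRID",
]


@dataclass
class ComparisonResult:
    levene_statistic: float
    levene_p: float
    t_statistic: float
    t_p: float
    df: float
    variance_assumption: str  # "pooled" | "welch"
    mean_difference: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class BoxSummary:
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def levene_test(a, b) -> tuple[float, float]:
    """Levene's test (mean-centered) for equality of variances of two samples.

    W = (N - k)/(k - 1) * sum_i n_i (Zbar_i - Zbar)^2 / sum_ij (Z_ij - Zbar_i)^2
    with Z_ij = |x_ij - mean_i|; p from F(k-1, N-k).
    """
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    groups = [a, b]
    z = [np.abs(g - g.mean()) for g in groups]
    n = np.array([len(g) for g in groups], np.float64)
    N, k = n.sum(), 2
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = np.concatenate(z).mean()
    num = (N - k) * float(np.sum(n * (zbar_i - zbar) ** 2))
    den = (k - 1) * float(sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbar_i)))
    if den == 0.0:
        return 0.0, 1.0
    w = num / den
    p = float(f_dist.sf(w, k - 1, N - k))
    return float(w), p


def t_test(a, b, levene_p: float | None = None, alpha: float = 0.05) -> ComparisonResult:
    """Two-sided two-sample t test, variance assumption chosen by Levene.

    Pooled-variance Student's t when ``levene_p`` > ``alpha`` (variances
    homogeneous), Welch's t otherwise.  If ``levene_p`` is None it is
    computed here.
    """
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if levene_p is None:
        lev_stat, levene_p = levene_test(a, b)
    else:
        lev_stat = float("nan")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb
    if levene_p > alpha:
        assumption = "pooled"
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        assumption = "welch"
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = float((va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
        else:
            df = float(na + nb - 2)
    if se == 0.0:
        t_stat = 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t_stat = float(diff / se)
        p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return ComparisonResult(lev_stat, float(levene_p), t_stat, p, df, assumption, float(diff))


def box_summary(sample) -> BoxSummary:
    """Boxplot summary: linear-interpolation quartiles, Tukey whiskers,
    points beyond 1.5*IQR flagged as outliers."""
    x = np.asarray(sample, np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )


def compare_methods(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Levene-then-t comparison for each shared metric column of two
    per-case metric tables."""
    out = {}
    cols = [c for c in ("dsc", "iou", "hausdorff", "asd", "mae") if c in metrics_a and c in metrics_b]
    for col in cols:
        a = metrics_a[col].dropna().to_numpy()
        b = metrics_b[col].dropna().to_numpy()
        stat, p = levene_test(a, b)
        res = t_test(a, b, levene_p=p, alpha=alpha)
        res.levene_statistic = stat
        out[col] = res.as_dict()
    return out


# ---------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------

#: major-component rows: plain encoder-decoder, + skip connections,
#: + transformer bottleneck
COMPONENT_GRID = (
    {"use_skip": False, "use_transformer": False},
    {"use_skip": True, "use_transformer": False},
    {"use_skip": True, "use_transformer": True},
)
#: transformer-depth rows
DEPTH_GRID = (2, 4, 6, 8)


def run_ablation(
    train_cases,
    test_cases,
    base_config,
    train_config,
    component_grid=COMPONENT_GRID,
    depth_grid=DEPTH_GRID,
    spacing=(1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train every variant with the identical configuration and seed and
    evaluate on the shared test split.

    Returns (component table, depth table); the component table has one row
    per entry of ``component_grid`` with ED/SC/TF flags, the depth table one
    row per transformer depth.  Deterministic under a fixed seed.
    """
    from .infer import binarize, predict_volume
    from .metrics import evaluate_case
    from .network import SegmentationNetwork
    from .trainer import train

    for variant in component_grid:
        bad = set(variant) - {"use_skip", "use_transformer"}
        if bad:
            raise ValueError(f"unknown ablation flags: {sorted(bad)}")
        if variant.get("use_transformer") and variant.get("use_ed") is False:
            raise ValueError("transformer requires the encoder-decoder backbone")

    def _run(cfg):
        net = SegmentationNetwork(cfg, seed=train_config.seed)
        train(net, train_cases, train_config)
        rows = []
        for case in test_cases:
            prob = predict_volume(net, case.image, slab_depth=train_config.slab_depth)
            pred = binarize(prob)
            rows.append(evaluate_case(pred, case.mask, spacing=spacing).as_dict())
        df = pd.DataFrame(rows)
        return {
            "dsc": df["dsc"].mean(),
            "hausdorff": df["hausdorff"].mean(),
            "iou": df["iou"].mean(),
            "mae": df["mae"].mean(),
            "asd": df["asd"].mean(),
            "n_params": net.param_count(),
        }

    comp_rows = []
    for variant in component_grid:
        cfg = base_config.with_ablation(**variant)
        res = _run(cfg)
        comp_rows.append(
            {
                "ED_DSConv": True,
                "SC": cfg.use_skip,
                "TF": cfg.use_transformer,
                **res,
            }
        )
    comp_df = pd.DataFrame(comp_rows)

    depth_rows = []
    for depth in depth_grid:
        cfg = base_config.with_ablation(
            use_skip=True, use_transformer=True, n_transformer_layers=depth
        )
        res = _run(cfg)
        depth_rows.append({"layers": depth, **res})
    depth_df = pd.DataFrame(depth_rows)
    return comp_df, depth_df
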