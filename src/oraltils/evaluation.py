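"""Evaluation machinery: overlap metrics, consistency tests, and MCDA.

Covers the quantitative procedures used to judge both pipeline stages:

* IoU and Dice between predicted and reference pixel sets, per class;
* the dominant-cell-type generalization test (a patch is labelled by the
  most abundant predicted nucleus class and compared with its region
  label);
* the self-consistency test — agreement (IoU and a single-window SSIM)
  between predictions on original and perturbed copies of the same tile,
  usable when no ground truth exists;
* confusion-matrix summaries with per-class accuracy/precision/recall/F1;
* entropy-weighted TOPSIS ranking of competing models over a benefit-type
  decision matrix (criterion weights from the dispersion of each column,
  closeness from distances to the ideal and anti-ideal alternatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .weak_supervision import DEFAULT_PALETTE, Palette, render_density_map

__all__ = [
    "SSIMParams",
    "iou",
    "dice",
    "dominant_cell_label",
    "confusion_matrix",
    "per_class_metrics",
    "ssim",
    "self_consistency",
    "entropy_weights",
    "topsis_rank",
    "rank_models",
    "load_reference_matrix",
    "REFERENCE_BLOCKS",
]

CLASS_NAMES = {1: "tumour", 2: "tils", 3: "stroma"}

#: bundled benefit matrices (accuracy/precision/recall/F1 of 12 classifier
#: configurations) for each TIL-infiltration category and overall
REFERENCE_BLOCKS = ("none_to_very_less", "slight", "moderate_to_marked", "overall")


@dataclass(frozen=True)
class SSIMParams:
    """Stabilizing constants of the single-window structural-similarity index."""

    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _binary_sets(pred: np.ndarray, gt: np.ndarray, class_id: int):
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground-truth shapes disagree")
    return pred == class_id, gt == class_id


def iou(pred: np.ndarray, gt: np.ndarray, class_id: int) -> float:
    """|A ∩ B| / |A ∪ B| of the class-``class_id`` pixel sets (1 when both empty)."""
    a, b = _binary_sets(pred, gt, class_id)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def dice(pred: np.ndarray, gt: np.ndarray, class_id: int) -> float:
    """2|A ∩ B| / (|A| + |B|) of the class pixel sets (1 when both empty)."""
    a, b = _binary_sets(pred, gt, class_id)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def dominant_cell_label(mask: np.ndarray) -> str:
    """Name of the most abundant nucleus class (tumour/tils/stroma).

    Ties break in fixed class order (tumour < tils < stroma).  A mask with
    no scored cellular content raises.
    """
    counts = {cls: int((mask == cls).sum()) for cls in CLASS_NAMES}
    if sum(counts.values()) == 0:
        raise ValueError("no cellular content: mask has no tumour/TIL/stroma pixels")
    best = max(CLASS_NAMES, key=lambda c: (counts[c], -c))
    return CLASS_NAMES[best]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int) -> np.ndarray:
    """K x K counts; rows are true classes, columns predictions."""
    cm = np.zeros((num_classes, num_classes), np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def per_class_metrics(
    cm: np.ndarray, class_names: list[str] | None = None, percent: bool = True
) -> pd.DataFrame:
    """Accuracy/precision/recall/F1 per class plus an overall row.

    Per-class accuracy is reported as the class recall (the convention of
    one-vs-rest per-class tables: of the samples of class c, the fraction
    retrieved).  The overall row carries micro accuracy and
    support-weighted precision/recall/F1.  Empty rows or columns yield 0
    with a warning.
    """
    cm = np.asarray(cm)
    k = cm.shape[0]
    names = class_names or [f"class_{i}" for i in range(k)]
    rows = []
    support = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    for c in range(k):
        tp = cm[c, c]
        if support[c] == 0 or pred_tot[c] == 0:
            warnings.warn(f"class {names[c]} has an empty row or column; metrics set to 0")
        rec[c] = tp / support[c] if support[c] else 0.0
        prec[c] = tp / pred_tot[c] if pred_tot[c] else 0.0
        f1[c] = (
            2 * prec[c] * rec[c] / (prec[c] + rec[c]) if (prec[c] + rec[c]) > 0 else 0.0
        )
        rows.append({"class": names[c], "accuracy": rec[c], "precision": prec[c],
                     "recall": rec[c], "f1": f1[c], "support": int(support[c])})
    w = support / max(support.sum(), 1)
    rows.append(
        {
            "class": "overall",
            "accuracy": float(np.trace(cm) / max(cm.sum(), 1)),
            "precision": float((prec * w).sum()),
            "recall": float((rec * w).sum()),
            "f1": float((f1 * w).sum()),
            "support": int(support.sum()),
        }
    )
    table = pd.DataFrame(rows).set_index("class")
    if percent:
        table[["accuracy", "precision", "recall", "f1"]] *= 100.0
    return table


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Single-window SSIM over the whole image.

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
           ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

    computed from global means, variances and covariance (one window, not
    the sliding-window variant), so identical images score exactly 1.
    """
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    p = params or SSIMParams()
    xf = x.astype(np.float64).ravel()
    yf = y.astype(np.float64).ravel()
    mx, my = xf.mean(), yf.mean()
    vx, vy = xf.var(), yf.var()
    cov = ((xf - mx) * (yf - my)).mean()
    return float(
        (2 * mx * my + p.c1) * (2 * cov + p.c2)
        / ((mx**2 + my**2 + p.c1) * (vx + vy + p.c2))
    )


def _mean_present_iou(a: np.ndarray, b: np.ndarray, num_classes: int = 5) -> float:
    """Macro IoU over the classes present in either mask of the pair."""
    present = [c for c in range(num_classes) if (a == c).any() or (b == c).any()]
    return float(np.mean([iou(a, b, c) for c in present]))


def self_consistency(
    predict_fn,
    images,
    transform: str = "horizontal_flip",
    noise_sigma: float = 10.0,
    seed: int = 0,
    palette: Palette = DEFAULT_PALETTE,
    ssim_params: SSIMParams | None = None,
) -> pd.DataFrame:
    """Prediction agreement between original and perturbed copies of tiles.

    ``predict_fn`` maps a uint8 RGB tile to an integer label mask.  For the
    geometric transform (``horizontal_flip``) the perturbed prediction is
    flipped back before comparison; ``gaussian_noise`` adds seeded pixel
    noise of the given sigma.  Per tile the macro IoU over classes present
    in either mask and the SSIM of the two rendered density maps are
    reported; the DataFrame carries per-image rows, with means available
    via ``.mean()``.
    """
    if transform not in ("horizontal_flip", "gaussian_noise"):
        raise ValueError("transform must be 'horizontal_flip' or 'gaussian_noise'")
    rng = np.random.default_rng(seed)
    rows = []
    for i, img in enumerate(images):
        base = predict_fn(img)
        if transform == "horizontal_flip":
            aug = predict_fn(img[:, ::-1])[:, ::-1]  # undo the flip before comparing
        else:
            noisy = img.astype(np.float32) + rng.normal(0.0, noise_sigma, img.shape)
            aug = predict_fn(np.clip(noisy, 0, 255).astype(np.uint8))
        rows.append(
            {
                "image": i,
                "iou": _mean_present_iou(base, aug),
                "ssim": ssim(
                    render_density_map(base, palette),
                    render_density_map(aug, palette),
                    ssim_params,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("image")


# ---------------------------------------------------------------------------
# entropy weighting + TOPSIS
# ---------------------------------------------------------------------------

def entropy_weights(matrix: pd.DataFrame) -> pd.Series:
    """Information-entropy criterion weights for a positive benefit matrix.

    Column shares p_ij = x_ij / sum_i x_ij give each criterion a Shannon
    entropy E_j = -(1/ln m) sum_i p_ij ln p_ij (0 ln 0 := 0); the weight is
    the normalized divergence w_j = (1 - E_j) / sum_k (1 - E_k).  A
    criterion identical across alternatives carries zero weight; if every
    criterion is constant the weights are undefined and an error is raised.
    """
    x = matrix.to_numpy(dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("entropy weighting needs at least two alternatives")
    if (x <= 0).any():
        raise ValueError("decision matrix must be strictly positive")
    p = x / x.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=0) / np.log(x.shape[0])
    divergence = 1.0 - entropy
    total = divergence.sum()
    if total <= 1e-15:
        raise ValueError("all criteria are constant; entropy weights are undefined")
    return pd.Series(divergence / total, index=matrix.columns)


def topsis_rank(
    matrix: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    normalization: str = "vector",
) -> pd.DataFrame:
    """Closeness-to-ideal scores and ranks for benefit criteria.

    Columns are normalized (``vector``: x / ||x||_2 per column, the usual
    companion of entropy weighting; ``minmax`` provided as an alternative),
    weighted, and each alternative scored by C = D- / (D+ + D-) with D+/D-
    the Euclidean distances to the per-column max (ideal) and min
    (anti-ideal).  Ranks descend by closeness with ties broken by input
    order.
    """
    x = matrix.to_numpy(dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("TOPSIS needs at least two alternatives")
    w = np.asarray(weights, dtype=np.float64)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    if normalization == "vector":
        r = x / np.sqrt((x**2).sum(axis=0))
    elif normalization == "minmax":
        span = x.max(axis=0) - x.min(axis=0)
        r = (x - x.min(axis=0)) / np.where(span > 0, span, 1.0)
    else:
        raise ValueError("normalization must be 'vector' or 'minmax'")
    v = r * w
    ideal = v.max(axis=0)
    anti = v.min(axis=0)
    d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((v - anti) ** 2).sum(axis=1))
    closeness = d_neg / (d_pos + d_neg)
    order = np.lexsort((np.arange(len(closeness)), -closeness))
    ranks = np.empty(len(closeness), np.int64)
    ranks[order] = np.arange(1, len(closeness) + 1)
    return pd.DataFrame(
        {"closeness": closeness, "rank": ranks}, index=matrix.index
    )


def rank_models(matrix: pd.DataFrame, normalization: str = "vector") -> pd.DataFrame:
    """Entropy-weighted TOPSIS in one call, sorted best-first."""
    scores = topsis_rank(matrix, entropy_weights(matrix), normalization)
    return scores.sort_values("rank")


def load_reference_matrix(block: str) -> pd.DataFrame:
    """Load a bundled reference decision matrix.

    The four blocks hold the published accuracy/precision/recall/F1 (in
    percent) of twelve TIL-classifier configurations — image-only,
    density-map-only and fused, each under four optimizer/learning-rate
    settings — for the three infiltration categories and overall.
    """
    if block not in REFERENCE_BLOCKS:
        raise ValueError(f"block must be one of {REFERENCE_BLOCKS}")
    ref = resources.files("oraltils.data").joinpath(f"tilclass_metrics_{block}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)
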