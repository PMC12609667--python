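"""Confusion-matrix metrics and bootstrap model comparison.

The confusion matrix accumulates joint pixel counts ``n[i][j]`` (reference
class i, predicted class j) over a whole test set; mIoU, accuracy,
precision/recall/F1 (foreground class by default) and Cohen's kappa all
derive from it.  Per-image score lists feed a paired percentile bootstrap
for comparing two models on the same test images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np


class ConfusionMatrix:
    """Pixel-count confusion matrix ``n[i][j]`` for ``nc`` classes."""

    def __init__(self, num_classes: int = 2, counts: np.ndarray | None = None):
        if counts is not None:
            counts = np.asarray(counts, dtype=np.int64)
            if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
                raise ValueError("counts must be a square matrix")
            if (counts < 0).any():
                raise ValueError("counts must be nonnegative")
            self.n = counts.copy()
        else:
            self.n = np.zeros((num_classes, num_classes), dtype=np.int64)

    @property
    def num_classes(self) -> int:
        return self.n.shape[0]

    @property
    def total(self) -> int:
        return int(self.n.sum())

    @classmethod
    def from_binary_counts(cls, tp: int, fn: int, fp: int, tn: int) -> "ConfusionMatrix":
        """Binary matrix with class 1 = foreground: n = [[TN, FP], [FN, TP]]."""
        return cls(counts=np.array([[tn, fp], [fn, tp]], dtype=np.int64))

    def accumulate(self, pred: np.ndarray, ref: np.ndarray) -> "ConfusionMatrix":
        pred = np.asarray(pred)
        ref = np.asarray(ref)
        if pred.shape != ref.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
        nc = self.num_classes
        if pred.max(initial=0) >= nc or ref.max(initial=0) >= nc:
            raise ValueError(f"mask values must be < {nc}")
        idx = ref.astype(np.int64).ravel() * nc + pred.astype(np.int64).ravel()
        self.n += np.bincount(idx, minlength=nc * nc).reshape(nc, nc)
        return self

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(counts=self.n + other.n)

    def __repr__(self):
        return f"ConfusionMatrix({self.n.tolist()})"


def accumulate(pred, ref, cm: ConfusionMatrix | None = None) -> ConfusionMatrix:
    """Functional form: add one prediction/reference pair into ``cm``."""
    cm = cm if cm is not None else ConfusionMatrix()
    return cm.accumulate(pred, ref)


def per_class_iou(cm: ConfusionMatrix) -> np.ndarray:
    """IoU per class; NaN marks classes with empty union."""
    n = cm.n.astype(np.float64)
    inter = np.diag(n)
    union = n.sum(axis=1) + n.sum(axis=0) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, np.nan)
    return iou


def miou(cm: ConfusionMatrix) -> float:
    """Mean IoU over classes; zero-union classes are excluded with a warning."""
    iou = per_class_iou(cm)
    valid = ~np.isnan(iou)
    if not valid.any():
        raise ValueError("no class has a nonzero union")
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} zero-union class(es) from mIoU",
            stacklevel=2,
        )
    return float(iou[valid].mean())


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.n) / cm.total)


def precision_recall(cm: ConfusionMatrix, foreground: int = 1) -> tuple[float, float]:
    n = cm.n
    tp = float(n[foreground, foreground])
    fp = float(n[:, foreground].sum() - tp)
    fn = float(n[foreground, :].sum() - tp)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    return prec, rec


def f1(cm: ConfusionMatrix, foreground: int = 1, average: str = "foreground") -> float:
    """F1 = 2PR/(P+R); foreground-only by default, macro over classes optionally.

    Degenerate denominators yield 0 with a warning.
    """
    if average == "macro":
        vals = [f1(cm, foreground=c) for c in range(cm.num_classes)]
        return float(np.mean(vals))
    p, r = precision_recall(cm, foreground)
    if p + r == 0:
        warnings.warn("undefined F1 (no true/predicted foreground); reporting 0", stacklevel=2)
        return 0.0
    return 2.0 * p * r / (p + r)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa (po - pe) / (1 - pe); degenerate pe = 1 reports 0."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.n.astype(np.float64)
    po = np.trace(n) / total
    pe = float((n.sum(axis=1) * n.sum(axis=0)).sum()) / (float(total) ** 2)
    if abs(1.0 - pe) < 1e-15:
        warnings.warn("degenerate single-class matrix (pe = 1); kappa reported as 0", stacklevel=2)
        return 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class MetricsReport:
    miou: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    per_class_iou: list[float]
    confusion: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compute_report(cm: ConfusionMatrix, foreground: int = 1) -> MetricsReport:
    p, r = precision_recall(cm, foreground)
    return MetricsReport(
        miou=miou(cm),
        accuracy=accuracy(cm),
        precision=p,
        recall=r,
        f1=f1(cm, foreground),
        kappa=kappa(cm),
        per_class_iou=[float(v) for v in per_class_iou(cm)],
        confusion=cm.n.tolist(),
    )


@dataclass
class BootstrapResult:
    n_resamples: int
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    diff_mean: float
    diff_ci: tuple[float, float]
    significant: bool
    resampled_diffs: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "n_resamples": self.n_resamples,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "ci_a": list(self.ci_a),
            "ci_b": list(self.ci_b),
            "diff_mean": self.diff_mean,
            "diff_ci": list(self.diff_ci),
            "significant": self.significant,
        }


def bootstrap_compare(scores_a, scores_b, n_resamples: int = 10_000,
                      seed: int = 0, keep_diffs: bool = True) -> BootstrapResult:
    """Paired percentile bootstrap over images.

    Images (not pixels) are resampled with replacement, the same indices for
    both models; 2.5/97.5 percentile intervals are reported for each model's
    mean score and for the paired difference (b - a).  The difference is
    significant when its interval excludes zero.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("score lists must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("score lists must be non-empty")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_resamples, a.size))
    means_a = a[idx].mean(axis=1)
    means_b = b[idx].mean(axis=1)
    diffs = means_b - means_a
    lo, hi = 2.5, 97.5
    ci_a = tuple(np.percentile(means_a, [lo, hi]))
    ci_b = tuple(np.percentile(means_b, [lo, hi]))
    diff_ci = tuple(np.percentile(diffs, [lo, hi]))
    significant = bool(diff_ci[0] > 0.0 or diff_ci[1] < 0.0)
    return BootstrapResult(
        n_resamples=n_resamples,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        diff_mean=float(b.mean() - a.mean()),
        diff_ci=(float(diff_ci[0]), float(diff_ci[1])),
        significant=significant,
        resampled_diffs=diffs if keep_diffs else None,
    )
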