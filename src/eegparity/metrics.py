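"""Performance metrics and the paired sign-flip permutation test.

Balanced accuracy (BA) is the mean of sensitivity and specificity; the
Matthews correlation coefficient (MCC) summarizes the whole confusion
matrix and stays informative under the heavy non-target:target class
imbalance of RSVP calibration (about 10:1).  Per-subject metric vectors
from the two filtering conditions are compared with a two-tailed paired
permutation t-test built from random sign flips of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricResult",
    "PermutationTestConfig",
    "PermutationTestResult",
    "balanced_accuracy",
    "matthews_cc",
    "paired_permutation_test",
]


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionMatrix":
        labels = np.asarray(labels).astype(bool)
        predictions = np.asarray(predictions).astype(bool)
        if labels.shape != predictions.shape:
            raise ValueError("labels and predictions must have equal length")
        return cls(tp=int(np.sum(labels & predictions)),
                   tn=int(np.sum(~labels & ~predictions)),
                   fp=int(np.sum(~labels & predictions)),
                   fn=int(np.sum(labels & ~predictions)))

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """(TPR + TNR) / 2; undefined (raises) when a class is empty."""
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    tpr = cm.tp / cm.n_positive
    tnr = cm.tn / cm.n_negative
    return (tpr + tnr) / 2.0


def matthews_cc(cm: ConfusionMatrix) -> float:
    """(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Any zero factor in the denominator (a degenerate prediction or class)
    yields 0 by convention: no better than a random prediction.
    """
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
             * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


@dataclass
class MetricResult:
    """Cross-validated (or single-shot) BA/MCC summary."""

    ba: float
    mcc: float
    tpr: float = float("nan")
    tnr: float = float("nan")
    fold_ba: np.ndarray = field(default_factory=lambda: np.empty(0))
    fold_mcc: np.ndarray = field(default_factory=lambda: np.empty(0))
    ba_sd: float = float("nan")
    mcc_sd: float = float("nan")
    chosen_params: Optional[dict] = None


@dataclass
class PermutationTestConfig:
    n_permutations: int = 50_000
    alpha: float = 0.05
    two_tailed: bool = True
    df: Optional[int] = None  # defaults to n_subjects - 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PermutationTestResult:
    t_observed: float
    p_value: float
    threshold: float  # two-tailed t-quantile at alpha (cluster-forming)
    df: int
    n_permutations: int


def _paired_t(d: np.ndarray) -> float:
    n = d.shape[-1]
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(d.mean() / (sd / math.sqrt(n)))


def paired_permutation_test(a, b,
                            cfg: PermutationTestConfig) -> PermutationTestResult:
    """Two-tailed paired permutation t-test via random sign flips.

    The null distribution is built by flipping the sign of each paired
    difference independently ``n_permutations`` times; the p-value uses
    the add-one correction (1 + #extreme) / (1 + n_permutations), which
    keeps Monte-Carlo p-values in (0, 1].  The reported ``threshold`` is
    the two-tailed t quantile at ``alpha`` (the cluster-forming threshold
    convention), computed with ``df`` degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1-D vectors, n >= 2")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not allowed")
    d = a - b
    n = d.size
    df = cfg.df if cfg.df is not None else n - 1
    threshold = float(stats.t.ppf(1 - cfg.alpha / 2, df))

    t_obs = _paired_t(d)
    if np.all(d == 0):
        return PermutationTestResult(0.0, 1.0, threshold, df,
                                     cfg.n_permutations)

    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, n))
    dp = signs * d[None, :]
    means = dp.mean(axis=1)
    sds = dp.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / math.sqrt(n)),
                          np.where(means == 0, 0.0, np.inf))
    n_extreme = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + n_extreme) / (1 + cfg.n_permutations)
    return PermutationTestResult(t_obs, float(p), threshold, df,
                                 cfg.n_permutations)
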