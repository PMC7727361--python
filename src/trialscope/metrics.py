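"""Shared evaluation kernel: confusion metrics, Brier score, concordance
statistic, reliability binning, and the percentile bootstrap.

All metrics treat labels as binary (positive = True/1). Ratios with a zero
denominator are reported as ``None`` rather than NaN so that serialized
reports stay JSON-clean. The concordance statistic (C-statistic, equal to
the area under the ROC curve) counts tied score pairs as 1/2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Point estimates with percentile-bootstrap intervals.

    Percentile intervals are computed from resampled statistics; the point
    estimate is computed on the full data and is not guaranteed to lie
    inside the interval (it almost always does, but this is a property of
    the percentile method, not a contract).
    """

    point_estimates: dict[str, Optional[float]] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0
    level: float = 0.95
    reliability_bins: Optional[list[tuple[float, float, int]]] = None

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def confusion_metrics(pred: Sequence[bool], labels: Sequence[bool]) -> dict[str, Optional[float]]:
    pred = np.asarray(pred, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if pred.shape != labels.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {labels.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "precision": prec, "recall": sens, "f1": f1}


def brier(probs: Sequence[float], labels: Sequence[bool]) -> float:
    """Mean squared difference between probabilities and 0/1 outcomes."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.shape != labels.shape:
        raise ValueError("length mismatch")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities outside [0, 1]")
    return float(np.mean((probs - labels) ** 2))


def c_statistic(probs: Sequence[float], labels: Sequence[bool]) -> Optional[float]:
    """P(score of random positive > score of random negative), ties 1/2.

    Computed via the rank-sum identity; returns None for one-class labels.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return None
    from scipy.stats import rankdata

    ranks = rankdata(probs)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def reliability_curve(
    probs: Sequence[float], labels: Sequence[bool], n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Equal-width reliability bins on [0, 1]; empty bins omitted.

    Returns (mean predicted probability, observed frequency, count) per bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        bins.append((float(probs[mask].mean()), float(labels[mask].mean()), count))
    return bins


def percentile_bootstrap(
    stat_fn: Callable,
    data: Sequence,
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Percentile bootstrap of ``stat_fn`` over rows of ``data``.

    ``data`` may be a sequence or a tuple of parallel sequences (resampled
    jointly). A resample on which the statistic raises or returns None is
    redrawn up to ``max_retries`` times, after which the interval is absent.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(data, tuple):
        arrays = [np.asarray(a) for a in data]
        n = len(arrays[0])
        full = stat_fn(*arrays)
    else:
        arrays = [np.asarray(data)]
        n = len(arrays[0])
        full = stat_fn(arrays[0])
    stats = []
    for _ in range(n_iter):
        value = None
        for _attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                value = stat_fn(*(a[idx] for a in arrays))
            except (ValueError, ZeroDivisionError):
                value = None
            if value is not None:
                break
        if value is None:
            logger.warning("bootstrap resample statistic undefined after %d retries", max_retries)
            return full, None, None
        stats.append(value)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return full, float(lo), float(hi)
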