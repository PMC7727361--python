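"""Risk-of-bias scoring.

The overall label follows the standard rule of thumb for the first version
of the Cochrane risk-of-bias tool: a trial is at low risk of bias overall
only when every assessed domain (sequence generation, allocation
concealment, blinding, ...) is rated low; one or more high or unclear
domains make the overall rating not-low. High and unclear are merged into a
single "not_low" class because the downstream use is ranking by the
probability of being low overall, not per-domain assertions.

The predictive model is a ridge-penalized logistic regression over
unigram, bigram, and trigram bag-of-words features of title + abstract —
chosen for calibrated probabilities rather than raw accuracy. Registry
records are never scored (no training data exists for them); prediction
returns absent for them rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .metrics import (EvaluationReport, brier, c_statistic, confusion_metrics,
                      percentile_bootstrap, reliability_curve)
from .records import StudyRecord

logger = logging.getLogger(__name__)

LOW, NOT_LOW = "low", "not_low"


def derive_overall(domain_ratings: dict[str, str]) -> str:
    """"low" iff every rated domain is low; empty map is an error."""
    if not domain_ratings:
        raise ValueError("at least one domain rating is required")
    for domain, rating in domain_ratings.items():
        if rating not in ("low", "high", "unclear"):
            raise ValueError(f"unknown rating {rating!r} for domain {domain}")
    return LOW if all(r == "low" for r in domain_ratings.values()) else NOT_LOW


@dataclass
class BiasModel:
    vectorizer: CountVectorizer
    classifier: LogisticRegression
    penalty_strength: float
    decision_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def coefficient(self, ngram: str) -> Optional[float]:
        """Coefficient for an n-gram toward the low class (None if absent)."""
        idx = self.vectorizer.vocabulary_.get(ngram)
        if idx is None:
            return None
        return float(self.classifier.coef_[0, idx])


def _low_labels(corpus) -> np.ndarray:
    labels = []
    for _record, gold in corpus:
        if not gold.bias_domains:
            raise ValueError("record without domain ratings in bias training corpus")
        labels.append(derive_overall(gold.bias_domains) == LOW)
    return np.asarray(labels, dtype=bool)


def train_bias_model(corpus, penalty: Optional[float] = None, seed: int = 0) -> BiasModel:
    """Fit the n-gram logistic model on (StudyRecord, GoldLabel) pairs.

    ``penalty`` is the inverse ridge strength (C); when omitted it is
    selected on a validation split by Brier score.
    """
    labels = _low_labels(corpus)
    if labels.all() or not labels.any():
        raise ValueError("bias training corpus contains a single class")
    texts = [record.text for record, _ in corpus]
    vectorizer = CountVectorizer(ngram_range=(1, 3), min_df=2)
    X = vectorizer.fit_transform(texts)

    if penalty is None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(texts))
        n_val = max(20, len(texts) // 5)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        if len(set(labels[fit_idx])) < 2 or len(set(labels[val_idx])) < 2:
            fit_idx = val_idx = order
        best_c, best_brier = 1.0, np.inf
        for c in (0.01, 0.1, 1.0, 10.0):
            clf = LogisticRegression(C=c, max_iter=2000, random_state=seed)
            clf.fit(X[fit_idx], labels[fit_idx])
            b = brier(clf.predict_proba(X[val_idx])[:, 1], labels[val_idx])
            if b < best_brier:
                best_c, best_brier = c, b
        penalty = best_c

    clf = LogisticRegression(C=penalty, max_iter=2000, random_state=seed)
    clf.fit(X, labels)
    return BiasModel(vectorizer=vectorizer, classifier=clf, penalty_strength=penalty,
                     metadata={"n_train": len(texts), "seed": seed})


def predict_low_rob(model: BiasModel, record: StudyRecord) -> Optional[float]:
    """Probability the trial is at low risk of bias overall.

    Registry records return None (predictions are made for published
    abstracts only).
    """
    if record.source == "registry":
        logger.info("no bias prediction for registry record %s", record.record_id)
        return None
    X = model.vectorizer.transform([record.text])
    return float(model.classifier.predict_proba(X)[0, 1])


def evaluate_bias_model(model: BiasModel, corpus, n_boot: int = 1000, seed: int = 0) -> EvaluationReport:
    """Held-out precision/recall at 0.5, Brier, C-statistic, reliability bins,
    with percentile bootstrap intervals."""
    labels = _low_labels(corpus)
    probs = np.array([predict_low_rob(model, record) for record, _ in corpus], dtype=float)

    report = EvaluationReport(n_boot=n_boot, seed=seed)
    cm = confusion_metrics(probs >= model.decision_threshold, labels)
    report.point_estimates = {
        "precision": cm["precision"],
        "recall": cm["recall"],
        "brier": brier(probs, labels),
        "c_statistic": c_statistic(probs, labels),
    }
    data = (probs, labels)
    stat_fns = {
        "precision": lambda p, y: confusion_metrics(p >= model.decision_threshold, y)["precision"],
        "recall": lambda p, y: confusion_metrics(p >= model.decision_threshold, y)["recall"],
        "brier": brier,
        "c_statistic": c_statistic,
    }
    for name, fn in stat_fns.items():
        _point, lo, hi = percentile_bootstrap(fn, data, n_iter=n_boot, seed=seed)
        if lo is not None:
            report.intervals[name] = (lo, hi)
    report.reliability_bins = reliability_curve(probs, labels, n_bins=10)
    return report
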