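"""Study-design screening: RCT vs non-RCT and human vs non-human.

The RCT screener is an ensemble of a max-margin bag-of-words classifier
(linear SVM with a held-out logistic link for probability calibration) and
several independently initialized convolutional text classifiers; member
probabilities are combined by unweighted mean. For records that already
carry a manually applied publication type, a three-valued indicator
(tagged-RCT / tagged-other / untagged) is appended to the input features.

The operating threshold is "balanced": the score cut maximizing
sensitivity + specificity on a calibration split (the outer-left extreme of
the ROC curve). Because the publication-type feature shifts the score
distribution, separate thresholds are stored for indexed and not-yet-indexed
records. Threshold stability is assessed by bootstrap: each iteration sets
the threshold on a with-replacement resample and evaluates precision and
recall on the out-of-bag records.

The human-study filter is a single calibrated linear SVM trained on labels
derived from whether the "Humans" indexing term was applied (or generator
truth for synthetic corpora), thresholded at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.svm import LinearSVC

from ._nn import TextCNN
from .metrics import EvaluationReport, brier, c_statistic, confusion_metrics
from .records import StudyRecord
from .synth import HUMANS_MESH, RCT_PUBTYPE

logger = logging.getLogger(__name__)


def ptype_indicator(publication_types: set[str]) -> np.ndarray:
    """Three-valued indicator: tagged-RCT / tagged-other / untagged."""
    if not publication_types:
        return np.array([0.0, 0.0, 1.0])
    if RCT_PUBTYPE in publication_types:
        return np.array([1.0, 0.0, 0.0])
    return np.array([0.0, 1.0, 0.0])


def _calibrated_svm(seed: int) -> CalibratedClassifierCV:
    return CalibratedClassifierCV(
        LinearSVC(C=1.0, random_state=seed), method="sigmoid", cv=3
    )


@dataclass
class RctTrainConfig:
    n_cnn: int = 10
    ptyp_feature_enabled: bool = True
    seed: int = 0
    calibration_fraction: float = 0.2
    cnn_epochs: int = 8
    cnn_embed_dim: int = 16
    cnn_filters: int = 32


@dataclass
class RctEnsembleModel:
    vectorizer: TfidfVectorizer
    linear_member: CalibratedClassifierCV
    cnn_members: list[TextCNN]
    ptyp_feature_enabled: bool
    balanced_threshold_indexed: float = 0.5
    balanced_threshold_unindexed: float = 0.5
    metadata: dict = field(default_factory=dict)

    def threshold_for(self, record: StudyRecord) -> float:
        if record.publication_types:
            return self.balanced_threshold_indexed
        return self.balanced_threshold_unindexed


def _features(model_vec, texts, ptypes, enabled: bool):
    X = model_vec.transform(texts)
    if enabled:
        ind = np.vstack([ptype_indicator(p) for p in ptypes])
        X = sparse.hstack([X, sparse.csr_matrix(ind)]).tocsr()
    return X


def _require_two_classes(labels: Sequence[bool]) -> None:
    if len(set(bool(x) for x in labels)) < 2:
        raise ValueError("training corpus contains a single class")


def train_rct_ensemble(corpus, config: RctTrainConfig | None = None) -> RctEnsembleModel:
    """Train the SVM + CNN ensemble on (StudyRecord, GoldLabel) pairs."""
    config = config or RctTrainConfig()
    records = [r for r, _ in corpus]
    labels = np.array([g.is_rct for _, g in corpus], dtype=bool)
    _require_two_classes(labels)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(records))
    n_cal = max(20, int(len(records) * config.calibration_fraction))
    cal_idx, fit_idx = order[:n_cal], order[n_cal:]
    if len(set(labels[fit_idx])) < 2 or len(set(labels[cal_idx])) < 2:
        fit_idx = cal_idx = order  # tiny corpora: calibrate in-sample

    texts = [r.text for r in records]
    ptypes = [r.publication_types for r in records]

    vectorizer = TfidfVectorizer(ngram_range=(1, 2), min_df=2, sublinear_tf=True)
    vectorizer.fit([texts[i] for i in fit_idx])
    X_fit = _features(vectorizer, [texts[i] for i in fit_idx], [ptypes[i] for i in fit_idx],
                      config.ptyp_feature_enabled)
    svm = _calibrated_svm(config.seed)
    svm.fit(X_fit, labels[fit_idx])

    cnn_members = []
    n_extra = 3 if config.ptyp_feature_enabled else 0
    fit_texts = [texts[i] for i in fit_idx]
    fit_extra = np.vstack([ptype_indicator(ptypes[i]) for i in fit_idx]) if n_extra else None
    for member in range(config.n_cnn):
        cnn = TextCNN(
            embed_dim=config.cnn_embed_dim, n_filters=config.cnn_filters,
            epochs=config.cnn_epochs, n_extra=n_extra,
            seed=config.seed * 1009 + member + 1,
        )
        cnn.fit(fit_texts, labels[fit_idx], extra=fit_extra)
        cnn_members.append(cnn)

    model = RctEnsembleModel(
        vectorizer=vectorizer, linear_member=svm, cnn_members=cnn_members,
        ptyp_feature_enabled=config.ptyp_feature_enabled,
        metadata={"n_cnn": config.n_cnn, "seed": config.seed, "n_train": len(fit_idx)},
    )

    cal_records = [records[i] for i in cal_idx]
    cal_scores = predict_rct_batch(model, cal_records)
    cal_labels = labels[cal_idx]
    indexed = np.array([bool(r.publication_types) for r in cal_records])
    for mask, attr in ((indexed, "balanced_threshold_indexed"),
                       (~indexed, "balanced_threshold_unindexed")):
        if mask.sum() >= 4 and len(set(cal_labels[mask])) == 2:
            thr = select_balanced_threshold(cal_scores[mask], cal_labels[mask])
        else:
            thr = select_balanced_threshold(cal_scores, cal_labels)
        setattr(model, attr, float(thr))
    return model


def predict_rct_batch(model: RctEnsembleModel, records: Sequence[StudyRecord]) -> np.ndarray:
    texts = [r.text for r in records]
    for r in records:
        if not r.text:
            logger.warning("empty title+abstract for %s; scoring empty text", r.record_id)
    ptypes = [r.publication_types for r in records]
    X = _features(model.vectorizer, texts, ptypes, model.ptyp_feature_enabled)
    member_probs = [model.linear_member.predict_proba(X)[:, 1]]
    extra = (np.vstack([ptype_indicator(p) for p in ptypes])
             if model.ptyp_feature_enabled else None)
    for cnn in model.cnn_members:
        member_probs.append(cnn.predict_proba(texts, extra=extra))
    return np.mean(member_probs, axis=0)


def predict_rct(model: RctEnsembleModel, record: StudyRecord) -> float:
    """Mean of member probabilities for one record."""
    return float(predict_rct_batch(model, [record])[0])


def select_balanced_threshold(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Score cut maximizing sensitivity + specificity (rule: score >= cut).

    Candidate cuts are the minimum score (all positive), midpoints between
    consecutive distinct scores, and a cut just above the maximum (all
    negative). Ties in the objective are broken toward the largest cut.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0 or labels.all() or not labels.any():
        raise ValueError("both classes required to set a threshold")
    cuts = np.unique(scores)
    gap = float(np.min(np.diff(cuts))) / 2 if len(cuts) > 1 else 0.5
    candidates = np.concatenate([[cuts[0]], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1] + gap]])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores >= t
        j = (pred & labels).sum() / n_pos + (~pred & ~labels).sum() / n_neg
        if j > best_j or (j == best_j and t > best_t):
            best_t, best_j = float(t), float(j)
    return best_t


def bootstrap_threshold_stability(
    scores: Sequence[float], labels: Sequence[bool], n_iter: int = 5000, seed: int = 0
) -> EvaluationReport:
    """Out-of-bag precision/recall of the balanced-threshold rule.

    Each iteration fits the threshold on a with-replacement resample and
    evaluates on the records not drawn; iterations with a one-class resample
    or empty out-of-bag set are redrawn. The report also carries Brier score
    and C-statistic of the raw scores with bootstrap intervals.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(scores)
    rows: dict[str, list[float]] = {"precision": [], "recall": [], "brier": [], "c_statistic": []}
    done = 0
    while done < n_iter:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0 or len(set(labels[idx])) < 2 or not labels[oob].any():
            logger.debug("redrawing degenerate bootstrap resample")
            continue
        thr = select_balanced_threshold(scores[idx], labels[idx])
        cm = confusion_metrics(scores[oob] >= thr, labels[oob])
        if cm["precision"] is None:
            continue
        rows["precision"].append(cm["precision"])
        rows["recall"].append(cm["recall"])
        rows["brier"].append(brier(np.clip(scores[idx], 0, 1), labels[idx]))
        rows["c_statistic"].append(c_statistic(scores[idx], labels[idx]))
        done += 1

    thr_full = select_balanced_threshold(scores, labels)
    cm_full = confusion_metrics(scores >= thr_full, labels)
    report = EvaluationReport(n_boot=n_iter, seed=seed)
    report.point_estimates = {
        "threshold": thr_full,
        "precision": cm_full["precision"],
        "recall": cm_full["recall"],
        "brier": brier(np.clip(scores, 0, 1), labels),
        "c_statistic": c_statistic(scores, labels),
    }
    for name, vals in rows.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        report.intervals[name] = (float(lo), float(hi))
    return report


# ---------------------------------------------------------------------------
# Human vs non-human


@dataclass
class HumanModel:
    vectorizer: TfidfVectorizer
    classifier: CalibratedClassifierCV
    threshold: float = 0.5


def human_label(record: StudyRecord) -> bool:
    """Label derived from whether the "Humans" indexing term was applied."""
    return HUMANS_MESH in record.mesh_terms


def train_human_model(corpus, seed: int = 0, labels: Optional[Sequence[bool]] = None) -> HumanModel:
    records = [r for r, _ in corpus] if corpus and isinstance(corpus[0], tuple) else list(corpus)
    if labels is None:
        labels = [human_label(r) for r in records]
    labels = np.asarray(labels, dtype=bool)
    _require_two_classes(labels)
    texts = [r.text for r in records]
    vectorizer = TfidfVectorizer(ngram_range=(1, 2), min_df=2, sublinear_tf=True)
    X = vectorizer.fit_transform(texts)
    clf = _calibrated_svm(seed)
    clf.fit(X, labels)
    return HumanModel(vectorizer=vectorizer, classifier=clf)


def predict_human(model: HumanModel, record: StudyRecord) -> float:
    X = model.vectorizer.transform([record.text])
    return float(model.classifier.predict_proba(X)[0, 1])
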