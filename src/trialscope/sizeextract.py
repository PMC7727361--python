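"""Extraction of the number randomized from an abstract.

Pipeline: normalize English number words to numerals (offset-mapped), treat
every remaining integer token as a candidate (excluding percentages and
decimal fragments), describe each candidate by its context — dense word
vectors of adjacent tokens, coarse part-of-speech one-hots for surrounding
words, and indicator features such as proximity of a "patients"-variant
token or a randomization verb — score candidates with a small feed-forward
network, and return the winner when it clears the decision threshold.

The target is the number of people randomized, not the number completing
the trial. Registry records bypass the model entirely: their target sample
size field is used directly.

Word vectors are learned from the training corpus itself by positive-PMI
factorization (truncated SVD of the shifted co-occurrence matrix), so the
extractor has no external embedding dependency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import TruncatedSVD
from sklearn.neural_network import MLPClassifier

from ._text import POS_TAGS, NormalizedAbstract, normalize_numwords, pos_tag, tokenize
from .records import StudyRecord

logger = logging.getLogger(__name__)

PATIENT_VARIANTS = {
    "patients", "patient", "participants", "participant", "subjects", "subject",
    "individuals", "adults", "children", "volunteers", "men", "women", "people",
    "rats", "mice", "dogs", "piglets", "chickens", "zebrafish", "animals",
}
RANDOMIZATION_VERBS = {"randomized", "randomised", "assigned", "allocated", "enrolled", "randomly"}
MONTHS = {
    "january", "february", "march", "april", "may", "june", "july",
    "august", "september", "october", "november", "december",
}
PATIENT_WINDOW = 3   # tokens on either side for the "patients"-variant indicator
RANDOM_WINDOW = 5    # tokens for randomization-verb proximity


class SizeFeaturizer:
    """Corpus-trained dense word vectors: PPMI co-occurrence + truncated SVD."""

    def __init__(self, dim: int = 16, window: int = 3, max_vocab: int = 2000, seed: int = 0):
        self.dim = dim
        self.window = window
        self.max_vocab = max_vocab
        self.seed = seed
        self.vocab_: dict[str, int] = {}
        self.vectors_: np.ndarray | None = None

    def fit(self, texts: Sequence[str]) -> "SizeFeaturizer":
        counts: dict[str, int] = {}
        token_lists = []
        for t in texts:
            toks = [w.lower() for w, _, _ in tokenize(t)]
            token_lists.append(toks)
            for w in toks:
                counts[w] = counts.get(w, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: self.max_vocab]
        self.vocab_ = {w: i for i, (w, _) in enumerate(ranked)}
        V = len(self.vocab_)
        cooc: dict[tuple[int, int], float] = {}
        for toks in token_lists:
            ids = [self.vocab_.get(w, -1) for w in toks]
            for i, wi in enumerate(ids):
                if wi < 0:
                    continue
                for j in range(max(0, i - self.window), min(len(ids), i + self.window + 1)):
                    wj = ids[j]
                    if j == i or wj < 0:
                        continue
                    cooc[(wi, wj)] = cooc.get((wi, wj), 0.0) + 1.0
        if not cooc:
            self.vectors_ = np.zeros((V, self.dim))
            return self
        rows, cols, vals = zip(*((r, c, v) for (r, c), v in cooc.items()))
        M = sparse.coo_matrix((vals, (rows, cols)), shape=(V, V)).tocsr()
        total = M.sum()
        row_sums = np.asarray(M.sum(axis=1)).ravel()
        col_sums = np.asarray(M.sum(axis=0)).ravel()
        M = M.tocoo()
        pmi = np.log((M.data * total) / (row_sums[M.row] * col_sums[M.col]))
        ppmi = np.maximum(pmi, 0.0)
        P = sparse.coo_matrix((ppmi, (M.row, M.col)), shape=(V, V)).tocsr()
        k = min(self.dim, V - 1)
        svd = TruncatedSVD(n_components=k, random_state=self.seed)
        vecs = svd.fit_transform(P)
        if k < self.dim:
            vecs = np.pad(vecs, ((0, 0), (0, self.dim - k)))
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        self.vectors_ = vecs / np.maximum(norms, 1e-9)
        return self

    def vector(self, word: str) -> np.ndarray:
        idx = self.vocab_.get(word.lower(), -1)
        if idx < 0 or self.vectors_ is None:
            return np.zeros(self.dim)
        return self.vectors_[idx]


@dataclass
class SizeCandidate:
    value: int
    token_index: int
    norm_offsets: tuple[int, int]
    features: np.ndarray
    probability: Optional[float] = None


def _one_hot_pos(token: Optional[str]) -> np.ndarray:
    v = np.zeros(len(POS_TAGS))
    if token is not None:
        v[POS_TAGS.index(pos_tag(token))] = 1.0
    return v


def enumerate_candidates(
    norm: NormalizedAbstract, featurizer: Optional[SizeFeaturizer] = None
) -> list[SizeCandidate]:
    """One unscored candidate per integer token of the normalized text.

    Integers immediately followed by "%" or preceded by a decimal point are
    excluded. If no featurizer is supplied the embedding block is zero (the
    feature vector length is unchanged).
    """
    tokens = tokenize(norm.text)
    words = [t[0] for t in tokens]
    lowers = [w.lower() for w in words]
    dim = featurizer.dim if featurizer is not None else SizeFeaturizer().dim
    out: list[SizeCandidate] = []
    for i, (tok, start, end) in enumerate(tokens):
        if not tok.isdigit():
            continue
        nxt = words[i + 1] if i + 1 < len(words) else None
        prv = words[i - 1] if i > 0 else None
        if nxt == "%" or prv == ".":
            continue
        value = int(tok)
        if value <= 0:
            continue

        # counts precede the noun they quantify ("112 patients"), so the
        # window looks ahead, plus the immediately preceding token
        lo = max(0, i - 1)
        hi = min(len(words), i + PATIENT_WINDOW + 1)
        near_patients = float(any(w in PATIENT_VARIANTS for w in lowers[lo:hi] if w != tok))
        lo2 = max(0, i - RANDOM_WINDOW)
        hi2 = min(len(words), i + RANDOM_WINDOW + 1)
        near_random = float(any(w in RANDOMIZATION_VERBS for w in lowers[lo2:hi2]))
        percent_context = float(nxt is not None and nxt.lower() in ("%", "percent"))
        year_range = float(1900 <= value <= 2099)
        near_month_or_paren = float(
            (prv in ("(",) or nxt in (")",))
            or (prv is not None and prv.lower() in MONTHS)
            or (nxt is not None and nxt.lower() in MONTHS)
        )
        prev_vec = featurizer.vector(prv) if (featurizer and prv) else np.zeros(dim)
        next_vec = featurizer.vector(nxt) if (featurizer and nxt) else np.zeros(dim)
        features = np.concatenate([
            prev_vec, next_vec,
            _one_hot_pos(prv), _one_hot_pos(nxt),
            [near_patients, near_random, percent_context, year_range,
             near_month_or_paren, math.log1p(value) / 10.0],
        ])
        out.append(SizeCandidate(value=value, token_index=i,
                                 norm_offsets=(start, end), features=features))
    return out


@dataclass
class SizeModel:
    network: MLPClassifier
    featurizer: SizeFeaturizer
    decision_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)


@dataclass
class SizeTrainConfig:
    seed: int = 0
    hidden: tuple[int, ...] = (32,)
    holdout_fraction: float = 0.2
    embed_dim: int = 16


def _candidate_matrix(records, golds, featurizer):
    """Per-abstract candidates and positive flags against gold sizes."""
    per_abstract = []
    for record, gold_size in zip(records, golds):
        norm = normalize_numwords(record.abstract)
        cands = enumerate_candidates(norm, featurizer)
        flags = [gold_size is not None and c.value == gold_size for c in cands]
        per_abstract.append((cands, flags, gold_size))
    return per_abstract


def _extraction_prf(per_abstract, probs_by_abstract, threshold):
    tp = fp = fn = 0
    for (cands, _flags, gold_size), probs in zip(per_abstract, probs_by_abstract):
        pred = None
        if cands:
            best = max(range(len(cands)), key=lambda k: (probs[k], cands[k].value))
            if probs[best] >= threshold:
                pred = cands[best].value
        if pred is not None and gold_size is not None and pred == gold_size:
            tp += 1
        elif pred is not None:
            fp += 1
        if gold_size is not None and (pred is None or pred != gold_size):
            fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def train_size_model(corpus, config: SizeTrainConfig | None = None) -> SizeModel:
    """Train the candidate scorer; threshold tuned on a held-out split by F1."""
    config = config or SizeTrainConfig()
    records = [r for r, _ in corpus]
    golds = [g.sample_size for _, g in corpus]
    if not any(g is not None for g in golds):
        raise ValueError("no abstracts with a gold sample size")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(records))
    n_hold = max(10, int(len(records) * config.holdout_fraction))
    hold_idx, fit_idx = order[:n_hold], order[n_hold:]

    featurizer = SizeFeaturizer(dim=config.embed_dim, seed=config.seed)
    featurizer.fit([records[i].abstract for i in fit_idx])

    fit_pa = _candidate_matrix([records[i] for i in fit_idx], [golds[i] for i in fit_idx], featurizer)
    X, y = [], []
    for cands, flags, _gold in fit_pa:
        for c, f in zip(cands, flags):
            X.append(c.features)
            y.append(f)
    if not any(y):
        raise ValueError("no positive size candidates in training corpus")
    X = np.vstack(X)
    y = np.asarray(y, dtype=bool)
    net = MLPClassifier(hidden_layer_sizes=config.hidden, random_state=config.seed,
                        max_iter=400, early_stopping=False)
    net.fit(X, y)

    hold_pa = _candidate_matrix([records[i] for i in hold_idx], [golds[i] for i in hold_idx], featurizer)
    probs_by_abstract = []
    for cands, _flags, _gold in hold_pa:
        if cands:
            probs_by_abstract.append(net.predict_proba(np.vstack([c.features for c in cands]))[:, 1])
        else:
            probs_by_abstract.append(np.array([]))
    best_thr, best_f1 = 0.5, -1.0
    for thr in np.linspace(0.05, 0.95, 19):
        _p, _r, f1 = _extraction_prf(hold_pa, probs_by_abstract, thr)
        if f1 > best_f1:
            best_thr, best_f1 = float(thr), f1
    return SizeModel(network=net, featurizer=featurizer, decision_threshold=best_thr,
                     metadata={"holdout_f1": best_f1, "seed": config.seed})


def score_candidates(model: SizeModel, norm: NormalizedAbstract) -> list[SizeCandidate]:
    cands = enumerate_candidates(norm, model.featurizer)
    if cands:
        probs = model.network.predict_proba(np.vstack([c.features for c in cands]))[:, 1]
        for c, p in zip(cands, probs):
            c.probability = float(p)
    return cands


def extract_sample_size(model: SizeModel, record: StudyRecord) -> Optional[int]:
    """Highest-probability candidate above threshold; ties favor the larger
    integer. Registry records use the target sample size field directly."""
    if record.source == "registry":
        return record.registry_fields.target_sample_size
    cands = score_candidates(model, normalize_numwords(record.abstract))
    if not cands:
        return None
    best = max(cands, key=lambda c: (c.probability, c.value))
    if best.probability >= model.decision_threshold:
        return best.value
    return None
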