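"""PICO span tagging, abbreviation expansion, and concept linking.

Span tagging is token-level sequence labeling over a BIO scheme with three
facets (population, intervention, outcome; interventions and comparators
share one label). The tagger is a linear-chain structured model — an
averaged structured perceptron over lexical context features with Viterbi
decoding under BIO-consistent transition constraints — trained directly on
gold spans. Decoded label runs are converted back to character spans.

Concept linking follows the dictionary-lookup approach of lightweight
metathesaurus matchers: every vocabulary synonym is minimally normalized
(trailing bracket tags such as "[NOS]" stripped, lowercased, whitespace
collapsed) into a token-sequence index; abbreviations inside a snippet are
first expanded using definitions found anywhere in the abstract (long form
immediately preceding a parenthesized short form, characters matched in
order); then the snippet is scanned longest-match-first, non-overlapping,
case-insensitively. Strict evaluation counts exact concept matches;
relaxed evaluation additionally accepts immediate parent or child concepts.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._text import tokenize
from .metrics import percentile_bootstrap
from .records import PICO_FACETS, ConceptAssignment, PicoSpan
from .vocab import Vocabulary

logger = logging.getLogger(__name__)

LABELS = ("O",) + tuple(f"{p}-{f}" for f in PICO_FACETS for p in ("B", "I"))
_LABEL_IDX = {lab: i for i, lab in enumerate(LABELS)}


def _allowed_transition(prev: str, cur: str) -> bool:
    if not cur.startswith("I-"):
        return True
    facet = cur[2:]
    return prev in (f"B-{facet}", f"I-{facet}")


def _shape(word: str) -> str:
    if word.isdigit():
        return "d"
    if word.isupper():
        return "U"
    if word[:1].isupper():
        return "C"
    return "x"


def _token_features(words: list[str], i: int) -> list[str]:
    w = words[i]
    low = w.lower()
    prev = words[i - 1].lower() if i > 0 else "<s>"
    nxt = words[i + 1].lower() if i + 1 < len(words) else "</s>"
    prev2 = words[i - 2].lower() if i > 1 else "<s>"
    nxt2 = words[i + 2].lower() if i + 2 < len(words) else "</s>"
    return [
        f"w={low}", f"p={prev}", f"n={nxt}", f"p2={prev2}", f"n2={nxt2}",
        f"pw={prev}|{low}", f"wn={low}|{nxt}",
        f"sfx={low[-3:]}", f"pfx={low[:2]}", f"sh={_shape(w)}",
    ]


@dataclass
class SpanTagger:
    """Linear-chain BIO tagger (averaged structured perceptron)."""

    weights: dict = field(default_factory=dict)          # (feature, label_idx) -> float
    transitions: np.ndarray = field(default_factory=lambda: np.zeros((len(LABELS), len(LABELS))))
    metadata: dict = field(default_factory=dict)

    def _emission_scores(self, feats_per_token) -> np.ndarray:
        L = len(LABELS)
        scores = np.zeros((len(feats_per_token), L))
        for t, feats in enumerate(feats_per_token):
            for f in feats:
                row = self.weights.get(f)
                if row is not None:
                    scores[t] += row
        return scores

    def decode(self, words: list[str]) -> list[str]:
        if not words:
            return []
        feats = [_token_features(words, i) for i in range(len(words))]
        em = self._emission_scores(feats)
        L = len(LABELS)
        T = len(words)
        NEG = -1e12
        delta = np.full((T, L), NEG)
        back = np.zeros((T, L), dtype=int)
        for lab in range(L):
            if not LABELS[lab].startswith("I-"):
                delta[0, lab] = em[0, lab]
        mask = np.array([[_allowed_transition(LABELS[a], LABELS[b]) for b in range(L)]
                         for a in range(L)])
        trans = np.where(mask, self.transitions, NEG)
        for t in range(1, T):
            cand = delta[t - 1][:, None] + trans
            back[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + em[t]
        path = [int(delta[T - 1].argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return [LABELS[i] for i in reversed(path)]


def _gold_bio(words_offsets, spans: list[PicoSpan]) -> list[str]:
    labels = []
    for _w, start, end in words_offsets:
        tag = "O"
        for sp in spans:
            if start >= sp.start and end <= sp.end:
                prefix = "B" if start == sp.start else "I"
                tag = f"{prefix}-{sp.label}"
                break
        labels.append(tag)
    return labels


@dataclass
class TaggerTrainConfig:
    epochs: int = 6
    seed: int = 0


def train_span_tagger(corpus, config: TaggerTrainConfig | None = None) -> SpanTagger:
    """Train on (StudyRecord, GoldLabel) pairs with gold spans."""
    config = config or TaggerTrainConfig()
    examples = []
    n_spans = 0
    for record, gold in corpus:
        toks = tokenize(record.abstract)
        if not toks:
            continue
        words = [t[0] for t in toks]
        labels = _gold_bio(toks, gold.pico_spans)
        n_spans += len(gold.pico_spans)
        examples.append((words, labels))
    if n_spans == 0:
        raise ValueError("corpus contains no gold spans")

    L = len(LABELS)
    tagger = SpanTagger()
    weights: dict[str, np.ndarray] = {}
    totals: dict[str, np.ndarray] = {}
    stamps: dict[str, int] = {}
    trans = np.zeros((L, L))
    trans_tot = np.zeros((L, L))
    trans_stamp = np.zeros((L, L), dtype=int)
    tagger.weights = weights
    tagger.transitions = trans

    rng = np.random.default_rng(config.seed)
    step = 0

    def bump(feat: str, lab: int, delta: float) -> None:
        row = weights.get(feat)
        if row is None:
            row = np.zeros(L)
            weights[feat] = row
            totals[feat] = np.zeros(L)
            stamps[feat] = step
        totals[feat] += (step - stamps[feat]) * row
        stamps[feat] = step
        row[lab] += delta

    for _epoch in range(config.epochs):
        for idx in rng.permutation(len(examples)):
            words, gold_labels = examples[idx]
            step += 1
            pred = tagger.decode(words)
            if pred == gold_labels:
                continue
            feats = [_token_features(words, i) for i in range(len(words))]
            for t, (g, p) in enumerate(zip(gold_labels, pred)):
                if g != p:
                    for f in feats[t]:
                        bump(f, _LABEL_IDX[g], 1.0)
                        bump(f, _LABEL_IDX[p], -1.0)
                if t > 0:
                    gp, pp = gold_labels[t - 1], pred[t - 1]
                    if (gp, g) != (pp, p):
                        for (a, b), d in (((gp, g), 1.0), ((pp, p), -1.0)):
                            ai, bi = _LABEL_IDX[a], _LABEL_IDX[b]
                            trans_tot[ai, bi] += (step - trans_stamp[ai, bi]) * trans[ai, bi]
                            trans_stamp[ai, bi] = step
                            trans[ai, bi] += d

    # finalize averaged weights
    for f, row in weights.items():
        totals[f] += (step - stamps[f]) * row
        weights[f] = totals[f] / max(step, 1)
    trans_tot += (step - trans_stamp) * trans
    tagger.weights = weights
    tagger.transitions = trans_tot / max(step, 1)
    tagger.metadata = {"epochs": config.epochs, "seed": config.seed, "n_train": len(examples)}
    return tagger


def tag_spans(tagger: SpanTagger, abstract: str) -> list[PicoSpan]:
    """Decode BIO labels and convert maximal runs into character spans."""
    toks = tokenize(abstract)
    if not toks:
        return []
    labels = tagger.decode([t[0] for t in toks])
    spans: list[PicoSpan] = []
    run_start = run_end = None
    run_facet = None

    def flush() -> None:
        nonlocal run_start, run_end, run_facet
        if run_facet is not None:
            spans.append(PicoSpan(start=run_start, end=run_end, label=run_facet,
                                  text=abstract[run_start:run_end]))
        run_start = run_end = run_facet = None

    for (word, start, end), lab in zip(toks, labels):
        if lab == "O":
            flush()
            continue
        prefix, facet = lab.split("-", 1)
        if prefix == "B" or facet != run_facet:
            flush()
            run_start, run_end, run_facet = start, end, facet
        else:
            run_end = end
    flush()
    return spans


def evaluate_tagger(tagger: SpanTagger, corpus) -> dict[str, float]:
    """Token-level F1 per facet against gold spans."""
    tp = defaultdict(int)
    fp = defaultdict(int)
    fn = defaultdict(int)
    for record, gold in corpus:
        toks = tokenize(record.abstract)
        gold_labels = _gold_bio(toks, gold.pico_spans)
        pred_labels = tagger.decode([t[0] for t in toks])
        for g, p in zip(gold_labels, pred_labels):
            gf = g.split("-", 1)[1] if g != "O" else None
            pf = p.split("-", 1)[1] if p != "O" else None
            if gf == pf and gf is not None:
                tp[gf] += 1
            else:
                if pf is not None:
                    fp[pf] += 1
                if gf is not None:
                    fn[gf] += 1
    out = {}
    for facet in PICO_FACETS:
        prec = tp[facet] / (tp[facet] + fp[facet]) if tp[facet] + fp[facet] else 0.0
        rec = tp[facet] / (tp[facet] + fn[facet]) if tp[facet] + fn[facet] else 0.0
        out[facet] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return out


# ---------------------------------------------------------------------------
# Abbreviation expansion

_PAREN_RE = re.compile(r"\(([^()]{1,12})\)")


def _valid_long_form(long_words: list[str], sf: str) -> bool:
    """Short-form characters appear in order; first character at a word start."""
    if not long_words or long_words[0][:1].lower() != sf[:1].lower():
        return False
    text = " ".join(long_words).lower()
    pos = 0
    for ch in sf.lower():
        found = text.find(ch, pos)
        if found < 0:
            return False
        pos = found + 1
    return True


def find_abbreviations(text: str) -> dict[str, str]:
    """Map short form -> long form for definitions like "Atrial Fibrillation (AF)".

    The long form immediately precedes the parenthesized short form and may
    be at most min(|SF|+5, |SF|*2) words; the shortest valid word suffix is
    taken.
    """
    defs: dict[str, str] = {}
    for m in _PAREN_RE.finditer(text):
        sf = m.group(1).strip()
        if not (2 <= len(sf) <= 10) or not sf[:1].isalpha() or " " in sf:
            continue
        if not any(c.isupper() for c in sf):
            continue
        before = text[: m.start()].rstrip()
        words = re.findall(r"\S+", before)
        max_words = min(len(sf) + 5, len(sf) * 2)
        for k in range(1, min(max_words, len(words)) + 1):
            cand = words[-k:]
            if _valid_long_form(cand, sf):
                start = before.rfind(" ".join(cand))
                defs[sf] = before[start:].strip() if start >= 0 else " ".join(cand)
                break
    return defs


def expand_abbreviations(snippet: str, full_abstract: str) -> str:
    """Replace bare short-form mentions in ``snippet`` by their long forms."""
    if "(" not in full_abstract:
        return snippet
    defs = find_abbreviations(full_abstract)
    out = snippet
    for sf, lf in defs.items():
        out = re.sub(rf"(?<![\w(]){re.escape(sf)}(?![\w)])", lf, out)
    return out


# ---------------------------------------------------------------------------
# Synonym index and concept linking

_BRACKET_TAG_RE = re.compile(r"\s*\[[^\]]*\]\s*$")


def normalize_synonym(s: str) -> str:
    s = _BRACKET_TAG_RE.sub("", s)
    return " ".join(s.lower().split())


class SynonymIndex:
    """Multimap from normalized synonym token sequences to concept ids."""

    def __init__(self) -> None:
        self._by_key: dict[tuple[str, ...], set[str]] = defaultdict(set)
        self.max_len = 0

    def add(self, synonym: str, concept_id: str) -> None:
        norm = normalize_synonym(synonym)
        if not norm:
            logger.warning("synonym %r of %s normalizes to empty; dropped", synonym, concept_id)
            return
        key = tuple(w for w, _, _ in tokenize(norm))
        self._by_key[key].add(concept_id)
        self.max_len = max(self.max_len, len(key))

    def lookup(self, tokens: tuple[str, ...]) -> set[str]:
        return self._by_key.get(tokens, set())

    def keys(self):
        return self._by_key.keys()


def build_synonym_index(vocab: Vocabulary) -> SynonymIndex:
    index = SynonymIndex()
    for entry in vocab:
        for syn in entry.synonyms:
            index.add(syn, entry.concept_id)
    return index


def link_concepts(index: SynonymIndex, span: PicoSpan, abstract: str) -> list[ConceptAssignment]:
    """Longest-match-first, non-overlapping dictionary lookup in the
    abbreviation-expanded snippet; one assignment per concept per match."""
    snippet = expand_abbreviations(span.text, abstract)
    toks = tokenize(snippet)
    lowers = [t[0].lower() for t in toks]
    out: list[ConceptAssignment] = []
    i = 0
    while i < len(toks):
        matched = False
        for n in range(min(index.max_len, len(toks) - i), 0, -1):
            key = tuple(lowers[i : i + n])
            concepts = index.lookup(key)
            if concepts:
                start = toks[i][1]
                end = toks[i + n - 1][2]
                for cid in sorted(concepts):
                    out.append(ConceptAssignment(
                        concept_id=cid, facet=span.label,
                        matched_text=snippet[start:end], span_offsets=(start, end),
                    ))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Strict / relaxed concept evaluation


def _match_sets(pred: set[str], gold: set[str], vocab: Vocabulary, mode: str):
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "relaxed":
        for cid in pred | gold:
            if cid not in vocab:
                raise ValueError(f"unknown concept id {cid!r} in relaxed evaluation")

    def hits(p: str, g: str) -> bool:
        if p == g:
            return True
        return mode == "relaxed" and g in vocab.neighbours(p)

    tp_pred = sum(1 for p in pred if any(hits(p, g) for g in gold))
    found_gold = sum(1 for g in gold if any(hits(p, g) for p in pred))
    return tp_pred, len(pred), found_gold, len(gold)


def evaluate_concepts(predicted, gold, vocab: Vocabulary, mode: str = "strict",
                      n_boot: int = 1000, seed: int = 0):
    """Micro-averaged per-facet precision/recall with record-level bootstrap CIs.

    ``predicted`` and ``gold`` are parallel lists of per-record dicts
    facet -> set of concept ids. Returns
    {facet: {"precision": (point, lo, hi), "recall": (point, lo, hi)}}.
    """
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold must cover the same records")
    results = {}
    for facet in PICO_FACETS:
        counts = []
        for p_rec, g_rec in zip(predicted, gold):
            counts.append(_match_sets(set(p_rec.get(facet, ())), set(g_rec.get(facet, ())),
                                      vocab, mode))
        counts = np.array(counts, dtype=float)

        def precision_stat(rows):
            denom = rows[:, 1].sum()
            return rows[:, 0].sum() / denom if denom else None

        def recall_stat(rows):
            denom = rows[:, 3].sum()
            return rows[:, 2].sum() / denom if denom else None

        res = {}
        for name, stat in (("precision", precision_stat), ("recall", recall_stat)):
            point, lo, hi = percentile_bootstrap(stat, counts, n_iter=n_boot, seed=seed)
            res[name] = (point, lo, hi)
        results[facet] = res
    return results
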