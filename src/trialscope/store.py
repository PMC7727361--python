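"""Annotated-record store, structured PICO querying, and quality ranking.

The full annotation chain for a published record: RCT screening -> human
screening -> (records failing either gate are discarded) -> sample-size
extraction -> PICO span tagging -> concept linking -> risk-of-bias scoring.
Registry records pass their structured fields through directly (design,
target sample size), have their free-text PICO snippets concept-linked, and
are never given a bias probability.

Queries are conjunctive over (concept, facet) terms; the default order is
recency, and the optional quality ranking orders by
``w_q * P(low risk of bias) + w_n * log10(sample size)``, bringing large
low-bias trials to the top without letting mega-trials swamp quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter, defaultdict
from typing import Optional

import joblib

from . import bias as bias_mod
from . import pico as pico_mod
from . import screening as screening_mod
from . import sizeextract as size_mod
from .records import Annotation, ConceptAssignment, PicoSpan, StudyRecord
from .vocab import Vocabulary

ARCHIVE_VERSION = 1


@dataclass
class PipelineModels:
    rct: screening_mod.RctEnsembleModel
    human: screening_mod.HumanModel
    size: size_mod.SizeModel
    tagger: pico_mod.SpanTagger
    bias: bias_mod.BiasModel
    vocab: Vocabulary

    def __post_init__(self) -> None:
        for name in ("rct", "human", "size", "tagger", "bias", "vocab"):
            if getattr(self, name) is None:
                raise ValueError(f"pipeline model {name!r} is missing")

    def save(self, path) -> None:
        joblib.dump({"version": ARCHIVE_VERSION, "models": self}, path)

    @classmethod
    def load(cls, path) -> "PipelineModels":
        payload = joblib.load(path)
        if payload.get("version") != ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {payload.get('version')}")
        return payload["models"]


def annotate_record(record: StudyRecord, models: PipelineModels,
                    index: Optional[pico_mod.SynonymIndex] = None) -> Optional[Annotation]:
    """Run the annotation chain; None means the record was screened out."""
    if index is None:
        index = pico_mod.build_synonym_index(models.vocab)

    if record.source == "registry":
        rf = record.registry_fields
        design = (rf.study_design or "").lower()
        is_rct = "random" in design
        ann = Annotation(
            is_rct_prob=1.0 if is_rct else 0.0, is_rct=is_rct,
            is_human_prob=1.0, is_human=True,
            sample_size=size_mod.extract_sample_size(models.size, record),
            low_rob_prob=None,
        )
        if not is_rct:
            return None
        for facet, text in (("population", rf.population_text),
                            ("intervention", rf.intervention_text),
                            ("outcome", rf.outcome_text)):
            if text:
                span = PicoSpan(start=0, end=len(text), label=facet, text=text)
                ann.pico_concepts.extend(pico_mod.link_concepts(index, span, text))
        return ann

    rct_prob = screening_mod.predict_rct(models.rct, record)
    threshold = models.rct.threshold_for(record)
    human_prob = screening_mod.predict_human(models.human, record)
    is_rct = rct_prob >= threshold
    is_human = human_prob >= models.human.threshold
    if not (is_rct and is_human):
        return None
    spans = pico_mod.tag_spans(models.tagger, record.abstract)
    concepts: list[ConceptAssignment] = []
    for span in spans:
        concepts.extend(pico_mod.link_concepts(index, span, record.abstract))
    return Annotation(
        is_rct_prob=rct_prob, is_rct=is_rct,
        is_human_prob=human_prob, is_human=is_human,
        sample_size=size_mod.extract_sample_size(models.size, record),
        pico_spans=spans, pico_concepts=concepts,
        low_rob_prob=bias_mod.predict_low_rob(models.bias, record),
    )


@dataclass
class Query:
    terms: list[tuple[str, str]] = field(default_factory=list)  # (concept_id, facet|"any")
    include_published: bool = True
    include_registered: bool = True
    rank_by_quality: bool = False

    def __post_init__(self) -> None:
        if not self.terms and not (self.include_published or self.include_registered):
            raise ValueError("query needs at least one term or include flag")


@dataclass
class RankedResult:
    record: StudyRecord
    annotation: Annotation
    match_facets: dict[str, set[str]]
    rank_score: Optional[float] = None


def quality_rank_score(annotation: Annotation, w_quality: float = 1.0, w_size: float = 0.5) -> float:
    """Larger and lower-bias trials score higher; absent fields contribute 0."""
    score = 0.0
    if annotation.low_rob_prob is not None:
        score += w_quality * annotation.low_rob_prob
    if annotation.sample_size is not None and annotation.sample_size > 0:
        score += w_size * math.log10(annotation.sample_size)
    return score


class AnnotatedStore:
    """In-memory store over annotated records with a concept inverted index."""

    def __init__(self, vocab: Vocabulary):
        self.vocab = vocab
        self.items: list[tuple[StudyRecord, Annotation]] = []
        # (concept_id, facet) -> set of item indices
        self._index: dict[tuple[str, str], set[int]] = defaultdict(set)

    def add(self, record: StudyRecord, annotation: Annotation) -> None:
        idx = len(self.items)
        self.items.append((record, annotation))
        for ca in annotation.pico_concepts:
            self._index[(ca.concept_id, ca.facet)].add(idx)
            self._index[(ca.concept_id, "any")].add(idx)

    def __len__(self) -> int:
        return len(self.items)

    def run_query(self, query: Query, w_quality: float = 1.0, w_size: float = 0.5) -> list[RankedResult]:
        """Conjunctive concept matching, source filters, then ordering."""
        for cid, _facet in query.terms:
            if cid not in self.vocab:
                raise ValueError(f"unknown concept id {cid!r}")
        if query.terms:
            sets = [self._index.get((cid, facet), set()) for cid, facet in query.terms]
            hits = set.intersection(*sets) if sets else set()
        else:
            hits = set(range(len(self.items)))
        results = []
        for idx in hits:
            record, ann = self.items[idx]
            if record.source == "pubmed" and not query.include_published:
                continue
            if record.source == "registry" and not query.include_registered:
                continue
            facets = {
                cid: {ca.facet for ca in ann.pico_concepts if ca.concept_id == cid}
                for cid, _f in query.terms
            }
            results.append(RankedResult(record=record, annotation=ann, match_facets=facets))
        if query.rank_by_quality:
            for r in results:
                r.rank_score = quality_rank_score(r.annotation, w_quality, w_size)
            results.sort(key=lambda r: (-r.rank_score, r.record.record_id))
        else:
            results.sort(key=lambda r: (-(r.record.year or 0), r.record.record_id))
        return results

    def suggest_terms(self, prefix: str) -> list[tuple[str, str]]:
        """Concepts whose preferred term or any synonym starts with the
        normalized prefix, each with its modal facet in the store, ranked by
        store frequency (descending)."""
        if len(prefix) < 2:
            raise ValueError("prefix must be at least 2 characters")
        norm_prefix = " ".join(prefix.lower().split())
        matches = []
        for entry in self.vocab:
            surfaces = [entry.preferred_term] + list(entry.synonyms)
            if any(pico_mod.normalize_synonym(s).startswith(norm_prefix) for s in surfaces):
                matches.append(entry.concept_id)
        usage: dict[str, Counter] = defaultdict(Counter)
        for _record, ann in self.items:
            for ca in ann.pico_concepts:
                usage[ca.concept_id][ca.facet] += 1
        out = []
        for cid in matches:
            counts = usage.get(cid)
            if counts:
                facet, _ = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
                freq = sum(counts.values())
            else:
                facet = self.vocab[cid].facet_prior or "any"
                freq = 0
            out.append((cid, facet, freq))
        out.sort(key=lambda t: (-t[2], t[0]))
        return [(cid, facet) for cid, facet, _ in out]


def build_store(records, models: PipelineModels) -> AnnotatedStore:
    """Annotate and keep the records that pass the RCT-and-human gate."""
    index = pico_mod.build_synonym_index(models.vocab)
    store = AnnotatedStore(models.vocab)
    for record in records:
        ann = annotate_record(record, models, index=index)
        if ann is not None:
            store.add(record, ann)
    return store
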