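"""Annotation pipeline, structured querying, ranking, suggestion."""

from __future__ import annotations

from collections import Counter

import pytest

from trialscope.records import Annotation, StudyRecord
from trialscope.store import (AnnotatedStore, Query, annotate_record,
                              build_store, quality_rank_score)
from trialscope.synth import generate_registry_records


@pytest.fixture(scope="module")
def annotated_store(pipeline_models, corpus_mixed):
    records = [r for r, _ in corpus_mixed[800:]]
    registry = [r for r, _ in generate_registry_records(30, seed=3,
                                                        vocab=pipeline_models.vocab)]
    return build_store(records + registry, pipeline_models)


def test_non_rct_records_are_screened_out(pipeline_models, corpus_mixed):
    non_rct = next(r for r, g in corpus_mixed[800:] if not g.is_rct)
    assert annotate_record(non_rct, pipeline_models) is None


def test_non_human_records_are_screened_out(pipeline_models, corpus_mixed):
    candidates = [r for r, g in corpus_mixed[800:] if g.is_rct and not g.is_human]
    dropped = sum(annotate_record(r, pipeline_models) is None for r in candidates)
    assert dropped / len(candidates) >= 0.9


def test_rct_annotation_fields_populated(pipeline_models, corpus_mixed):
    hit = next(r for r, g in corpus_mixed[800:] if g.is_rct and g.is_human)
    ann = annotate_record(hit, pipeline_models)
    assert ann is not None
    assert ann.is_rct and ann.is_human
    assert ann.is_rct == (ann.is_rct_prob >= pipeline_models.rct.threshold_for(hit))
    assert ann.pico_spans and ann.pico_concepts
    assert ann.low_rob_prob is not None and 0 <= ann.low_rob_prob <= 1


def test_registry_annotation_passthrough(pipeline_models, vocab):
    record = generate_registry_records(1, seed=9, vocab=vocab)[0][0]
    ann = annotate_record(record, pipeline_models)
    assert ann is not None
    assert ann.sample_size == record.registry_fields.target_sample_size
    assert ann.low_rob_prob is None
    assert ann.pico_concepts  # linked from the free-text snippets


def test_store_keeps_only_gated_records(annotated_store, corpus_mixed):
    ids = {r.record_id for r, _ in annotated_store.items}
    gold_keep = {r.record_id for r, g in corpus_mixed[800:] if g.is_rct and g.is_human}
    gold_drop = {r.record_id for r, g in corpus_mixed[800:] if not (g.is_rct and g.is_human)}
    pubmed_ids = {i for i in ids if i.startswith("SYN")}
    # screening is imperfect but close to generator truth
    assert len(pubmed_ids & gold_keep) / len(gold_keep) >= 0.95
    assert len(pubmed_ids & gold_drop) / max(len(gold_drop), 1) <= 0.05


def test_query_is_conjunctive_and_facet_aware(annotated_store, corpus_mixed):
    record, gold = next(
        (r, g) for r, g in corpus_mixed[800:]
        if g.is_rct and g.is_human and g.pico_concepts["intervention"]
    )
    pop = next(iter(gold.pico_concepts["population"]))
    terms = [(pop, "population")]
    res_pop = annotated_store.run_query(Query(terms=terms))
    assert any(r.record.record_id == record.record_id for r in res_pop)
    # conjunction with an intervention term narrows, never widens
    iv = next(iter(gold.pico_concepts["intervention"]))
    res_both = annotated_store.run_query(Query(terms=terms + [(iv, "intervention")]))
    ids_both = {r.record.record_id for r in res_both}
    assert ids_both <= {r.record.record_id for r in res_pop}
    assert record.record_id in ids_both


def test_end_to_end_planted_pair_recall(annotated_store, corpus_mixed):
    """Every generated human RCT carrying a (population, intervention) pair
    is retrieved by the corresponding conjunctive query."""
    pairs = Counter()
    want: dict[tuple[str, str], set[str]] = {}
    for r, g in corpus_mixed[800:]:
        if not (g.is_rct and g.is_human):
            continue
        for pop in g.pico_concepts["population"]:
            for iv in g.pico_concepts["intervention"]:
                want.setdefault((pop, iv), set()).add(r.record_id)
    checked = 0
    missed = 0
    for (pop, iv), ids in list(want.items())[:40]:
        res = annotated_store.run_query(
            Query(terms=[(pop, "population"), (iv, "intervention")],
                  include_registered=False))
        got = {x.record.record_id for x in res}
        stored = {r.record_id for r, _ in annotated_store.items}
        expected = ids & stored  # records the screeners kept
        checked += len(expected)
        missed += len(expected - got)
    assert checked > 20
    assert missed == 0


def test_unknown_concept_raises(annotated_store):
    with pytest.raises(ValueError, match="nope"):
        annotated_store.run_query(Query(terms=[("nope", "population")]))


def test_empty_store_returns_nothing(vocab):
    store = AnnotatedStore(vocab)
    assert store.run_query(Query(terms=[(vocab.concept_ids[0], "any")])) == []


def test_source_filters(annotated_store):
    all_res = annotated_store.run_query(Query())
    pub = annotated_store.run_query(Query(include_registered=False))
    reg = annotated_store.run_query(Query(include_published=False))
    assert len(pub) + len(reg) == len(all_res)
    assert all(r.record.source == "pubmed" for r in pub)
    assert all(r.record.source == "registry" for r in reg)


# -- ranking ----------------------------------------------------------------


def test_quality_score_monotone_in_size_and_quality():
    a = Annotation(low_rob_prob=0.9, sample_size=1000)
    b = Annotation(low_rob_prob=0.9, sample_size=100)
    c = Annotation(low_rob_prob=0.4, sample_size=100)
    d = Annotation()
    assert quality_rank_score(a) > quality_rank_score(b) > quality_rank_score(c)
    assert quality_rank_score(d) == 0.0


def test_ranking_is_a_permutation_of_the_result_set(annotated_store):
    q_plain = Query()
    q_ranked = Query(rank_by_quality=True)
    plain = {r.record.record_id for r in annotated_store.run_query(q_plain)}
    ranked = annotated_store.run_query(q_ranked)
    assert {r.record.record_id for r in ranked} == plain
    scores = [r.rank_score for r in ranked]
    assert scores == sorted(scores, reverse=True)


def test_default_order_is_recency(annotated_store):
    res = annotated_store.run_query(Query())
    years = [r.record.year or 0 for r in res]
    assert years == sorted(years, reverse=True)


# -- suggestion -------------------------------------------------------------


def test_suggest_prefix_matches_and_modal_facet(annotated_store, vocab):
    # pick a concept with stored usage
    usage = Counter()
    for _, ann in annotated_store.items:
        for ca in ann.pico_concepts:
            usage[ca.concept_id] += 1
    cid = usage.most_common(1)[0][0]
    prefix = vocab[cid].preferred_term[:4]
    suggestions = annotated_store.suggest_terms(prefix)
    assert any(s[0] == cid for s in suggestions)
    facet = dict(suggestions)[cid]
    facet_counts = Counter(
        ca.facet for _, ann in annotated_store.items
        for ca in ann.pico_concepts if ca.concept_id == cid
    )
    assert facet == facet_counts.most_common(1)[0][0]


def test_suggest_frequency_ordering_matches_counting_oracle(annotated_store, vocab):
    usage = Counter()
    for _, ann in annotated_store.items:
        for ca in ann.pico_concepts:
            usage[ca.concept_id] += 1
    # a broad prefix hitting several drug names
    suggestions = annotated_store.suggest_terms("ve")
    freqs = [usage.get(cid, 0) for cid, _ in suggestions]
    assert freqs == sorted(freqs, reverse=True)


def test_suggest_no_match_and_short_prefix(annotated_store):
    assert annotated_store.suggest_terms("zzzzqq") == []
    with pytest.raises(ValueError):
        annotated_store.suggest_terms("z")
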