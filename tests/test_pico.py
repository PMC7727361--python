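"""PICO span tagging, abbreviation expansion, synonym index, linking, eval."""

from __future__ import annotations

import itertools

import pytest

from trialscope.pico import (build_synonym_index, evaluate_concepts,
                             evaluate_tagger, expand_abbreviations,
                             find_abbreviations, link_concepts,
                             normalize_synonym, tag_spans, train_span_tagger,
                             TaggerTrainConfig)
from trialscope.records import PicoSpan
from trialscope.vocab import ConceptEntry, Vocabulary


# -- span tagger ------------------------------------------------------------


def test_tagger_heldout_token_f1_per_facet(tagger, corpus_rct):
    f1 = evaluate_tagger(tagger, corpus_rct[800:1000])
    assert f1["population"] >= 0.80
    assert f1["intervention"] >= 0.80
    assert f1["outcome"] >= 0.80


def test_tagger_memorizes_single_abstract(corpus_rct):
    one = corpus_rct[:1]
    t = train_span_tagger(one, TaggerTrainConfig(epochs=50, seed=0))
    f1 = evaluate_tagger(t, one)
    assert all(v == 1.0 for v in f1.values())
    # decoded spans equal the gold spans
    record, gold = one[0]
    assert tag_spans(t, record.abstract) == gold.pico_spans


def test_tagger_reproducible_under_seed(corpus_rct):
    small = corpus_rct[:60]
    a = train_span_tagger(small, TaggerTrainConfig(epochs=3, seed=4))
    b = train_span_tagger(small, TaggerTrainConfig(epochs=3, seed=4))
    abstract = corpus_rct[70][0].abstract
    assert tag_spans(a, abstract) == tag_spans(b, abstract)


def test_tagger_empty_abstract_and_zero_span_corpus(tagger, corpus_rct):
    assert tag_spans(tagger, "") == []
    record, gold = corpus_rct[0]
    stripped = [(record, type(gold)(is_rct=True, is_human=True))]
    with pytest.raises(ValueError):
        train_span_tagger(stripped)


def test_tagged_spans_slice_back_and_are_facet_disjoint(tagger, corpus_rct):
    for record, _ in corpus_rct[1000:1050]:
        spans = tag_spans(tagger, record.abstract)
        for span in spans:
            assert record.abstract[span.start:span.end] == span.text
        by_facet: dict[str, list[PicoSpan]] = {}
        for span in spans:
            by_facet.setdefault(span.label, []).append(span)
        for group in by_facet.values():
            group.sort(key=lambda s: s.start)
            for a, b in itertools.pairwise(group):
                assert a.end <= b.start  # no within-facet overlap


# -- abbreviation expansion -------------------------------------------------


def _subsequence_oracle(long_form: str, sf: str) -> bool:
    """Independent check of the character-matching rule."""
    words = long_form.split()
    if not words or words[0][:1].lower() != sf[:1].lower():
        return False
    text = " ".join(words).lower()
    it = iter(range(len(text)))
    pos = -1
    for ch in sf.lower():
        pos = text.find(ch, pos + 1)
        if pos == -1:
            return False
    return True


def test_abbreviation_definition_and_snippet_expansion():
    abstract = "Atrial Fibrillation (AF) is the most common arrhythmia."
    assert find_abbreviations(abstract) == {"AF": "Atrial Fibrillation"}
    assert expand_abbreviations("patients with AF", abstract) == \
        "patients with Atrial Fibrillation"


def test_expansion_noop_without_parentheses():
    assert expand_abbreviations("patients with AF", "No definitions here.") == \
        "patients with AF"


def test_candidate_long_forms_match_subsequence_oracle():
    cases = [
        ("heat shock protein", "HSP", True),
        ("the results showed", "HSP", False),
        ("Atrial Fibrillation", "AF", True),
        ("forced expiratory volume", "FEV", True),
        ("random words only", "ZQX", False),
        ("Body Mass Index", "BMI", True),
    ]
    for long_form, sf, expected in cases:
        abstract = f"We measured {long_form} ({sf}) at baseline."
        found = find_abbreviations(abstract)
        assert (sf in found) == expected, (long_form, sf)
        assert _subsequence_oracle(long_form, sf) == expected


def test_long_form_word_budget_enforced():
    # long form may span at most min(|SF|+5, 2*|SF|) words
    abstract = "alpha beta gamma delta epsilon zeta (AZ) here"
    found = find_abbreviations(abstract)
    assert "AZ" not in found  # would need 6 words; budget is min(7, 4) = 4


# -- synonym index ----------------------------------------------------------


@pytest.fixture()
def toy_vocab():
    return Vocabulary([
        ConceptEntry("C-mi", "myocardial infarction",
                     ["myocardial infarction", "Myocardial Infarction [NOS]", "heart attack"]),
        ConceptEntry("C-awmi", "anterior wall myocardial infarction",
                     ["anterior wall myocardial infarction"], parents={"C-mi"}),
        ConceptEntry("C-dem", "vascular dementia", ["vascular dementia", "VASCULAR DEMENTIA"]),
        ConceptEntry("C-inf", "infarction", ["infarction"]),
        ConceptEntry("C-shared", "attack episode", ["heart attack"]),
    ])


def test_bracket_tags_stripped_and_lowercased(toy_vocab):
    assert normalize_synonym("Myocardial Infarction [NOS]") == "myocardial infarction"
    index = build_synonym_index(toy_vocab)
    assert index.lookup(("myocardial", "infarction")) == {"C-mi"}


def test_shared_synonym_is_a_multimap(toy_vocab):
    index = build_synonym_index(toy_vocab)
    assert index.lookup(("heart", "attack")) == {"C-mi", "C-shared"}


def test_exhaustive_self_retrieval(vocab):
    """Every stored synonym, re-normalized, retrieves its own concept."""
    from trialscope._text import tokenize

    index = build_synonym_index(vocab)
    for entry in vocab:
        for syn in entry.synonyms:
            key = tuple(w for w, _, _ in tokenize(normalize_synonym(syn)))
            assert entry.concept_id in index.lookup(key), syn


# -- concept linking --------------------------------------------------------


def test_link_simple_span(toy_vocab):
    index = build_synonym_index(toy_vocab)
    abstract = "We studied patients with vascular dementia for a year."
    snippet = "patients with vascular dementia"
    start = abstract.index(snippet)
    span = PicoSpan(start=start, end=start + len(snippet), label="population",
                    text=snippet)
    out = link_concepts(index, span, abstract)
    assert [(a.concept_id, a.facet) for a in out] == [("C-dem", "population")]
    assert out[0].matched_text == "vascular dementia"


def test_longest_match_suppresses_nested_concept(toy_vocab):
    index = build_synonym_index(toy_vocab)
    abstract = "anterior wall myocardial infarction occurred"
    span = PicoSpan(start=0, end=35, label="population", text=abstract[:35])
    out = link_concepts(index, span, abstract)
    assert {a.concept_id for a in out} == {"C-awmi"}  # not C-mi or C-inf


def test_link_through_abbreviation(toy_vocab):
    index = build_synonym_index(toy_vocab)
    abstract = "Vascular Dementia (VD) is studied. Patients with VD were enrolled."
    span_text = "Patients with VD"
    start = abstract.index(span_text)
    span = PicoSpan(start=start, end=start + len(span_text), label="population",
                    text=span_text)
    out = link_concepts(index, span, abstract)
    assert {a.concept_id for a in out} == {"C-dem"}


def test_empty_span_links_nothing(toy_vocab):
    index = build_synonym_index(toy_vocab)
    span = PicoSpan(start=0, end=1, label="population", text=" ")
    assert link_concepts(index, span, " ") == []


def test_linker_recall_one_on_verbatim_synonym_spans(vocab, corpus_rct):
    """Gold spans embed vocabulary synonyms verbatim: every gold concept is
    recovered by dictionary lookup over the gold spans."""
    index = build_synonym_index(vocab)
    for record, gold in corpus_rct[:200]:
        found: dict[str, set[str]] = {f: set() for f in ("population", "intervention", "outcome")}
        for span in gold.pico_spans:
            for ca in link_concepts(index, span, record.abstract):
                found[ca.facet].add(ca.concept_id)
        for facet, ids in gold.pico_concepts.items():
            assert ids <= found[facet], (record.record_id, facet)


def test_every_assignment_names_a_known_concept(vocab, corpus_rct):
    index = build_synonym_index(vocab)
    for record, gold in corpus_rct[:50]:
        for span in gold.pico_spans:
            for ca in link_concepts(index, span, record.abstract):
                assert ca.concept_id in vocab


# -- strict / relaxed evaluation --------------------------------------------


def test_parent_match_counts_only_in_relaxed(toy_vocab):
    predicted = [{"population": {"C-awmi"}}]
    gold = [{"population": {"C-mi"}}]
    strict = evaluate_concepts(predicted, gold, toy_vocab, mode="strict", n_boot=10)
    relaxed = evaluate_concepts(predicted, gold, toy_vocab, mode="relaxed", n_boot=10)
    assert strict["population"]["precision"][0] == 0.0
    assert relaxed["population"]["precision"][0] == 1.0
    assert strict["population"]["recall"][0] == 0.0
    assert relaxed["population"]["recall"][0] == 1.0


def test_identical_sets_perfect_in_both_modes(toy_vocab):
    labeling = [{"population": {"C-mi"}, "intervention": set(), "outcome": set()}]
    for mode in ("strict", "relaxed"):
        res = evaluate_concepts(labeling, labeling, toy_vocab, mode=mode, n_boot=10)
        assert res["population"]["precision"][0] == 1.0
        assert res["population"]["recall"][0] == 1.0


def test_toy_counts_match_hand_oracle(toy_vocab):
    predicted = [
        {"population": {"C-mi", "C-dem"}},
        {"population": {"C-awmi"}},
        {"population": set()},
        {"population": {"C-inf"}},
        {"population": {"C-shared"}},
    ]
    gold = [
        {"population": {"C-mi"}},          # 1 of 2 predictions correct
        {"population": {"C-mi"}},          # parent only in relaxed
        {"population": {"C-dem"}},         # missed
        {"population": set()},             # false positive
        {"population": {"C-shared"}},      # exact
    ]
    strict = evaluate_concepts(predicted, gold, toy_vocab, mode="strict", n_boot=10)
    # hand counts: predictions 5 total, strict TPs = C-mi + C-shared = 2
    assert strict["population"]["precision"][0] == pytest.approx(2 / 5)
    # gold items 4 total, strict found = 2
    assert strict["population"]["recall"][0] == pytest.approx(2 / 4)
    relaxed = evaluate_concepts(predicted, gold, toy_vocab, mode="relaxed", n_boot=10)
    # C-awmi counts via parent C-mi
    assert relaxed["population"]["precision"][0] == pytest.approx(3 / 5)
    assert relaxed["population"]["recall"][0] == pytest.approx(3 / 4)


def test_relaxed_never_below_strict(vocab, corpus_rct):
    index = build_synonym_index(vocab)
    predicted, gold = [], []
    for record, g in corpus_rct[:80]:
        found: dict[str, set[str]] = {f: set() for f in ("population", "intervention", "outcome")}
        for span in g.pico_spans:
            for ca in link_concepts(index, span, record.abstract):
                found[ca.facet].add(ca.concept_id)
        predicted.append(found)
        gold.append(g.pico_concepts)
    strict = evaluate_concepts(predicted, gold, vocab, mode="strict", n_boot=20)
    relaxed = evaluate_concepts(predicted, gold, vocab, mode="relaxed", n_boot=20)
    for facet in ("population", "intervention", "outcome"):
        for metric in ("precision", "recall"):
            assert relaxed[facet][metric][0] >= strict[facet][metric][0]


def test_unknown_concept_in_relaxed_mode_raises(toy_vocab):
    with pytest.raises(ValueError, match="C-nope"):
        evaluate_concepts([{"population": {"C-nope"}}], [{"population": {"C-mi"}}],
                          toy_vocab, mode="relaxed", n_boot=5)
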