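"""Synthetic labeled corpora for training and testing the whole pipeline.

Real training resources for evidence-surveillance models (crowd-labeled
abstract collections, expert PICO annotations, registry dumps, licensed
thesauri) are external and large. This module generates stand-ins: a mini
controlled vocabulary with parent/child structure, and template-based
abstracts with exact gold annotations recorded at construction time —
randomization sentences embedding the sample size (sometimes as number
words), PICO sentences realized from vocabulary synonyms with recorded
character spans, distractor integers (durations, years, percentages, ages),
abbreviation definitions with later bare mentions, and methods phrases
whose inclusion follows a stated log-odds model tied to per-domain
risk-of-bias ratings.

Everything is deterministic under a fixed seed; identical configuration
yields a bit-identical corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .records import Annotation, PicoSpan, RegistryFields, StudyRecord
from .vocab import ConceptEntry, Vocabulary

RCT_PUBTYPE = "Randomized Controlled Trial"
HUMANS_MESH = "Humans"

BIAS_DOMAINS = (
    "random_sequence_generation",
    "allocation_concealment",
    "blinding",
    "incomplete_outcome_data",
)

# One methods phrase per bias domain. Inclusion probability follows
# sigmoid(b0 + b1 * [domain rated low]); coefficients are recorded in the
# corpus metadata so tests can check the realized frequencies.
BIAS_PHRASES = {
    "random_sequence_generation": "The allocation sequence was computer-generated randomization.",
    "allocation_concealment": "Allocation concealment was maintained using sealed opaque envelopes.",
    "blinding": "Participants and outcome assessors were double-blind to treatment assignment.",
    "incomplete_outcome_data": "Outcome data were complete with minimal attrition.",
}
BIAS_LOGODDS_INTERCEPT = -1.8
BIAS_LOGODDS_LOW = 3.4

_POP_MODIFIERS = ("chronic", "acute", "severe", "refractory", "early-stage", "advanced", "mild")
_POP_BASES = (
    "asthma", "migraine", "hypertension", "osteoarthritis", "depression",
    "dermatitis", "anemia", "insomnia", "angina", "neuropathy", "colitis",
    "glaucoma", "psoriasis", "epilepsy", "vascular dementia", "bronchitis",
    "sinusitis", "gastritis", "fibromyalgia", "rosacea",
)
_DRUG_STEMS = ("velo", "mira", "dexa", "lora", "cari", "zebi", "fano", "teri", "olu", "pexi", "rula", "santo")
_DRUG_SUFFIXES = ("tinib", "mab", "pril", "olol", "statin", "cycline", "azole", "setron")
_THERAPIES = (
    "supervised exercise therapy", "cognitive behavioural therapy",
    "mindfulness training", "telehealth coaching", "resistance training",
    "dietary counselling",
)
_OUTCOME_BASES = (
    "systolic blood pressure", "pain score", "fatigue score", "hemoglobin level",
    "relapse rate", "walking distance", "sleep quality", "seizure frequency",
    "body weight", "serum glucose", "quality of life score", "forced expiratory volume",
    "anxiety score", "wound healing time", "bone mineral density", "exercise capacity",
)
_ANIMALS = ("Wistar rats", "BALB/c mice", "beagle dogs", "piglets", "broiler chickens", "zebrafish")

_UNITS_W = ["zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
            "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
            "sixteen", "seventeen", "eighteen", "nineteen"]
_TENS_W = {20: "twenty", 30: "thirty", 40: "forty", 50: "fifty", 60: "sixty",
           70: "seventy", 80: "eighty", 90: "ninety"}


def render_number_words(n: int) -> str:
    """English cardinal rendering with "and" ("one hundred and twelve")."""
    if not 0 <= n <= 999_999:
        raise ValueError("renderable range is 0..999999")
    if n < 20:
        return _UNITS_W[n]
    if n < 100:
        tens, unit = divmod(n, 10)
        word = _TENS_W[tens * 10]
        return f"{word}-{_UNITS_W[unit]}" if unit else word
    if n < 1000:
        hundreds, rest = divmod(n, 100)
        head = f"{_UNITS_W[hundreds]} hundred"
        return f"{head} and {render_number_words(rest)}" if rest else head
    thousands, rest = divmod(n, 1000)
    head = f"{render_number_words(thousands)} thousand"
    if not rest:
        return head
    if rest < 100:
        return f"{head} and {render_number_words(rest)}"
    return f"{head} {render_number_words(rest)}"


@dataclass
class GoldLabel:
    """Generator ground truth for one record."""

    is_rct: bool
    is_human: bool
    sample_size: Optional[int] = None
    pico_spans: list[PicoSpan] = field(default_factory=list)
    pico_concepts: dict[str, set[str]] = field(default_factory=dict)
    bias_domains: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    n_records: int = 1000
    rct_fraction: float = 0.5
    human_fraction: float = 0.9
    # Log-uniform bounds for the number randomized; (8, 600) puts the
    # median near 70, in line with typical published trials.
    sample_size_bounds: tuple[int, int] = (8, 600)
    low_bias_fraction: float = 0.3
    seed: int = 0
    # Fraction of RCTs whose indexing has caught up (publication type applied).
    ptype_index_rate: float = 0.7
    numword_fraction: float = 0.2
    abbrev_fraction: float = 0.35

    def __post_init__(self) -> None:
        for name in ("rct_fraction", "human_fraction", "low_bias_fraction",
                     "ptype_index_rate", "numword_fraction", "abbrev_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.sample_size_bounds
        if not (0 < lo <= hi):
            raise ValueError("sample_size_bounds must be positive and ordered")


class SyntheticCorpus(list):
    """List of (StudyRecord, GoldLabel) pairs with generation metadata."""

    def __init__(self, pairs, config: GeneratorConfig, vocab: Vocabulary, metadata: dict):
        super().__init__(pairs)
        self.config = config
        self.vocab = vocab
        self.metadata = metadata


# ---------------------------------------------------------------------------
# Vocabulary generation


def _case_variant(term: str, rng: np.random.Generator) -> str:
    choice = rng.integers(0, 3)
    if choice == 0:
        return term.title()
    if choice == 1:
        return term.upper()
    return term.capitalize()


def make_vocabulary(seed: int, n_concepts: int) -> Vocabulary:
    """Build a synthetic MeSH-like vocabulary partitioned across PICO facets.

    Roughly 40% population, 35% intervention, 25% outcome concepts. Base
    terms get child concepts formed with a modifier (the child synonym
    contains the parent term, exercising longest-match linking and relaxed
    parent/child evaluation). Some synonyms carry a trailing bracket tag and
    mixed case, exercising index normalization.
    """
    if n_concepts < 10:
        raise ValueError("n_concepts must be >= 10")
    rng = np.random.default_rng(seed)
    n_pop = max(3, int(round(n_concepts * 0.40)))
    n_int = max(3, int(round(n_concepts * 0.35)))
    n_out = max(2, n_concepts - n_pop - n_int)

    entries: list[ConceptEntry] = []

    def add_concept(cid: str, term: str, facet: str, parent: str | None) -> None:
        synonyms = [term]
        if rng.random() < 0.6:
            synonyms.append(_case_variant(term, rng))
        if rng.random() < 0.4:
            synonyms.append(f"{term} [NOS]")
        if rng.random() < 0.3:
            synonyms.append(f"{term} [TC]")
        # keep at most 4, always nonempty
        entries.append(
            ConceptEntry(
                concept_id=cid,
                preferred_term=term,
                synonyms=synonyms[:4],
                parents={parent} if parent else set(),
                facet_prior=facet,
            )
        )

    def fill(facet: str, prefix: str, n: int, bases: list[str], modifiers: tuple[str, ...]) -> None:
        made = 0
        base_idx = 0
        while made < n:
            base = bases[base_idx % len(bases)]
            suffix = "" if base_idx < len(bases) else f" type {base_idx // len(bases) + 1}"
            term = base + suffix
            cid = f"{prefix}{base_idx:04d}"
            add_concept(cid, term, facet, None)
            made += 1
            base_idx += 1
            # child concept: modifier + parent term
            if made < n and rng.random() < 0.5:
                mod = modifiers[int(rng.integers(0, len(modifiers)))]
                add_concept(f"{cid}c", f"{mod} {term}", facet, cid)
                made += 1

    drug_names = [stem + suffix for suffix in _DRUG_SUFFIXES for stem in _DRUG_STEMS]
    rng.shuffle(drug_names)
    interventions = ["placebo", "usual care"] + drug_names + list(_THERAPIES)

    fill("population", "P", n_pop, list(_POP_BASES), _POP_MODIFIERS)
    fill("intervention", "I", n_int, interventions, ("low-dose", "high-dose", "adjunctive", "intensive"))
    fill("outcome", "O", n_out, list(_OUTCOME_BASES), ("mean", "change in", "baseline-adjusted"))

    return Vocabulary(entries)


# ---------------------------------------------------------------------------
# Abstract assembly


class _Builder:
    """Accumulates abstract text while recording exact character spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0
        self.spans: list[PicoSpan] = []

    def add(self, text: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(text)
        self.pos += len(text)
        return start, self.pos

    def add_span(self, text: str, label: str) -> None:
        start, end = self.add(text)
        self.spans.append(PicoSpan(start=start, end=end, label=label, text=text))

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _clean_synonym(entry: ConceptEntry, rng: np.random.Generator) -> str:
    """A synonym safe to place in running text (no bracket tag)."""
    clean = [s for s in entry.synonyms if "[" not in s]
    return clean[int(rng.integers(0, len(clean)))]


def _abbreviate(term: str) -> str:
    words = [w for w in term.replace("-", " ").split() if w]
    return "".join(w[0].upper() for w in words)


def _sample_size(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _pick(rng: np.random.Generator, items: list) -> object:
    return items[int(rng.integers(0, len(items)))]


def _distinct_int(rng: np.random.Generator, lo: int, hi: int, taken: set[int]) -> int:
    for _ in range(100):
        v = int(rng.integers(lo, hi + 1))
        if v not in taken:
            taken.add(v)
            return v
    raise RuntimeError("could not draw distinct integer")


def _sample_bias_domains(rng: np.random.Generator, low_bias_fraction: float) -> dict[str, str]:
    if rng.random() < low_bias_fraction:
        return {d: "low" for d in BIAS_DOMAINS}
    while True:
        ratings = {
            d: ("low" if rng.random() < 0.5 else ("high" if rng.random() < 0.5 else "unclear"))
            for d in BIAS_DOMAINS
        }
        if any(v != "low" for v in ratings.values()):
            return ratings


def generate_corpus(config: GeneratorConfig, vocab: Vocabulary) -> SyntheticCorpus:
    """Generate ``config.n_records`` abstracts with full gold annotations."""
    rng = np.random.default_rng(config.seed)
    by_facet = {
        facet: [e for e in vocab if e.facet_prior == facet]
        for facet in ("population", "intervention", "outcome")
    }
    for facet, pool in by_facet.items():
        if not pool:
            raise ValueError(f"vocabulary has no {facet} concepts")

    pairs = []
    for i in range(config.n_records):
        record_id = f"SYN{i:06d}"
        is_rct = bool(rng.random() < config.rct_fraction)
        is_human = bool(rng.random() < config.human_fraction)
        if is_rct:
            record, gold = _make_rct(record_id, rng, config, by_facet, is_human)
        else:
            record, gold = _make_nonrct(record_id, rng, config, by_facet, is_human)
        pairs.append((record, gold))

    metadata = {
        "bias_logodds": {"intercept": BIAS_LOGODDS_INTERCEPT, "low_coefficient": BIAS_LOGODDS_LOW},
        "bias_phrases": dict(BIAS_PHRASES),
        "seed": config.seed,
    }
    return SyntheticCorpus(pairs, config, vocab, metadata)


def _make_rct(record_id, rng, config, by_facet, is_human):
    pop = _pick(rng, by_facet["population"])
    n_int = 1 if rng.random() < 0.6 else 2
    ints = list(rng.choice(len(by_facet["intervention"]), size=n_int, replace=False))
    int_entries = [by_facet["intervention"][k] for k in ints]
    n_out = 1 if rng.random() < 0.6 else 2
    outs = list(rng.choice(len(by_facet["outcome"]), size=n_out, replace=False))
    out_entries = [by_facet["outcome"][k] for k in outs]

    pop_syn = _clean_synonym(pop, rng)
    int_syns = [_clean_synonym(e, rng) for e in int_entries]
    out_syns = [_clean_synonym(e, rng) for e in out_entries]

    size = _sample_size(rng, config.sample_size_bounds)
    taken = {size}
    weeks = _distinct_int(rng, 2, 52, taken)
    year0 = _distinct_int(rng, 1995, 2020, taken)
    pct = _distinct_int(rng, 1, 99, taken)
    age = _distinct_int(rng, 18, 85, taken)

    use_animal = not is_human
    subject = _pick(rng, list(_ANIMALS)) if use_animal else "patients"

    use_abbrev = is_human and rng.random() < config.abbrev_fraction and len(pop_syn.split()) >= 2
    abbr = _abbreviate(pop_syn) if use_abbrev else None

    b = _Builder()
    b.add(f"Background: {pop_syn.capitalize()}")
    if abbr:
        b.add(f" ({abbr})")
    b.add(" is associated with substantial morbidity, and current management is often inadequate.")

    # Randomization sentence embedding the gold sample size.
    as_words = rng.random() < config.numword_fraction
    size_text = render_number_words(size) if as_words else str(size)
    b.add(" Methods: We randomly assigned ")
    b.add(size_text)
    b.add(" ")
    if abbr:
        b.add_span(f"{subject} with {abbr}", "population")
    else:
        b.add_span(f"{subject} with {pop_syn}", "population")
    b.add(" to receive ")
    b.add_span(int_syns[0], "intervention")
    if len(int_syns) == 2:
        b.add(" plus ")
        b.add_span(int_syns[1], "intervention")
    b.add(f" or matching placebo for {weeks} weeks.")
    b.add(f" Mean age was {age} years, and enrolment ran from {year0} to {year0 + 2}.")

    # Bias-domain-correlated methods phrases (generative log-odds model).
    domains = _sample_bias_domains(rng, config.low_bias_fraction)
    for domain in BIAS_DOMAINS:
        logit = BIAS_LOGODDS_INTERCEPT + (BIAS_LOGODDS_LOW if domains[domain] == "low" else 0.0)
        if rng.random() < 1.0 / (1.0 + math.exp(-logit)):
            b.add(" " + BIAS_PHRASES[domain])

    b.add(" The primary outcome was ")
    b.add_span(out_syns[0], "outcome")
    if len(out_syns) == 2:
        b.add(" and the secondary outcome was ")
        b.add_span(out_syns[1], "outcome")
    b.add(f" after {weeks} weeks of treatment.")
    b.add(" Results: ")
    b.add_span(int_syns[0].capitalize(), "intervention")
    b.add(" improved ")
    b.add_span(out_syns[0], "outcome")
    b.add(f" compared with placebo (response rate {pct}%).")

    abstract = b.text
    title_subject = subject if use_animal else f"patients with {pop_syn}"
    title = f"A randomized controlled trial of {int_syns[0]} in {title_subject}"

    pub_types = set()
    if rng.random() < config.ptype_index_rate:
        pub_types = {RCT_PUBTYPE, "Journal Article"}
    mesh = {HUMANS_MESH} if is_human else set()

    record = StudyRecord(
        record_id=record_id, source="pubmed", title=title, abstract=abstract,
        publication_types=pub_types, mesh_terms=mesh, year=int(year0 + 2),
    )
    concepts = {
        "population": {pop.concept_id},
        "intervention": {e.concept_id for e in int_entries},
        "outcome": {e.concept_id for e in out_entries},
    }
    gold = GoldLabel(
        is_rct=True, is_human=is_human, sample_size=size,
        pico_spans=b.spans, pico_concepts=concepts, bias_domains=domains,
    )
    for span in gold.pico_spans:
        span.check_against(abstract)
    return record, gold


_OBS_DESIGNS = (
    ("retrospective cohort study", "hospital records were retrospectively reviewed"),
    ("case-control study", "cases were matched to controls by age and sex"),
    ("cross-sectional survey", "participants completed a structured questionnaire"),
    ("systematic chart review", "charts were audited by two independent reviewers"),
)


def _make_nonrct(record_id, rng, config, by_facet, is_human):
    pop = _pick(rng, by_facet["population"])
    out = _pick(rng, by_facet["outcome"])
    pop_syn = _clean_synonym(pop, rng)
    out_syn = _clean_synonym(out, rng)
    design, detail = _pick(rng, list(_OBS_DESIGNS))

    taken: set[int] = set()
    year0 = _distinct_int(rng, 1995, 2018, taken)
    cohort = _distinct_int(rng, 50, 5000, taken)
    pct = _distinct_int(rng, 1, 99, taken)

    subject = "patients" if is_human else _pick(rng, list(_ANIMALS))

    b = _Builder()
    b.add(f"We conducted a {design} of ")
    b.add_span(f"{subject} with {pop_syn}", "population")
    b.add(f" seen between {year0} and {year0 + 3}; {detail}.")
    b.add(f" Among {cohort} eligible {subject}, exposure status was ascertained from registries.")
    b.add(" The association with ")
    b.add_span(out_syn, "outcome")
    b.add(f" was estimated using adjusted regression models ({pct}% follow-up).")

    abstract = b.text
    title = f"{design.capitalize()} of {out_syn} in {subject} with {pop_syn}"
    pub_types = set()
    if rng.random() < config.ptype_index_rate:
        pub_types = {"Journal Article", "Observational Study"}
    mesh = {HUMANS_MESH} if is_human else set()

    record = StudyRecord(
        record_id=record_id, source="pubmed", title=title, abstract=abstract,
        publication_types=pub_types, mesh_terms=mesh, year=int(year0 + 3),
    )
    gold = GoldLabel(
        is_rct=False, is_human=is_human, sample_size=None,
        pico_spans=b.spans,
        pico_concepts={"population": {pop.concept_id}, "intervention": set(), "outcome": {out.concept_id}},
        bias_domains={},
    )
    for span in gold.pico_spans:
        span.check_against(abstract)
    return record, gold


# ---------------------------------------------------------------------------
# Registry records


def generate_registry_records(n: int, seed: int, vocab: Vocabulary) -> list[tuple[StudyRecord, GoldLabel]]:
    """Registry entries with semi-structured fields mirroring trial registers."""
    rng = np.random.default_rng(seed)
    by_facet = {
        facet: [e for e in vocab if e.facet_prior == facet]
        for facet in ("population", "intervention", "outcome")
    }
    out = []
    for i in range(n):
        pop = _pick(rng, by_facet["population"])
        intv = _pick(rng, by_facet["intervention"])
        outc = _pick(rng, by_facet["outcome"])
        pop_syn = _clean_synonym(pop, rng)
        int_syn = _clean_synonym(intv, rng)
        out_syn = _clean_synonym(outc, rng)
        is_rct = rng.random() < 0.8
        design = "Randomized controlled trial" if is_rct else "Observational cohort"
        target = _sample_size(rng, (20, 2000))
        rf = RegistryFields(
            study_design=design,
            target_sample_size=int(target),
            population_text=f"Adults with {pop_syn}",
            intervention_text=f"{int_syn} versus standard care",
            outcome_text=f"Change in {out_syn}",
        )
        record = StudyRecord(
            record_id=f"REG{i:05d}", source="registry",
            title=f"Registered study of {int_syn} for {pop_syn}",
            abstract="", year=int(rng.integers(2015, 2024)), registry_fields=rf,
        )
        gold = GoldLabel(
            is_rct=bool(is_rct), is_human=True, sample_size=int(target),
            pico_concepts={
                "population": {pop.concept_id},
                "intervention": {intv.concept_id},
                "outcome": {outc.concept_id},
            },
        )
        out.append((record, gold))
    return out


# ---------------------------------------------------------------------------
# Fixture writers (consumed by records_io readers)


def _xml_escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def corpus_to_medline_xml(corpus, path: str | Path, structured_fraction: float = 0.3,
                          seed: int = 0) -> None:
    """Write records as MEDLINE-style citation XML.

    A fraction of abstracts is emitted as two labeled AbstractText sections
    split at a space so that the reader's single-space join reproduces the
    stored abstract exactly.
    """
    rng = np.random.default_rng(seed)
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<PubmedArticleSet>"]
    for item in corpus:
        record = item[0] if isinstance(item, tuple) else item
        lines.append("<PubmedArticle><MedlineCitation>")
        lines.append(f"<PMID>{_xml_escape(record.record_id)}</PMID>")
        lines.append("<Article>")
        lines.append(f"<ArticleTitle>{_xml_escape(record.title)}</ArticleTitle>")
        if record.year is not None:
            lines.append(f"<Journal><JournalIssue><PubDate><Year>{record.year}</Year>"
                         "</PubDate></JournalIssue></Journal>")
        if record.abstract:
            lines.append("<Abstract>")
            split_at = -1
            if rng.random() < structured_fraction:
                spaces = [k for k, ch in enumerate(record.abstract) if ch == " "]
                mid = [k for k in spaces if 20 < k < len(record.abstract) - 20]
                if mid:
                    split_at = mid[len(mid) // 2]
            if split_at > 0:
                part1 = record.abstract[:split_at]
                part2 = record.abstract[split_at + 1:]
                lines.append(f'<AbstractText Label="BACKGROUND">{_xml_escape(part1)}</AbstractText>')
                lines.append(f'<AbstractText Label="METHODS">{_xml_escape(part2)}</AbstractText>')
            else:
                lines.append(f"<AbstractText>{_xml_escape(record.abstract)}</AbstractText>")
            lines.append("</Abstract>")
        if record.publication_types:
            lines.append("<PublicationTypeList>")
            for pt in sorted(record.publication_types):
                lines.append(f"<PublicationType>{_xml_escape(pt)}</PublicationType>")
            lines.append("</PublicationTypeList>")
        lines.append("</Article>")
        if record.mesh_terms:
            lines.append("<MeshHeadingList>")
            for term in sorted(record.mesh_terms):
                lines.append(f"<MeshHeading><DescriptorName>{_xml_escape(term)}</DescriptorName></MeshHeading>")
            lines.append("</MeshHeadingList>")
        lines.append("</MedlineCitation></PubmedArticle>")
    lines.append("</PubmedArticleSet>")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def registry_to_csv(pairs, path: str | Path) -> None:
    """Write registry records as the CSV dialect read_registry_csv expects."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "record_id", "study_design", "target_sample_size",
            "population_text", "intervention_text", "outcome_text", "year",
        ])
        for item in pairs:
            record = item[0] if isinstance(item, tuple) else item
            rf = record.registry_fields
            writer.writerow([
                record.record_id, rf.study_design,
                "" if rf.target_sample_size is None else str(rf.target_sample_size),
                rf.population_text, rf.intervention_text, rf.outcome_text,
                "" if record.year is None else str(record.year),
            ])


def corpus_records(corpus) -> list[StudyRecord]:
    return [record for record, _ in corpus]


def gold_annotation(record: StudyRecord, gold: GoldLabel, threshold: float = 0.5) -> Annotation:
    """Turn generator truth into an Annotation (for store tests without models)."""
    return Annotation(
        is_rct_prob=1.0 if gold.is_rct else 0.0,
        is_rct=gold.is_rct,
        is_human_prob=1.0 if gold.is_human else 0.0,
        is_human=gold.is_human,
        sample_size=gold.sample_size,
        pico_spans=list(gold.pico_spans),
        pico_concepts=[],
        low_rob_prob=None,
    )
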