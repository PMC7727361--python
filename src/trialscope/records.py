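"""Core record and annotation types.

A :class:`StudyRecord` is one citation (PubMed-style) or one trial-registry
entry. The machine-read layer lives in :class:`Annotation`: screening
probabilities and flags, the extracted number randomized, PICO text spans,
linked vocabulary concepts, and (for published reports only) the predicted
probability that the trial is at low risk of bias overall.

Character offsets throughout the package are 0-based, half-open intervals
over the Unicode code points of the stored abstract string. Readers never
mutate abstract text, so ``abstract[start:end]`` always reproduces the
snippet a span was created from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

PICO_FACETS = ("population", "intervention", "outcome")


@dataclass
class RegistryFields:
    """Structured fields carried by a registry entry (passed through, not predicted)."""

    study_design: str = ""
    target_sample_size: Optional[int] = None
    population_text: str = ""
    intervention_text: str = ""
    outcome_text: str = ""


@dataclass
class StudyRecord:
    record_id: str
    source: str  # "pubmed" | "registry"
    title: str = ""
    abstract: str = ""
    publication_types: set[str] = field(default_factory=set)
    mesh_terms: set[str] = field(default_factory=set)
    year: Optional[int] = None
    registry_fields: Optional[RegistryFields] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be nonempty")
        if self.source not in ("pubmed", "registry"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "registry" and self.registry_fields is None:
            raise ValueError("registry record requires registry_fields")
        if self.source == "pubmed" and self.registry_fields is not None:
            raise ValueError("pubmed record must not carry registry_fields")

    @property
    def text(self) -> str:
        """Title and abstract joined: the text input to the classifiers."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class PicoSpan:
    """A labeled character interval in an abstract.

    Interventions and comparators share the single ``intervention`` label.
    """

    start: int
    end: int
    label: str
    text: str

    def __post_init__(self) -> None:
        if self.label not in PICO_FACETS:
            raise ValueError(f"unknown facet label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span interval [{self.start}, {self.end})")

    def check_against(self, abstract: str) -> None:
        if self.end > len(abstract):
            raise ValueError("span extends past end of abstract")
        if abstract[self.start : self.end] != self.text:
            raise ValueError("span text does not match abstract slice")


@dataclass
class ConceptAssignment:
    concept_id: str
    facet: str
    matched_text: str
    span_offsets: tuple[int, int]  # offsets into the (expanded) snippet


@dataclass
class Annotation:
    is_rct_prob: float = 0.0
    is_rct: bool = False
    is_human_prob: float = 0.0
    is_human: bool = False
    sample_size: Optional[int] = None
    pico_spans: list[PicoSpan] = field(default_factory=list)
    pico_concepts: list[ConceptAssignment] = field(default_factory=list)
    low_rob_prob: Optional[float] = None


def record_to_dict(record: StudyRecord, annotation: Optional[Annotation] = None) -> dict:
    d = asdict(record)
    d["publication_types"] = sorted(record.publication_types)
    d["mesh_terms"] = sorted(record.mesh_terms)
    if annotation is not None:
        a = asdict(annotation)
        for ca in a["pico_concepts"]:
            ca["span_offsets"] = list(ca["span_offsets"])
        d["annotation"] = a
    return d


def record_from_dict(d: dict) -> tuple[StudyRecord, Optional[Annotation]]:
    d = dict(d)
    ann_d = d.pop("annotation", None)
    rf = d.pop("registry_fields", None)
    record = StudyRecord(
        record_id=d["record_id"],
        source=d["source"],
        title=d.get("title", ""),
        abstract=d.get("abstract", ""),
        publication_types=set(d.get("publication_types", ())),
        mesh_terms=set(d.get("mesh_terms", ())),
        year=d.get("year"),
        registry_fields=RegistryFields(**rf) if rf is not None else None,
    )
    annotation = None
    if ann_d is not None:
        annotation = Annotation(
            is_rct_prob=ann_d["is_rct_prob"],
            is_rct=ann_d["is_rct"],
            is_human_prob=ann_d["is_human_prob"],
            is_human=ann_d["is_human"],
            sample_size=ann_d.get("sample_size"),
            pico_spans=[PicoSpan(**s) for s in ann_d.get("pico_spans", ())],
            pico_concepts=[
                ConceptAssignment(
                    concept_id=c["concept_id"],
                    facet=c["facet"],
                    matched_text=c["matched_text"],
                    span_offsets=tuple(c["span_offsets"]),
                )
                for c in ann_d.get("pico_concepts", ())
            ],
            low_rob_prob=ann_d.get("low_rob_prob"),
        )
    return record, annotation
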