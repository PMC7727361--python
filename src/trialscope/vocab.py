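"""Controlled vocabulary: concepts, synonyms and parent/child structure.

Mirrors the shape of a MeSH-style thesaurus slice: every concept has a
preferred term, one or more synonyms (possibly decorated with database tags
such as a trailing ``[NOS]``), and immediate parent/child links forming a
forest. Stored on disk as TSV with pipe-separated multi-valued columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

TSV_COLUMNS = ("concept_id", "preferred_term", "synonyms", "parent_ids", "facet_prior")


@dataclass
class ConceptEntry:
    concept_id: str
    preferred_term: str
    synonyms: list[str]
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)
    facet_prior: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError(f"concept {self.concept_id} has no synonyms")


class Vocabulary:
    """Concept dictionary keyed by concept_id with symmetric parent/child edges."""

    def __init__(self, entries: Iterable[ConceptEntry] = ()):
        self._entries: dict[str, ConceptEntry] = {}
        for e in entries:
            self.add(e)
        self._link()

    def add(self, entry: ConceptEntry) -> None:
        if entry.concept_id in self._entries:
            raise ValueError(f"duplicate concept id {entry.concept_id}")
        self._entries[entry.concept_id] = entry

    def _link(self) -> None:
        """Make parent/child edges symmetric and reject self-loops."""
        for e in self._entries.values():
            for p in e.parents:
                if p == e.concept_id:
                    raise ValueError(f"self-loop at {e.concept_id}")
                parent = self._entries.get(p)
                if parent is None:
                    raise ValueError(f"{e.concept_id} names missing parent {p}")
                parent.children.add(e.concept_id)
        for e in self._entries.values():
            for c in e.children:
                self._entries[c].parents.add(e.concept_id)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._entries

    def __getitem__(self, concept_id: str) -> ConceptEntry:
        return self._entries[concept_id]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self._entries)

    def neighbours(self, concept_id: str) -> set[str]:
        """Immediate parents and children (for relaxed concept matching)."""
        e = self._entries[concept_id]
        return set(e.parents) | set(e.children)

    # ---- TSV round-trip -------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(TSV_COLUMNS)]
        for cid in self.concept_ids:
            e = self._entries[cid]
            lines.append(
                "\t".join(
                    [
                        e.concept_id,
                        e.preferred_term,
                        "|".join(e.synonyms),
                        "|".join(sorted(e.parents)),
                        e.facet_prior or "",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header = tuple(lines[0].split("\t"))
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected vocabulary header {header}")
        entries = []
        for line in lines[1:]:
            if not line.strip():
                continue
            cid, pref, syns, parents, prior = line.split("\t")
            entries.append(
                ConceptEntry(
                    concept_id=cid,
                    preferred_term=pref,
                    synonyms=syns.split("|") if syns else [pref],
                    parents=set(p for p in parents.split("|") if p),
                    facet_prior=prior or None,
                )
            )
        return cls(entries)

    def assert_acyclic(self) -> None:
        """Raise if any concept is its own ancestor."""
        state: dict[str, int] = {}

        def visit(cid: str, stack: set[str]) -> None:
            if cid in stack:
                raise ValueError(f"cycle through {cid}")
            if state.get(cid):
                return
            stack.add(cid)
            for p in self._entries[cid].parents:
                visit(p, stack)
            stack.discard(cid)
            state[cid] = 1

        for cid in self._entries:
            visit(cid, set())
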