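"""Reading and writing study records.

Readers: MEDLINE-style citation XML (the PubMed efetch dialect) and registry
CSV. Persistence: JSON-lines with one annotated record per line (UTF-8).
Export: RIS for citation managers.

The abstract string is stored verbatim as read (structured abstracts are
joined with single spaces in document order), so character offsets produced
downstream remain valid against the stored text.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from .records import Annotation, RegistryFields, StudyRecord, record_from_dict, record_to_dict

logger = logging.getLogger(__name__)

REGISTRY_COLUMNS = (
    "record_id", "study_design", "target_sample_size",
    "population_text", "intervention_text", "outcome_text",
)


def read_medline_xml(path: str | Path) -> list[StudyRecord]:
    """Parse citation XML into StudyRecords.

    Multi-part structured abstracts are concatenated with single spaces in
    document order; a citation without an abstract yields ``abstract=""``.
    Citations lacking a PMID are skipped with a warning. Malformed XML
    raises ``lxml.etree.XMLSyntaxError`` (which carries the position).
    """
    tree = etree.parse(str(path))
    records = []
    for citation in tree.iter("MedlineCitation"):
        pmid = citation.findtext("PMID")
        if not pmid:
            logger.warning("skipping citation without PMID in %s", path)
            continue
        title = citation.findtext(".//ArticleTitle") or ""
        parts = [
            ("".join(el.itertext())).strip()
            for el in citation.iter("AbstractText")
        ]
        abstract = " ".join(p for p in parts if p)
        pub_types = {el.text.strip() for el in citation.iter("PublicationType") if el.text}
        mesh = {el.text.strip() for el in citation.iter("DescriptorName") if el.text}
        year_text = citation.findtext(".//PubDate/Year")
        year = int(year_text) if year_text and year_text.isdigit() else None
        records.append(
            StudyRecord(
                record_id=pmid.strip(), source="pubmed", title=title,
                abstract=abstract, publication_types=pub_types,
                mesh_terms=mesh, year=year,
            )
        )
    return records


def _parse_bare_int(cell: str) -> Optional[int]:
    cell = cell.strip()
    return int(cell) if cell.isdigit() else None


def read_registry_csv(path: str | Path) -> list[StudyRecord]:
    """Read registry entries; target sample size only from a bare-integer cell."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in REGISTRY_COLUMNS if c not in (reader.fieldnames or ())]
        if missing:
            raise ValueError(f"registry CSV missing columns: {', '.join(missing)}")
        records = []
        for row in reader:
            rf = RegistryFields(
                study_design=row["study_design"],
                target_sample_size=_parse_bare_int(row["target_sample_size"]),
                population_text=row["population_text"],
                intervention_text=row["intervention_text"],
                outcome_text=row["outcome_text"],
            )
            year = _parse_bare_int(row.get("year", "") or "")
            records.append(
                StudyRecord(
                    record_id=row["record_id"], source="registry",
                    title=row.get("title", ""), abstract="",
                    year=year, registry_fields=rf,
                )
            )
    return records


def write_jsonl(items: Sequence[tuple[StudyRecord, Optional[Annotation]]], path: str | Path) -> int:
    """One JSON object per line; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for record, annotation in items:
            fh.write(json.dumps(record_to_dict(record, annotation), ensure_ascii=False))
            fh.write("\n")
            n += 1
    return n


def read_jsonl(path: str | Path) -> list[tuple[StudyRecord, Optional[Annotation]]]:
    items = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                items.append(record_from_dict(json.loads(line)))
    return items


def export_ris(items: Sequence[tuple[StudyRecord, Optional[Annotation]]], path: str | Path) -> int:
    """Write one RIS entry per record (type JOUR for published reports).

    The abstract tag is omitted when the abstract is empty. Returns the
    number of entries written.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for record, _annotation in items:
            fh.write("TY  - JOUR\n" if record.source == "pubmed" else "TY  - GEN\n")
            fh.write(f"ID  - {record.record_id}\n")
            if record.title:
                fh.write(f"TI  - {record.title}\n")
            if record.year is not None:
                fh.write(f"PY  - {record.year}\n")
            if record.abstract:
                fh.write(f"AB  - {record.abstract}\n")
            fh.write("ER  - \n")
            n += 1
    return n
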