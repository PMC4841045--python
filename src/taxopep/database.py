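"""Multi-organism protein sequence databases with taxon annotations.

A :class:`SequenceDatabase` joins FASTA records from one or more source
files (e.g. a human reference proteome plus oral-bacteria proteomes)
with an accession -> taxon mapping, validated against a companion
:class:`~taxopep.taxonomy.TaxonomyTree`.  Accessions are resolved from
UniProt-style ``db|ACC|NAME`` headers when present, otherwise the first
whitespace-delimited token; a UniProt ``OX=`` field supplies the taxon
when the mapping table lacks the accession (the table takes precedence).

Contaminant filtering implements the usual proteomics hygiene step:
removal by explicit accession list plus an optional rule that treats
all keratin type I and II proteins as contaminants (skin desquamation
makes their endogenous presence in body-fluid samples unverifiable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxonomyTree

__all__ = [
    "ProteinRecord",
    "SequenceDatabase",
    "DatabaseError",
    "read_protein_database",
    "write_protein_database",
    "filter_contaminant_accessions",
    "min_proteins_per_taxon_filter",
]


class DatabaseError(ValueError):
    """Raised for malformed databases or unresolvable taxa."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    taxon_id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"empty sequence for accession {self.accession!r}")


@dataclass
class SequenceDatabase:
    """Protein records plus a per-accession source-database tag."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)
    source_labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    @property
    def accessions(self) -> list[str]:
        return sorted(self.records)

    def taxon_of(self, accession: str) -> str:
        return self.records[accession].taxon_id

    def add(self, record: ProteinRecord, source_label: str) -> None:
        if record.accession in self.records:
            raise DatabaseError(f"duplicate accession {record.accession!r}")
        self.records[record.accession] = record
        self.source_labels[record.accession] = source_label


_UNIPROT_HEADER = re.compile(r"^[a-z]{2}\|([^|\s]+)\|")
_OX_FIELD = re.compile(r"\bOX=(\S+)")


def _accession_from_header(header_id: str) -> str:
    m = _UNIPROT_HEADER.match(header_id)
    return m.group(1) if m else header_id


def read_protein_database(
    fasta_paths: Iterable,
    taxon_map: object | None = None,
    tree: TaxonomyTree | None = None,
    source_labels: Iterable[str] | None = None,
    require_taxon: bool = True,
) -> SequenceDatabase:
    """Read and validate one or more FASTA files into a database.

    Parameters
    ----------
    fasta_paths
        FASTA files; standard ">" headers, UniProt ``db|ACC|NAME ... OX=taxid``
        dialect recognized.
    taxon_map
        TSV with columns ``accession`` and ``taxon_id``.  Accessions absent
        from the map fall back to the header's ``OX=`` field; a record with
        neither is an error.
    tree
        When given, every taxon must resolve in this tree.
    source_labels
        One tag per FASTA path (e.g. "human", "oral_bacteria"); defaults to
        the file stem.
    """
    fasta_paths = list(fasta_paths)
    if source_labels is None:
        labels = [_stem(p) for p in fasta_paths]
    else:
        labels = list(source_labels)
        if len(labels) != len(fasta_paths):
            raise DatabaseError("need one source label per FASTA path")

    mapping: dict[str, str] = {}
    if taxon_map is not None:
        mdf = pd.read_csv(taxon_map, sep="\t", dtype=str, keep_default_na=False)
        for col in ("accession", "taxon_id"):
            if col not in mdf.columns:
                raise DatabaseError(f"taxon map is missing column {col!r}")
        mapping = dict(zip(mdf["accession"], mdf["taxon_id"]))

    db = SequenceDatabase()
    for path, label in zip(fasta_paths, labels):
        for rec in SeqIO.parse(str(path), "fasta"):
            accession = _accession_from_header(rec.id)
            taxon = mapping.get(accession)
            if taxon is None:
                m = _OX_FIELD.search(rec.description)
                if m is not None:
                    taxon = m.group(1)
                elif require_taxon:
                    raise DatabaseError(
                        f"accession {accession!r} has no taxon in the map and "
                        "no OX= header field"
                    )
                else:
                    taxon = "unassigned"
            if tree is not None and taxon not in tree:
                raise DatabaseError(
                    f"taxon {taxon!r} of accession {accession!r} not in taxonomy"
                )
            db.add(
                ProteinRecord(
                    accession=accession,
                    sequence=str(rec.seq).upper(),
                    taxon_id=taxon,
                    description=rec.description,
                ),
                source_label=label,
            )
    return db


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_protein_database(db: SequenceDatabase, fasta_path, taxon_map_path=None) -> None:
    """Write FASTA (accessions sorted) and, optionally, the taxon map TSV."""
    records = [
        SeqRecord(Seq(db[acc].sequence), id=acc, description=db[acc].description)
        for acc in db.accessions
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if taxon_map_path is not None:
        pd.DataFrame(
            {
                "accession": db.accessions,
                "taxon_id": [db[a].taxon_id for a in db.accessions],
                "source_label": [db.source_labels[a] for a in db.accessions],
            }
        ).to_csv(taxon_map_path, sep="\t", index=False)


_KERATIN = re.compile(r"keratin,?\s+type\s+i", re.IGNORECASE)


def _is_keratin(description: str) -> bool:
    # "type i" prefix-matches both "type I" and "type II"
    return bool(_KERATIN.search(description))


def filter_contaminant_accessions(
    db: SequenceDatabase,
    contaminant_list: Iterable[str] = (),
    drop_keratins: bool = False,
) -> tuple[SequenceDatabase, dict[str, int]]:
    """Drop listed contaminant accessions and, optionally, keratins.

    Keratin detection is a case-insensitive description match on
    "Keratin, type I" / "Keratin, type II".  Returns the filtered
    database and a removal report ``{reason: count}``.
    """
    contaminants = set(contaminant_list)
    kept = SequenceDatabase()
    report = {"contaminant": 0, "keratin": 0}
    for acc in db.accessions:
        rec = db[acc]
        if acc in contaminants:
            report["contaminant"] += 1
        elif drop_keratins and _is_keratin(rec.description):
            report["keratin"] += 1
        else:
            kept.add(rec, db.source_labels[acc])
    return kept, report


def min_proteins_per_taxon_filter(
    db: SequenceDatabase, min_proteins: int
) -> tuple[SequenceDatabase, dict[str, int]]:
    """Drop every record of a taxon represented by < ``min_proteins`` records.

    Mirrors the practice of restricting a community database to species
    with more than a handful of deposited sequences; off by default in
    all pipelines (``min_proteins <= 1`` is the identity).
    """
    counts: dict[str, int] = {}
    for rec in db:
        counts[rec.taxon_id] = counts.get(rec.taxon_id, 0) + 1
    kept = SequenceDatabase()
    dropped: dict[str, int] = {}
    for acc in db.accessions:
        rec = db[acc]
        if counts[rec.taxon_id] < min_proteins:
            dropped[rec.taxon_id] = dropped.get(rec.taxon_id, 0) + 1
        else:
            kept.add(rec, db.source_labels[acc])
    return kept, dropped
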