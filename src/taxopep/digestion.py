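"""In-silico proteolytic digestion and cross-database peptide overlap.

Digestion cleaves C-terminal to the configured residues (trypsin: K/R),
optionally blocked by a following proline, and enumerates all fragments
carrying up to ``max_missed_cleavages`` internal uncleaved sites.  The
nonredundant peptides of a database, keyed to the accessions that
produce them, form the :class:`PeptideIndex` on which taxonomic
assignment and quantification operate.  Because trypsin is typically
combined with LysC (which does cleave K-P bonds) and common search
engines default to trypsin/P, cleavage before proline is allowed by
default; ``block_proline=True`` restores classical trypsin specificity.

Peptides containing ambiguous residues (B, J, O, U, X, Z) are excluded
from indexing: an exact-sequence sharing analysis cannot interpret
them, and MS identification would not report them.  ``equate_il``
collapses isoleucine and leucine (isobaric, indistinguishable by MS)
to one symbol before keying; it is off by default to match
sequence-database search behaviour, where I and L are distinct letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .database import SequenceDatabase

__all__ = [
    "STANDARD_RESIDUES",
    "AMBIGUOUS_RESIDUES",
    "DigestionParams",
    "PeptideIndex",
    "OverlapSummary",
    "digest_protein",
    "build_peptide_index",
    "shared_peptide_fraction",
    "pairwise_overlap_matrix",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")


@dataclass(frozen=True)
class DigestionParams:
    """Cleavage specificity and peptide filters.

    Defaults reproduce the usual metaproteomic search space: cleave
    after K/R (including before proline), at most 2 missed cleavages,
    minimum peptide length 7.
    """

    cleavage_residues: frozenset[str] = frozenset("KR")
    block_proline: bool = False
    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int | None = None
    equate_il: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleavage_residues", frozenset(self.cleavage_residues))
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


def cleavage_sites(sequence: str, params: DigestionParams) -> list[int]:
    """0-based indices i such that the bond after residue i is cleaved."""
    last = len(sequence) - 1
    sites = []
    for i, aa in enumerate(sequence):
        if aa not in params.cleavage_residues or i == last:
            continue
        if params.block_proline and sequence[i + 1] == "P":
            continue
        sites.append(i)
    return sites


def digest_protein(sequence: str, params: DigestionParams | None = None) -> list[str]:
    """Enumerate cleavage-consistent peptides of one protein, N- to C-terminal.

    Returns every fragment whose boundaries are protein termini or
    cleavage sites and which spans at most ``max_missed_cleavages``
    internal sites, filtered by length and ambiguous-residue content.
    The same subsequence occurring at distinct positions appears once
    per position; an empty sequence yields an empty list.
    """
    if params is None:
        params = DigestionParams()
    if not sequence:
        return []
    # fragment boundaries: start positions of 0-missed-cleavage fragments
    starts = [0] + [i + 1 for i in cleavage_sites(sequence, params)]
    ends = starts[1:] + [len(sequence)]
    out: list[str] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for j in range(i, min(i + params.max_missed_cleavages + 1, n_frag)):
            pep = sequence[starts[i] : ends[j]]
            if len(pep) < params.min_length:
                continue
            if params.max_length is not None and len(pep) > params.max_length:
                continue
            if any(aa not in STANDARD_RESIDUES for aa in pep):
                continue
            out.append(pep)
    return out


def _key(peptide: str, params: DigestionParams) -> str:
    return peptide.replace("I", "L") if params.equate_il else peptide


class PeptideIndex:
    """Nonredundant digested peptides mapped to their source accessions.

    Built from a validated :class:`SequenceDatabase`; exposes derived
    views from peptide to source taxa and to source-database labels.
    """

    def __init__(self, params: DigestionParams, db: SequenceDatabase | None = None) -> None:
        self.params = params
        self._db = db
        self._peptides: dict[str, set[str]] = {}

    @classmethod
    def from_database(
        cls, db: SequenceDatabase, params: DigestionParams | None = None
    ) -> "PeptideIndex":
        if params is None:
            params = DigestionParams()
        index = cls(params, db)
        for acc in db.accessions:
            for pep in digest_protein(db[acc].sequence, params):
                index._peptides.setdefault(_key(pep, params), set()).add(acc)
        return index

    def __len__(self) -> int:
        return len(self._peptides)

    def __contains__(self, peptide: str) -> bool:
        return _key(peptide, self.params) in self._peptides

    def __iter__(self):
        return iter(self._peptides)

    @property
    def peptides(self) -> frozenset[str]:
        return frozenset(self._peptides)

    def accessions_for(self, peptide: str) -> frozenset[str]:
        return frozenset(self._peptides.get(_key(peptide, self.params), ()))

    def taxa_for(self, peptide: str) -> frozenset[str]:
        if self._db is None:
            raise ValueError("index was built without a database; no taxon view")
        return frozenset(
            self._db.taxon_of(acc) for acc in self._peptides.get(_key(peptide, self.params), ())
        )

    def sources_for(self, peptide: str) -> frozenset[str]:
        if self._db is None:
            raise ValueError("index was built without a database; no source view")
        return frozenset(
            self._db.source_labels[acc]
            for acc in self._peptides.get(_key(peptide, self.params), ())
        )

    @property
    def database(self) -> SequenceDatabase | None:
        return self._db

    def to_frame(self) -> pd.DataFrame:
        """Peptide table: peptide, semicolon-joined accessions, length."""
        peps = sorted(self._peptides)
        return pd.DataFrame(
            {
                "peptide": peps,
                "accessions": [";".join(sorted(self._peptides[p])) for p in peps],
                "length": [len(p) for p in peps],
            }
        )


def build_peptide_index(
    db: SequenceDatabase, params: DigestionParams | None = None
) -> PeptideIndex:
    """Digest every database protein and key nonredundant peptides to accessions."""
    return PeptideIndex.from_database(db, params)


@dataclass(frozen=True)
class OverlapSummary:
    """Set arithmetic on the nonredundant peptides of two databases."""

    n_a: int
    n_b: int
    n_shared: int

    @property
    def union(self) -> int:
        return self.n_a + self.n_b - self.n_shared

    @property
    def pct_shared(self) -> float:
        if self.union == 0:
            return 0.0
        return 100.0 * self.n_shared / self.union


def shared_peptide_fraction(index_a: PeptideIndex, index_b: PeptideIndex) -> OverlapSummary:
    """Fraction of nonredundant peptides identical between two databases.

    The percentage uses the union of both peptide sets as denominator,
    matching the convention for reporting cross-organism sharing (e.g.
    human vs. oral bacteria at ~0.04 %).
    """
    if index_a.params != index_b.params:
        raise ValueError("peptide indexes were built with different digestion parameters")
    a, b = index_a.peptides, index_b.peptides
    return OverlapSummary(n_a=len(a), n_b=len(b), n_shared=len(a & b))


def pairwise_overlap_matrix(
    dbs: Mapping[str, SequenceDatabase] | Sequence[tuple[str, SequenceDatabase]],
    params: DigestionParams | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], OverlapSummary]]:
    """All-vs-all shared-peptide percentages for labeled databases.

    Returns a symmetric DataFrame of ``pct_shared`` (diagonal 100) and
    the underlying :class:`OverlapSummary` per unordered label pair.
    """
    items = list(dbs.items()) if isinstance(dbs, Mapping) else list(dbs)
    if len(items) < 2:
        raise ValueError("pairwise overlap needs at least 2 databases")
    if params is None:
        params = DigestionParams()
    labels = [label for label, _ in items]
    indexes = {label: build_peptide_index(db, params) for label, db in items}
    summaries: dict[tuple[str, str], OverlapSummary] = {}
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if j < i:
                continue
            s = shared_peptide_fraction(indexes[li], indexes[lj])
            summaries[(li, lj)] = s
            summaries[(lj, li)] = OverlapSummary(s.n_b, s.n_a, s.n_shared)
            mat.loc[li, lj] = s.pct_shared
            mat.loc[lj, li] = s.pct_shared
    return mat, summaries
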