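"""Top-N peptide-intensity genus quantification and proteome summaries.

Genus abundance is estimated as the summed MS intensity of the N most
intense peptides of the genus's peptide pool (N=10 by default), in
analogy to top-three-peptide protein quantification.  The pool of a
genus contains every observed peptide with at least one source protein
whose lineage passes through that genus — shared peptides included,
because restricting to unique peptides would penalise genera with high
inter-species sequence identity.  Genera whose pool holds fewer than N
peptides are excluded from quantification rather than estimated from a
short pool.

Two top-N modes are provided because per-genus selection can be done
per sample or once across samples: ``per-sample`` picks the N largest
nonzero intensities independently in each sample; ``global-median``
ranks pool peptides by their median intensity across samples, fixes
the top N once, and sums those peptides per sample.  Zero intensity
means "not observed" and never occupies a top-N slot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .digestion import PeptideIndex
from .taxonomy import TaxonomyTree

__all__ = [
    "EvidenceTable",
    "GenusQuantParams",
    "GenusAbundanceTable",
    "read_evidence",
    "write_evidence",
    "genus_abundance_topn",
    "fold_change_between_states",
    "core_membership_histogram",
    "cumulative_abundance_fraction",
    "bacterial_fraction_by_rank",
    "zscore_within_sample",
    "pairwise_log_r2",
]

logger = logging.getLogger(__name__)


@dataclass
class EvidenceTable:
    """Observed peptides x samples intensity matrix (post filtering).

    ``intensities`` is indexed by peptide sequence with one column per
    sample; 0 means the peptide was not observed in that sample.
    """

    intensities: pd.DataFrame
    accessions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("evidence intensities must be finite")
        if (vals < 0).any():
            raise ValueError("evidence intensities must be nonnegative")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate sample names in evidence table")

    @property
    def peptides(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def scaled(self, factor: float) -> "EvidenceTable":
        return EvidenceTable(self.intensities * factor, dict(self.accessions))


_SEQ_COLUMNS = ("Sequence", "peptide", "Peptide")
_INTENSITY_PREFIX = "Intensity "


def read_evidence(
    path,
    remove_reverse: bool = True,
    remove_contaminants: bool = True,
) -> tuple[EvidenceTable, dict[str, int]]:
    """Read a MaxQuant-shaped peptide evidence TSV.

    Recognised columns: ``Sequence`` (required), optional ``Proteins``
    (semicolon-joined accessions), optional ``Reverse`` and ``Potential
    contaminant`` ("+" marks flagged rows), and one ``Intensity <sample>``
    column per sample.  Flagged rows are removed when the corresponding
    filter is on; if a flag column is missing the filter is a warning,
    not an error.  Rows sharing a peptide sequence are aggregated by
    summing intensities.  Returns the table and a removal report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    seq_col = next((c for c in _SEQ_COLUMNS if c in df.columns), None)
    if seq_col is None:
        raise ValueError(f"evidence table lacks a sequence column (one of {_SEQ_COLUMNS})")
    intensity_cols = [c for c in df.columns if c.startswith(_INTENSITY_PREFIX)]
    if not intensity_cols:
        raise ValueError("evidence table has no 'Intensity <sample>' columns")

    report = {"reverse": 0, "contaminant": 0}
    for flag_col, key, enabled in (
        ("Reverse", "reverse", remove_reverse),
        ("Potential contaminant", "contaminant", remove_contaminants),
    ):
        if not enabled:
            continue
        if flag_col not in df.columns:
            logger.warning("evidence table has no %r column; filter skipped", flag_col)
            continue
        flagged = df[flag_col].str.strip() == "+"
        report[key] = int(flagged.sum())
        df = df[~flagged]

    mat = pd.DataFrame(index=df[seq_col].to_numpy())
    for col in intensity_cols:
        raw = df[col].replace("", "0")
        try:
            vals = pd.to_numeric(raw)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric intensity in column {col!r}: {exc}") from exc
        if (vals < 0).any():
            raise ValueError(f"negative intensity in column {col!r}")
        mat[col[len(_INTENSITY_PREFIX):]] = vals.to_numpy(dtype=float)
    mat = mat.groupby(level=0, sort=True).sum()

    accessions: dict[str, tuple[str, ...]] = {}
    if "Proteins" in df.columns:
        for pep, prot in zip(df[seq_col], df["Proteins"]):
            if prot:
                prev = set(accessions.get(pep, ()))
                prev.update(prot.split(";"))
                accessions[pep] = tuple(sorted(prev))
    return EvidenceTable(mat, accessions), report


def write_evidence(table: EvidenceTable, path) -> None:
    """Write the MaxQuant-shaped dialect read by :func:`read_evidence`."""
    out = pd.DataFrame({"Sequence": table.peptides})
    out["Proteins"] = [
        ";".join(table.accessions.get(p, ())) for p in table.peptides
    ]
    for s in table.samples:
        out[f"Intensity {s}"] = table.intensities[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenusQuantParams:
    top_n: int = 10
    mode: str = "per-sample"  # or "global-median"
    pool: str = "all-peptides"  # or "unique-only"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.mode not in ("per-sample", "global-median"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pool not in ("all-peptides", "unique-only"):
            raise ValueError(f"unknown pool {self.pool!r}")


@dataclass
class GenusAbundanceTable:
    """Per-genus, per-sample top-N summed intensities.

    ``abundance`` holds only genera whose pool met the top_n threshold;
    ``excluded_genera`` records the rest with reasons.
    """

    abundance: pd.DataFrame
    n_peptides_in_pool: pd.Series
    excluded_genera: dict[str, str]
    params: GenusQuantParams

    @property
    def genera(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


def genus_pools(
    evidence: EvidenceTable,
    index: PeptideIndex,
    tree: TaxonomyTree,
    pool: str = "all-peptides",
) -> dict[str, list[str]]:
    """Observed peptides of each genus (sorted), by lineage membership.

    A peptide belongs to genus g's pool when at least one of its source
    proteins comes from a species whose lineage contains g.  With
    ``pool="unique-only"`` peptides projecting to more than one genus
    are dropped from every pool.
    """
    pools: dict[str, set[str]] = {}
    for pep in evidence.peptides:
        taxa = index.taxa_for(pep) if pep in index else frozenset()
        genera = {
            g.taxon_id
            for t in taxa
            if (g := tree.ancestor_at_rank(t, "genus")) is not None
        }
        if pool == "unique-only" and len(genera) > 1:
            continue
        for g in genera:
            pools.setdefault(g, set()).add(pep)
    return {g: sorted(peps) for g, peps in sorted(pools.items())}


def genus_abundance_topn(
    evidence: EvidenceTable,
    index: PeptideIndex,
    tree: TaxonomyTree,
    params: GenusQuantParams | None = None,
) -> GenusAbundanceTable:
    """Sum the top-N peptide intensities of each genus pool per sample.

    Genera with fewer than ``top_n`` pool peptides are excluded.  In
    per-sample mode the N largest *nonzero* intensities are summed per
    sample; in global-median mode the N pool peptides with the highest
    median intensity across samples are fixed once and summed per
    sample.  Intensity ties break by peptide lexicographic order.
    """
    if params is None:
        params = GenusQuantParams()
    pools = genus_pools(evidence, index, tree, params.pool)
    samples = evidence.samples
    rows: dict[str, np.ndarray] = {}
    n_pool: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for genus, peps in pools.items():
        n_pool[genus] = len(peps)
        if len(peps) < params.top_n:
            excluded[genus] = (
                f"pool has {len(peps)} peptides < top_n={params.top_n}"
            )
            continue
        sub = evidence.intensities.loc[peps, samples]
        if params.mode == "per-sample":
            vals = np.empty(len(samples))
            for k, s in enumerate(samples):
                col = sub[s]
                nonzero = col[col > 0].sort_values(
                    ascending=False, kind="mergesort"
                )
                # peptides pre-sorted lexicographically; stable sort keeps
                # that order within ties
                vals[k] = nonzero.iloc[: params.top_n].sum()
        else:  # global-median
            med = sub.median(axis=1)
            order = sorted(peps, key=lambda p: (-med[p], p))[: params.top_n]
            vals = sub.loc[order].sum(axis=0).to_numpy()
        rows[genus] = vals
    abundance = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    abundance = abundance.sort_index()
    return GenusAbundanceTable(
        abundance=abundance,
        n_peptides_in_pool=pd.Series(n_pool, dtype=int).sort_index(),
        excluded_genera=excluded,
        params=params,
    )


def fold_change_between_states(
    quant_a: GenusAbundanceTable,
    quant_b: GenusAbundanceTable,
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-genus ratio of mean abundances between two states.

    ``quant_a`` supplies state-A samples and ``quant_b`` state-B samples
    (they may be the same table, with ``grouping`` mapping each sample
    name to one of exactly two states; state labels sort A-first).
    ``ratio = mean_A / mean_B``.  Genera quantified in only one state
    are flagged not evaluable.  Returns the per-genus table and a
    summary with the mean and median fold change over evaluable genera.
    """
    if grouping is not None:
        states = sorted(set(grouping.values()))
        if len(states) != 2:
            raise ValueError(f"grouping must define exactly 2 states, got {states}")
        sa = [s for s in quant_a.samples if grouping.get(s) == states[0]]
        sb = [s for s in quant_b.samples if grouping.get(s) == states[1]]
    else:
        sa, sb = quant_a.samples, quant_b.samples
    if not sa or not sb:
        raise ValueError("each state needs at least one sample")

    genera = sorted(set(quant_a.genera) | set(quant_b.genera))
    rows = []
    for g in genera:
        in_a, in_b = g in quant_a.abundance.index, g in quant_b.abundance.index
        mean_a = float(quant_a.abundance.loc[g, sa].mean()) if in_a else np.nan
        mean_b = float(quant_b.abundance.loc[g, sb].mean()) if in_b else np.nan
        evaluable = in_a and in_b and mean_b > 0
        rows.append(
            {
                "genus": g,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "ratio": mean_a / mean_b if evaluable else np.nan,
                "evaluable": evaluable,
            }
        )
    table = pd.DataFrame(rows).set_index("genus")
    ratios = table.loc[table["evaluable"], "ratio"]
    summary = {
        "n_evaluable": int(table["evaluable"].sum()),
        "mean_fold_change": float(ratios.mean()) if len(ratios) else np.nan,
        "median_fold_change": float(ratios.median()) if len(ratios) else np.nan,
    }
    return table, summary


def core_membership_histogram(
    presence: pd.DataFrame,
) -> tuple[dict[int, int], frozenset[str], dict[int, float]]:
    """Distribution of proteins by the number of donors detecting them.

    ``presence`` is a donors x proteins boolean matrix.  Returns the
    histogram over bins 1..n_donors, the core set (proteins present in
    every donor), and percentages relative to proteins detected in at
    least one donor.
    """
    if presence.size == 0:
        raise ValueError("empty presence matrix")
    counts = presence.astype(bool).sum(axis=0)
    n_donors = presence.shape[0]
    detected = counts[counts > 0]
    hist = {k: int((detected == k).sum()) for k in range(1, n_donors + 1)}
    hist = {k: v for k, v in hist.items() if v > 0}
    core = frozenset(detected.index[detected == n_donors])
    total = int(len(detected))
    pct = {k: 100.0 * v / total for k, v in hist.items()} if total else {}
    return hist, core, pct


def cumulative_abundance_fraction(abundances: Mapping[str, float], k: int) -> float:
    """Fraction of total abundance mass carried by the k most abundant entries.

    Ties sort lexicographically; ``k >= n`` returns 1.0 exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(abundances.items(), key=lambda kv: (-kv[1], kv[0]))
    total = float(sum(v for _, v in items))
    if total <= 0:
        raise ValueError("all abundances are zero")
    if k >= len(items):
        return 1.0
    return float(sum(v for _, v in items[:k])) / total


def bacterial_fraction_by_rank(
    ranked: Iterable[tuple[str, str]], window: int = 100
) -> pd.DataFrame:
    """Cumulative percent of bacterial proteins along an abundance ranking.

    ``ranked`` is a descending-abundance list of (protein, origin) with
    origin in {"human", "bacterial"}.  Returns per rank r the cumulative
    percentage of bacterial proteins among the first r, plus a windowed
    percentage over consecutive blocks of ``window`` proteins.
    """
    labels = []
    for protein, origin in ranked:
        if origin not in ("human", "bacterial"):
            raise ValueError(f"unknown origin label {origin!r} for {protein!r}")
        labels.append(origin == "bacterial")
    flags = np.asarray(labels, dtype=float)
    ranks = np.arange(1, len(flags) + 1)
    cumulative = 100.0 * np.cumsum(flags) / ranks
    block = (ranks - 1) // window
    windowed = pd.Series(flags).groupby(block).mean() * 100.0
    return pd.DataFrame(
        {
            "rank": ranks,
            "cumulative_pct_bacterial": cumulative,
            "window_pct_bacterial": windowed.reindex(block).to_numpy(),
        }
    )


def zscore_within_sample(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each sample column to mean 0, population SD 1.

    Used before co-analysing MS genus abundances with shotgun-sequencing
    read counts, so the two modalities share a scale per sample.
    Constant columns are an error (naming the sample) because the
    Z-score is undefined there.
    """
    out = matrix.astype(float).copy()
    for col in out.columns:
        sd = out[col].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"sample {col!r} has a constant column; Z-score undefined")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass(frozen=True)
class LogR2Result:
    r2: float
    n_used: int
    n_dropped: int


def pairwise_log_r2(a: pd.Series, b: pd.Series) -> LogR2Result:
    """R^2 of a least-squares fit on log10 abundances shared by two samples.

    Entries nonpositive (or missing) in either vector are dropped and
    counted; at least 3 shared positive entries are required.
    """
    joined = pd.concat([a, b], axis=1, join="inner")
    joined.columns = ["a", "b"]
    ok = (joined["a"] > 0) & (joined["b"] > 0)
    n_dropped = int(len(joined) - ok.sum())
    used = joined[ok]
    if len(used) < 3:
        raise ValueError(f"only {len(used)} shared positive entries; need >= 3")
    res = stats.linregress(np.log10(used["a"]), np.log10(used["b"]))
    return LogR2Result(r2=float(res.rvalue**2), n_used=int(len(used)), n_dropped=n_dropped)
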