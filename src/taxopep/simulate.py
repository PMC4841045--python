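"""Synthetic metaproteome generator with planted ground truth.

Produces the three inputs every other module consumes — a ranked
taxonomy, a multi-organism protein database, and a multi-sample peptide
evidence table — with known ground truth, so the whole pipeline can be
exercised and validated without raw MS data.

The taxonomy is a balanced bacteria subtree (superkingdom -> phylum ->
genus -> species, deliberately skipping class/order/family) plus an
optional human-like outgroup under a second superkingdom, mirroring a
combined host + oral-microbiome search space.  Protein sequences are
i.i.d. random over the 20 residues with lysine/arginine boosted to
~11 % combined frequency, giving tryptic fragments a realistic mean
length around 9 residues.  Within-genus sequence identity — the reason
peptides are shared between species of one genus — is planted
explicitly: with probability ``cross_species_copy_prob`` a protein is
a point-mutated copy of a protein from a sibling species, and the
tryptic peptides the copy still shares with its template are recorded
in the ground truth.

Evidence emulates a two-state, multi-donor design: each genus has a
base abundance in state A, state-B abundance is the state-A value
times a planted fold change, every pool peptide carries a fixed
peptide-specific response factor, observations are thinned by a
per-sample Bernoulli detection probability, and intensities receive
multiplicative log-normal noise.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .database import ProteinRecord, SequenceDatabase, write_protein_database
from .digestion import DigestionParams, build_peptide_index, digest_protein
from .quantification import EvidenceTable, write_evidence
from .taxonomy import TaxonomyNode, TaxonomyTree, write_taxonomy

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_taxonomy",
    "simulate_database",
    "simulate_evidence",
    "simulate_dataset",
    "write_fixture_bundle",
]

#: Residue alphabet with K/R boosted to ~11 % combined so that tryptic
#: fragments average ~9 aa.
_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWYKR"))
_KR_FREQ = 0.055
_OTHER_FREQ = (1.0 - 2 * _KR_FREQ) / 18
_RESIDUE_P = np.array([_OTHER_FREQ] * 18 + [_KR_FREQ] * 2)

HUMAN_SPECIES_ID = "sp_homo"
HUMAN_GENUS_ID = "gen_homo"


@dataclass(frozen=True)
class SimulationConfig:
    """Study design knobs; defaults emulate a small two-state saliva cohort.

    Defaults: 4 phyla x 3 genera x 3 species (the paper-scale community
    had four main phyla), 20 proteins/species of mean length 300 aa,
    30 % within-genus copy probability with 2 % point mutation (high
    within-genus identity), a human-like outgroup, 8 samples per state
    (eight donors), 90 % peptide detection and log-normal intensity
    noise with sigma 0.5 on the natural-log scale (roughly a 50 % CV,
    typical for label-free peptide intensities).
    """

    seed: int = 0
    n_phyla: int = 4
    genera_per_phylum: int = 3
    species_per_genus: int = 3
    proteins_per_species: int = 20
    protein_length_mean: float = 300.0
    protein_length_sd: float = 80.0
    cross_species_copy_prob: float = 0.3
    point_mutation_rate: float = 0.02
    include_human_like_outgroup: bool = True
    state_a_abundances: Mapping[str, float] | None = None
    abundance_log10_range: tuple[float, float] = (8.0, 10.0)
    fold_changes: Mapping[str, float] | None = None
    samples_per_state: int = 8
    detection_prob: float = 0.9
    intensity_noise_sd: float = 0.5
    peptide_factor_log_sd: float = 1.0
    digestion: DigestionParams = field(default_factory=DigestionParams)

    def __post_init__(self) -> None:
        for name in ("n_phyla", "genera_per_phylum", "species_per_genus",
                     "proteins_per_species", "samples_per_state"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("cross_species_copy_prob", "point_mutation_rate", "detection_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fold_changes is not None and any(
            v <= 0 for v in self.fold_changes.values()
        ):
            raise ValueError("fold_changes must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    copy_events: list[tuple[str, str]] = field(default_factory=list)
    genus_shared_peptides: frozenset[str] = frozenset()
    abundance_a: dict[str, float] = field(default_factory=dict)
    abundance_b: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    sample_states: dict[str, str] = field(default_factory=dict)
    peptide_genus: dict[str, str] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            copy_events=self.copy_events + other.copy_events,
            genus_shared_peptides=self.genus_shared_peptides | other.genus_shared_peptides,
            abundance_a={**self.abundance_a, **other.abundance_a},
            abundance_b={**self.abundance_b, **other.abundance_b},
            fold_changes={**self.fold_changes, **other.fold_changes},
            sample_states={**self.sample_states, **other.sample_states},
            peptide_genus={**self.peptide_genus, **other.peptide_genus},
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def simulate_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Balanced bacteria tree, optionally with a human-like outgroup.

    Shape: root, one bacterial superkingdom, ``n_phyla`` phyla, each
    with ``genera_per_phylum`` genera of ``species_per_genus`` species
    (class/order/family skipped).  Node count without the outgroup is
    ``2 + p + p*g + p*g*s``; the outgroup adds a superkingdom, phylum,
    genus and species (4 nodes).
    """
    nodes = [
        TaxonomyNode("root", "root", "root", None),
        TaxonomyNode("sk_bacteria", "Bacteria", "superkingdom", "root"),
    ]
    for p in range(1, config.n_phyla + 1):
        pid = f"phy{p:02d}"
        nodes.append(TaxonomyNode(pid, f"Phylum{p:02d}", "phylum", "sk_bacteria"))
        for g in range(1, config.genera_per_phylum + 1):
            gid = f"gen{p:02d}.{g:02d}"
            nodes.append(TaxonomyNode(gid, f"Genus{p:02d}.{g:02d}", "genus", pid))
            for s in range(1, config.species_per_genus + 1):
                sid = f"sp{p:02d}.{g:02d}.{s:02d}"
                nodes.append(
                    TaxonomyNode(sid, f"Species{p:02d}.{g:02d}.{s:02d}", "species", gid)
                )
    if config.include_human_like_outgroup:
        nodes += [
            TaxonomyNode("sk_eukaryota", "Eukaryota", "superkingdom", "root"),
            TaxonomyNode("phy_chordata", "Chordata", "phylum", "sk_eukaryota"),
            TaxonomyNode(HUMAN_GENUS_ID, "Homo", "genus", "phy_chordata"),
            TaxonomyNode(HUMAN_SPECIES_ID, "Homo sapiens", "species", HUMAN_GENUS_ID),
        ]
    return TaxonomyTree(nodes)


def _random_sequence(rng: np.random.Generator, config: SimulationConfig) -> str:
    length = max(30, int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))))
    return "".join(rng.choice(_RESIDUES, size=length, p=_RESIDUE_P))


def _mutate(sequence: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return sequence
    chars = np.array(list(sequence))
    hit = rng.random(len(chars)) < rate
    if hit.any():
        chars[hit] = rng.choice(_RESIDUES, size=int(hit.sum()), p=_RESIDUE_P)
    return "".join(chars)


def simulate_database(
    tree: TaxonomyTree, config: SimulationConfig
) -> tuple[SequenceDatabase, GroundTruth]:
    """Random protein database with planted within-genus sequence identity.

    Each protein is, with probability ``cross_species_copy_prob``, a
    point-mutated copy of a previously generated protein from a sibling
    species of the same genus (when one exists), otherwise a fresh
    random sequence.  Tryptic peptides a copy shares with its template
    across species are recorded as genus-shared ground truth.
    """
    rng = _rng(config, 1)
    truth = GroundTruth()
    db = SequenceDatabase()
    shared: set[str] = set()

    genera = sorted(n.taxon_id for n in tree if n.rank == "genus")
    for genus in genera:
        species = sorted(c.taxon_id for c in tree.children(genus))
        made: list[tuple[str, str, str]] = []  # (species, accession, sequence)
        for sp in species:
            label = "human" if sp == HUMAN_SPECIES_ID else "oral_bacteria"
            for i in range(1, config.proteins_per_species + 1):
                acc = f"{sp}_p{i:03d}"
                donors = [m for m in made if m[0] != sp]
                if donors and rng.random() < config.cross_species_copy_prob:
                    src_sp, src_acc, src_seq = donors[rng.integers(len(donors))]
                    seq = _mutate(src_seq, rng, config.point_mutation_rate)
                    truth.copy_events.append((src_acc, acc))
                    overlap = set(digest_protein(src_seq, config.digestion)) & set(
                        digest_protein(seq, config.digestion)
                    )
                    shared.update(overlap)
                else:
                    seq = _random_sequence(rng, config)
                db.add(
                    ProteinRecord(acc, seq, sp, f"{acc} simulated protein OS={sp}"),
                    source_label=label,
                )
                made.append((sp, acc, seq))
    truth.genus_shared_peptides = frozenset(shared)
    return db, truth


def _genus_of_peptide(taxa: frozenset[str], tree: TaxonomyTree) -> str | None:
    genera = sorted(
        g.taxon_id
        for g in (tree.ancestor_at_rank(t, "genus") for t in taxa)
        if g is not None
    )
    return genera[0] if genera else None


def simulate_evidence(
    db: SequenceDatabase, tree: TaxonomyTree, config: SimulationConfig
) -> tuple[EvidenceTable, GroundTruth]:
    """Two-state multi-sample evidence with planted genus abundances.

    Observed intensity of peptide p (owning genus g) in a sample of
    state X is ``A_g(X) * f_p * exp(sigma * z)`` with a per-peptide
    factor ``f_p`` shared across samples and states, thinned by the
    detection probability; ``A_g(B) = A_g(A) * fold_change(g)``.
    """
    rng = _rng(config, 2)
    index = build_peptide_index(db, config.digestion)
    peptides = sorted(index.peptides)
    if not peptides:
        raise ValueError("simulated database yields no peptides to observe")

    genera = sorted(n.taxon_id for n in tree if n.rank == "genus")
    lo, hi = config.abundance_log10_range
    if config.state_a_abundances is not None:
        abundance_a = {g: float(config.state_a_abundances[g]) for g in genera}
    else:
        abundance_a = {
            g: float(10.0 ** rng.uniform(lo, hi)) for g in genera
        }
    folds = {g: 1.0 for g in genera}
    if config.fold_changes is not None:
        for g, v in config.fold_changes.items():
            if g not in folds:
                raise ValueError(f"fold change for unknown genus {g!r}")
            folds[g] = float(v)
    abundance_b = {g: abundance_a[g] * folds[g] for g in genera}

    peptide_genus: dict[str, str] = {}
    for pep in peptides:
        g = _genus_of_peptide(index.taxa_for(pep), tree)
        if g is not None:
            peptide_genus[pep] = g

    owned = [p for p in peptides if p in peptide_genus]
    factors = dict(
        zip(owned, np.exp(rng.normal(0.0, config.peptide_factor_log_sd, len(owned))))
    )

    samples = [f"A{k + 1}" for k in range(config.samples_per_state)] + [
        f"B{k + 1}" for k in range(config.samples_per_state)
    ]
    sample_states = {s: s[0] for s in samples}
    base = {
        s: (abundance_a if sample_states[s] == "A" else abundance_b) for s in samples
    }

    mat = np.zeros((len(owned), len(samples)))
    for j, s in enumerate(samples):
        detected = rng.random(len(owned)) < config.detection_prob
        if config.intensity_noise_sd > 0:
            noise = np.exp(rng.normal(0.0, config.intensity_noise_sd, len(owned)))
        else:
            noise = np.ones(len(owned))
        for i, pep in enumerate(owned):
            if detected[i]:
                mat[i, j] = base[s][peptide_genus[pep]] * factors[pep] * noise[i]

    intensities = pd.DataFrame(mat, index=owned, columns=samples)
    accessions = {p: tuple(sorted(index.accessions_for(p))) for p in owned}
    evidence = EvidenceTable(intensities, accessions)
    truth = GroundTruth(
        abundance_a=abundance_a,
        abundance_b=abundance_b,
        fold_changes=folds,
        sample_states=sample_states,
        peptide_genus=peptide_genus,
    )
    return evidence, truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: TaxonomyTree
    database: SequenceDatabase
    evidence: EvidenceTable
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three stages and merge their ground truths."""
    tree = simulate_taxonomy(config)
    db, truth_db = simulate_database(tree, config)
    evidence, truth_ev = simulate_evidence(db, tree, config)
    return SimulatedDataset(config, tree, db, evidence, truth_db.merged_with(truth_ev))


def write_fixture_bundle(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Emit taxonomy.tsv, db.fasta, accession_map.tsv, evidence.tsv,
    ground_truth.tsv and config.json into ``outdir``; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        name: os.path.join(str(outdir), name)
        for name in (
            "taxonomy.tsv",
            "db.fasta",
            "accession_map.tsv",
            "evidence.tsv",
            "ground_truth.tsv",
            "config.json",
        )
    }
    write_taxonomy(dataset.tree, paths["taxonomy.tsv"])
    write_protein_database(dataset.database, paths["db.fasta"], paths["accession_map.tsv"])
    write_evidence(dataset.evidence, paths["evidence.tsv"])
    truth = dataset.truth
    genera = sorted(truth.abundance_a)
    pd.DataFrame(
        {
            "genus": genera,
            "abundance_state_a": [truth.abundance_a[g] for g in genera],
            "abundance_state_b": [truth.abundance_b[g] for g in genera],
            "fold_change_b_over_a": [truth.fold_changes[g] for g in genera],
        }
    ).to_csv(paths["ground_truth.tsv"], sep="\t", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["state_a_abundances"] = (
        dict(cfg["state_a_abundances"]) if cfg["state_a_abundances"] else None
    )
    cfg["fold_changes"] = dict(cfg["fold_changes"]) if cfg["fold_changes"] else None
    cfg["digestion"] = {
        **cfg["digestion"],
        "cleavage_residues": sorted(cfg["digestion"]["cleavage_residues"]),
    }
    with open(paths["config.json"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    return paths
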