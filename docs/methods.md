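# Methods

## Taxonomy model

The taxonomy is a rooted tree over eight canonical ranks (root,
superkingdom, phylum, class, order, family, genus, species). Ranks
must strictly deepen from parent to child but may be skipped along an
edge (phylum → genus is legal), as real curated taxonomies do for
poorly resolved clades. The lowest common ancestor (LCA) of a taxon
set is computed on actual nodes — the deepest node present on every
member's root-first lineage — not on ranks, so rank skipping cannot
misplace an assignment. The host is modeled as an ordinary leaf under
its own superkingdom; "human vs. bacteria" peptide conflicts are then
just cross-superkingdom LCAs and need no special casing.

Taxonomies are read from a flat TSV (`taxon_id`, `parent_id`, `rank`,
`name`; the root row leaves `parent_id` empty) rather than from NCBI
taxdump files: the flat dialect keeps fixtures self-contained and
human-readable. Trees serialize to Newick via scikit-bio; plain labels
carry display names, and an optional rich-label form
(`taxon_id|rank|name`) is lossless for round-tripping.

## In-silico digestion

Digestion enumerates every fragment whose boundaries are protein
termini or cleavage sites and which spans at most
`max_missed_cleavages` internal sites. Defaults: cleavage C-terminal
to K/R, **including** before proline; at most 2 missed cleavages;
minimum length 7. Cleaving K-P/R-P bonds matches the common search
default for trypsin-plus-LysC digestion protocols (LysC cleaves K-P);
`block_proline=True` restores classical trypsin specificity, and both
settings are exercised in the tests because published protocols are
frequently ambiguous on this point.

Peptides containing ambiguous residues (B, J, O, U, X, Z) are kept in
stored protein sequences but excluded from the peptide index: exact
sequence-sharing logic cannot interpret them and MS search engines do
not report them. `equate_il` collapses I and L (isobaric) to one
symbol before indexing; it is off by default because sequence-database
searching treats them as distinct letters. Peptides are compared as
exact strings — mass-based equivalences belong upstream, in the
identification engine.

The shared-peptide percentage of two databases is
`100 · |A ∩ B| / |A ∪ B|` on the nonredundant peptide sets, computed
only when both indexes were built with identical digestion parameters.

## Split-by-taxonomy grouping

1. Project every observed, matched peptide to the split rank (default
   phylum): the set of split-rank ancestors of its source species.
   When a lineage skips the split rank, the projection falls back to
   the deepest ancestor at or above it (excluding root), so that every
   below-root taxon projects somewhere and the discard rule stays
   total. Peptides with ≥ 2 projections are discarded from
   identification.
2. Partition the remaining peptide-to-protein map by split taxon.
3. Within a partition, merge proteins with identical identifying-
   peptide sets, then greedily subsume any protein whose set is a
   subset of a larger surviving group's set (groups ordered by
   descending identifying-peptide count, ties lexicographic by leading
   accession). This is the simplest parsimony scheme consistent with
   protein-group semantics and the unique/razor peptide distinction.
4. Drop groups below `min_peptides_per_group` identifying peptides.
5. Mark as *unique* the identifying peptides occurring in exactly one
   surviving group; under the default unique-only quantification rule
   these are the only peptides that may quantify a group.

All tie-breaks (group order, leading accession, group ids) are
lexicographic, making output deterministic across runs and platforms.
Peptides matching no database protein are reported in an `unmatched`
sidecar, never silently dropped. Discarded cross-split peptides remain
available to the genus quantification pools — the discard applies to
identification only, because restricting genus pools to unique
peptides would penalize genera with high inter-species identity.

## Peptide-evidence tree

Each matched peptide is counted at exactly one node: its LCA. The
per-node counts form the taxonomic evidence tree. With pruning on
(default), a genus and its subtree are removed iff no peptide has its
LCA at the genus node or below; the peptides counted in a pruned
subtree are listed in a side report and **not** re-attributed upward,
since re-attribution would inflate family-level counts. Counts are
distinct peptide sequences, not spectrum-level observations; evidence
tables carrying multiplicities are collapsed per sequence at read
time. Species nodes inside a retained genus are kept regardless of
their own support.

## Top-N genus quantification

The pool of genus *g* contains every observed peptide with at least
one source protein whose lineage passes through *g* (`pool =
"unique-only"` restricts to single-genus peptides). Genera with fewer
than `top_n` (default 10) pool peptides are excluded with a reason
rather than quantified from a short pool. Zero intensity means "not
observed" and never occupies a top-N slot.

Two selection modes exist because "the N most intense peptides" can be
read per sample or across samples:

- `per-sample` (default): in each sample, sum the N largest nonzero
  intensities of the pool.
- `global-median`: rank pool peptides once by median intensity across
  samples (zeros included in the median), fix the top N, and sum those
  peptides per sample. The alternative reading (top-N per sample, then
  median) is not implemented; outputs are labeled with the mode used.

Intensity ties break by peptide lexicographic order. Fold changes
between two states are ratios of arithmetic means of per-sample
abundances (matching the "mean abundances" convention); genera not
quantified in both states are flagged not-evaluable. Abundances are
linear in a global intensity rescaling, so fold changes and
log-log R² comparisons are scale-invariant.

Descriptive summaries — core-proteome membership histograms,
cumulative abundance fraction of the top k proteins, cumulative
percent of bacterial proteins along an abundance ranking, per-sample
Z-scores (population SD; constant columns are an error naming the
sample), and pairwise log10 R² over shared positive entries — operate
on plain pandas structures and are exported as TSV.

## Evidence input

The evidence reader consumes MaxQuant-shaped text exports: `Sequence`,
optional `Proteins`, optional `Reverse` / `Potential contaminant`
("+" = flagged), and one `Intensity <sample>` column per sample.
Flagged rows are removed and counted; a missing flag column downgrades
the filter to a logged warning. Duplicate sequence rows are summed,
because the quantification unit here is the peptide. Decoy generation
and FDR control are upstream concerns and are consumed only as these
boolean columns. Contaminant filtering by accession list is
complemented by a keratin rule — case-insensitive description match on
"Keratin, type I/II" — since keratins in body-fluid samples cannot be
distinguished from skin desquamation.

## Synthetic data generator

The generator emulates a host + multi-phylum community measured in a
two-state, multi-donor design:

- **Taxonomy**: balanced tree, superkingdom → phylum → genus → species
  (class/order/family deliberately skipped, exercising rank-skip
  handling), plus an optional human-like outgroup under a second
  superkingdom. Node count without the outgroup is
  `2 + p + p·g + p·g·s`.
- **Sequences**: i.i.d. residues with K/R boosted to ~11 % combined
  frequency, giving tryptic fragments a realistic ~9 aa mean length.
  Protein length is normal (mean 300, SD 80, floor 30 aa).
- **Within-genus identity**: with probability
  `cross_species_copy_prob` (default 0.3) a protein is a point-mutated
  copy (per-residue rate 0.02) of a protein from a sibling species;
  the tryptic peptides still shared across species are recorded as
  ground truth. Cross-genus sharing arises only by random collision,
  which is negligible at length ≥ 7 over a 20-letter alphabet.
- **Evidence**: intensity of peptide *p* (owning genus *g*) in a
  sample of state X is `A_g(X) · f_p · exp(σ·z)`, with a fixed
  per-peptide response factor `f_p ~ lognormal(0, 1)`, log-normal
  noise σ = 0.5 by default (~50 % CV, typical for label-free peptide
  intensities), and Bernoulli detection (default 0.9) independent
  across samples. Genus base abundances are log-uniform over
  10^8–10^10 unless supplied; state-B abundances are state-A times the
  planted fold change. Defaults use 8 samples per state (an
  eight-donor cohort sampled in two states) and 4 phyla (the scale of
  the dominant phyla in oral communities).

All outputs are pure functions of (config, seed); the FASTA, TSV and
evidence writers are deterministic byte-for-byte.

What the generator does **not** emulate: spectrum-level noise and
interference, retention-time structure, shared peptides between
distantly related genera (homologous domains), protein-level
missingness correlated across peptides, and compositional effects of
sample loading. Passing tests therefore demonstrate the correctness of
the combinatorial and arithmetic machinery under planted conditions,
not identification performance on real spectra.

## Problem sizes and numerical choices

The test suite validates digestion against a brute-force substring
oracle (200 random sequences × a 12-point parameter grid), LCA against
a lineage-intersection oracle (100 random trees × 100 taxon sets), the
split guarantee on 50 simulated communities (2–4 phyla, copy
probability up to 0.8), and top-N quantification against a full-sort
oracle (100 random evidence tables). Simulated communities in tests
use 2–4 phyla, 2–3 genera per phylum, 2–3 species per genus and 3–6
proteins of ~120–180 aa per species — small enough to run the whole
suite in seconds while still producing thousands of peptides and
nontrivial within-genus sharing. Noiseless fold-change recovery is
asserted to 1e-9 (pure floating-point round-off); noisy recovery
(σ = 0.2, detection 0.9, 4 samples/state, 20 replicates) is asserted
to < 30 % median relative error per genus.

Known limitations: the greedy subsumption grouping is one of several
defensible parsimony schemes (it does not solve minimal set cover);
genus pools use any-source-protein membership, which can overestimate
the abundance of genera sharing peptides with abundant neighbors — an
acknowledged property of pool-based top-N quantification; and the
`min_proteins_per_taxon` database filter counts records per taxon
(off by default), since the per-file alternative is not meaningful
for merged databases.
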