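# Methods

## The project model

All state of a multilocus phylogenomic experiment lives in one `Project`
object: locus definitions, sequence records, alignments (raw and
trimmed), trees, supermatrix recipes and realizations, per-locus
statistics, and an append-only provenance ledger.  Every data object has
a stable identifier (`<locus>_<source>_f<serial>` for records,
`<serial>_<operation>`-prefixed ids for derived objects), and every
mutating operation appends exactly one ledger entry recording the
operation, its parameters, the tool name and version, timestamps and the
input/output object ids.  The ledger is therefore a complete, ordered
derivation graph: the provenance of any object can be replayed by
following `produced_by` links backwards.

Locus name matching folds case, underscores, hyphens and whitespace, so
GenBank's inconsistent gene naming (`cox1`, `COX-1`, `COI` as a declared
alias) resolves to one locus bin.  A record belongs to exactly one locus.

## Per-locus statistics

Five families are computed per locus alignment:

- **Column entropy** (bits): `SE = -Σ pᵢ log₂ pᵢ` over the frequencies
  of unambiguous residues in the column.  Gap characters (`-`, `?`, `.`)
  and ambiguity codes (N, X, IUPAC degenerates) are excluded from the
  frequencies — "ignoring gaps" generalized to all uninformative
  symbols.  A column with no informative residue has *missing* entropy
  (NaN), never 0; missing values are dropped from summaries.  Bounds:
  0 ≤ SE ≤ 2 bits for DNA, ≤ log₂ 20 for protein.
- **Gap score**: fraction of rows with a non-gap character (1 = gap-free
  column), matching the orientation used by gap-threshold trimmers.
- **Conservation**: frequency of the modal unambiguous residue among
  unambiguous residues.  This is an identity-based score; whether the
  originally cited score uses a similarity matrix is not recoverable, so
  the deterministic, matrix-free identity proxy is used and documented.
- **Length**: ungapped residue count per record (ambiguity codes count).
- **GC content**: (G+C)/(A+C+G+T) per record, ambiguity codes excluded
  from numerator and denominator.  The filtering module shares this
  single implementation.

Summaries are box-plot five-number summaries: quartiles by linear
interpolation between order statistics (fully specified so numbers are
bit-reproducible), whiskers the extreme data values within 1.5·IQR of
the box, and *null* whiskers when the box itself has zero height.

The **bias diagnostic** reports the Spearman rank correlation between
two per-locus summaries (e.g. median entropy vs median GC) so that an
entropy gradient can be shown not to be a disguised GC or missing-data
gradient.  Constant input on either side yields an undefined (NaN)
correlation, not 0.

## Gradient supermatrices: sort, slice, slide

Loci are totally ordered by any summary statistic (ties broken
lexicographically by name for determinism).  `slice` selects loci whose
summary lies in a closed interval; an empty selection is an error, never
an empty supermatrix.  `slide` walks the sorted gradient with a window
of `w` loci stepped by `s`: windows sit at offsets `k·s` for
`k = 0 … ⌊(n−w)/s⌋`, so the count is `⌊(n−w)/s⌋ + 1`; trailing loci that
cannot fill a final window are dropped, keeping all windows exactly `w`
loci wide (equal-sized supermatrices are what the gradient comparison
needs).  With n = 465, w = 200, s = 50 this yields six windows, from the
most variable to the most conserved loci.

A `Concatenation` is a declarative recipe (loci, OTU-defining metadata
field — default `organism` — and occupancy rules); `build` realizes it:
one concatenated row per OTU, 1-based inclusive partition intervals in
locus order, an OTU × locus occupancy table and a missing-cell count.
Missing loci are filled with `?` to stay distinguishable from alignment
gaps `-`.  When an OTU has several records for a locus the longest
ungapped sequence wins (ties to the smaller record id), and each choice
is logged.  The `complete` rules preset (every OTU must have every
locus) reproduces the no-missing-data regime.

## Stages

- **Align**: batch command touching every unaligned selected locus.
  The native method registers pre-aligned (equal-length) input as-is;
  production aligners plug in as external adapters (command template
  with `{in}`/`{out}`/`{params}`, a version probe that must succeed
  before anything runs, captured stdout/stderr, probed version recorded
  in the ledger).
- **Trim**: the native trimmer keeps columns whose non-gap fraction is
  ≥ `gt`.  `gt = 0` is the identity, `gt = 1` keeps only gap-free
  columns, and kept-column sets are monotone decreasing in `gt`.
- **Tree**: native neighbor joining on p-distances or JC69 distances
  (`d = -¾ ln(1 − 4p/3)`, an error when p ≥ ¾).  Distances are computed
  over sites where both rows are unambiguous; rows are sorted by record
  id before joining so degenerate (all-equal) inputs resolve
  deterministically.  Negative NJ branch lengths are clamped to zero
  with the deficit moved to the sibling branch.  The native NJ exists so
  the whole pipeline runs without external binaries; likelihood or
  Bayesian engines are adapter configuration, not dependencies.

## Tree comparison

Each branch of an unrooted tree induces a bipartition (split) of the
leaf set, keyed canonically by the side not containing the smallest
leaf label; the two root-incident edges of a rooted-binary Newick are
pooled into one branch, making all metrics invariant under re-rooting.

- **Robinson–Foulds symmetric distance**: number of non-trivial splits
  present in exactly one tree (0 iff same unrooted topology, ≤ 2(n−3)
  for binary trees).  Multifurcations are allowed.
- **Branch-score distance**: √Σ (b₁ − b₂)² over the union of splits,
  with b = 0 for an absent split.  Pendant branches are included by
  default (`include_pendant=False` restricts to internal structure).
- **Rate-standardized branch score**: the same after dividing every
  branch length by its own tree's total length, removing uniform rate
  differences.  "Standardized rate" is implemented as this per-tree
  total-length normalization — the simplest reading — and the
  normalizer is an explicit choice point.

Support values never enter the distances (lengths only).

## Provenance layer

The project serializes to one self-describing JSON document (sequences
and trees as plain strings, deterministic key order, embedded SHA-256
checksum) readable without this library.  The checkpoint store is
content-addressed: the checkpoint id is the hash of the serialized
content with ledger timestamps blanked, so identical states — including
replays of the same operations — share one object file, and saving an
unchanged project is a no-op.  History is a single linear chain
(`chain.jsonl`); restore loads any state in full (all intermediate
objects, ledger prefix) and, because the store is append-only, toggling
back to the head always works.

The report assembles a methods-style document from the ledger
(environment and library versions, per-stage tools/versions/parameters,
accession list, result inventories); only the generation timestamp line
varies between regenerations.  The archive zips the serialized project,
FASTA alignments, Newick + PhyloXML trees (leaf metadata as PhyloXML
properties), supermatrices with partition (`DNA, name = start-end`) and
occupancy files, the report, the checkpoint chain, and a SHA-256
manifest covering every member.

## Synthetic data

`synth_dataset` emulates the structure of the motivating use case:
**465 pre-aligned loci × 26 taxa, full occupancy** by default, with a
linear per-locus entropy gradient from 1.9 down to 0.1 bits.  Each
locus's target entropy is inverted (Brent's method) into the weight of a
dominant base in a (p, q, q, q) column distribution; residues are drawn
i.i.d. per column and taxon.  Locus length defaults to 500 bp — enough
that empirical median column entropies (26 residues per column, 500
columns) order a 10-locus gradient exactly and a 465-locus gradient at
rank correlation ≈ 1.

What the generator does *not* emulate: phylogenetic covariance (no tree
model — sequences are exchangeable within a locus), alignment gaps,
indel structure, GC heterogeneity across loci, or real missing-data
patterns.  A green gradient-recovery or window test therefore
establishes the bookkeeping and the statistics, not inference quality
on real data.  One consequence is intentional and visible: JC69
distances saturate between near-uniform i.i.d. sequences, so synthetic
trees are built with p-distances.

`synth_trees` produces random binary trees on a shared leaf set with
exponential branch lengths; a divergence knob counts random NNI
rearrangements applied per tree (0 = identical copies; large values
reach the RF ceiling).

## Numerical choices

- Entropy in bits (log base 2); any base preserves the ordering the
  gradient machinery uses.
- Percentiles: linear interpolation (the common default, pinned).
- Gap characters: `-`, `?`, `.` everywhere, one shared constant.
- Sort ties: lexicographic by locus name; NaN summaries sort last.
- Newick dialect: quoted labels and support-as-internal-label accepted
  on read; support written as internal labels.
- Partition coordinates 1-based inclusive (PHYLIP/RAxML convention).
- Seeds: a single integer drives `numpy.random.default_rng`.

## Limitations

- Whole-in-memory container; no streaming for datasets beyond RAM.
- No NEXUS writer; no network fetching of accessions; ab1 traces only
  after external conversion to FASTA.
- Native alignment is pass-through registration of pre-aligned input;
  de-novo alignment requires an external adapter (e.g. MAFFT).
- Protein support is limited to p-distances and the protein alphabet in
  statistics; fixtures are DNA-only.
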