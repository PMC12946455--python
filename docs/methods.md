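# Methods

## Problem and approach

A reference library for eDNA metabarcoding maps sequences to taxonomic
names. Curation must answer two questions per record: *is the taxonomic
label consistent with the sequence?* and *can this sequence discriminate
its species at all?* `mitoref` answers both phylogenetically: records are
placed on maximum-likelihood trees built per taxonomic order, and each
species' leaves are compared against the taxonomy of their tree
neighbourhood. Confirmed conflicts are removed; genuine indistinguishability
(recent speciation, introgression, incomplete lineage sorting) is kept but
annotated, because deleting such records would discard real signal and
silently bias downstream assignments.

## Filtering and subsampling

Record-level screens run in a fixed order — ambiguous-qualifier screen,
completeness/gene-content screen, RefSeq-preferring deduplication — so each
rejection carries exactly one primary reason and the kept/rejected sets
partition the input at every stage. Choices worth noting:

* **Completeness** is a case-insensitive substring match of a small keyword
  set against the DEFINITION line ("complete mitochondrial genome",
  "mitochondrion, complete genome", "whole mitochondrion", "complete
  mitogenome", "mitochondrial DNA, complete"), extensible via config.
  DEFINITION text is the only annotation reliably present across submission
  eras.
* **Ambiguous qualifiers** (`cf.`, `sp.`, `ssp.`, hybrid `x`) are matched as
  standalone whitespace tokens, so epithets like *spilota* or genera
  starting with X never trip the screen. Each qualifier can be retained via
  a `keep_*` switch; such records are then judged by their tree placement
  instead.
* **Gene mode** additionally keeps fragments that contain a target gene and
  whose record length meets the threshold (default 400 bp — long enough to
  exclude junk fragments, short enough to keep common barcode submissions).
  Records with *no* feature table at all are retained rather than rejected:
  absence of annotation is a submission defect, not evidence of absence of
  the gene.
* **Subsampling** caps each species at `max_sequences` (default 5). Byte
  identical duplicates collapse first (RefSeq preferred, then smallest
  accession); then one representative per (submitter, geographic origin)
  key (RefSeq, then longest, then smallest accession); any remaining excess
  is drawn uniformly at random. The random draw is seeded per species from
  `f"{rng_seed}:{species}"`, so adding or removing one species never
  perturbs another species' draw and results are independent of input
  order. In gene mode complete genomes fill the quota first and fragments
  are ranked by extracted target-gene length (ties by accession). The
  pre-subsampling count per species is logged so users can judge what the
  cap discarded.

## Gene extraction

Mitochondrial annotations are inconsistent, so genes are located by a table
of case-insensitive patterns anchored on alphanumeric boundaries, applied
to the `gene`, `product` and `note` qualifiers of CDS/rRNA features. The
anchoring prevents the classic cross-matches (COX1 inside COX3's "subunit
III", ND4 inside ND4L, ATP6 vs ATP8, 12S vs 16S); a validation routine
checks that every built-in pattern matches exactly its own gene. The first
matching feature in table order wins when a gene is annotated twice.
Excisions follow GenBank 1-based inclusive coordinates, concatenate
compound (`join`) spans in listed order, and reverse-complement
minus-strand features. Concatenation uses the standard vertebrate
mitogenome gene order; records where nothing can be extracted contribute
their full sequence instead (`fallback_used`), so extraction never loses a
record. Missing genes are skipped rather than gap-padded — the aligner
handles length variation downstream.

## Grouping and tree inference

Trees are built per taxonomic order, packed under a per-file cap (default
2000 sequences) by first-fit-decreasing: deterministic, near-optimal, and
stable under input reordering. An order larger than the cap becomes its own
file rather than being split, because splitting an order would separate the
very clades the detector compares. Outgroups do not count against the cap
and are copied into every group so all trees root consistently on the
outgroup MRCA. Alignment (MAFFT) and inference (FastTree `-nt -fastest`)
run behind a two-method adapter; the package validates only their contract
(IDs preserved, rectangular alignment, leaf set preserved) and treats the
content as opaque, which lets tests substitute stubs and users substitute
tools. Rooted trees may be multifurcating; nothing downstream assumes
binary resolution.

## Anomaly detection

The detector formalizes "clusters far from its expected clade" as follows.
For a leaf, walk its ancestors toward the root and take the first node
whose descendant leaves — excluding the leaf itself, its conspecifics and
all outgroup leaves — number at least `min_neighbors` (default 5); that set
is the leaf's *neighbourhood*. The *match level* is the best rank the leaf
shares with any neighbour: genus > family > order > none. `min_neighbors`
trades locality against robustness: 1 reduces to the sister leaf (brittle
to single misplaced neighbours), large values dilute the neighbourhood
toward the whole tree; 5 keeps the test local while tolerating an adjacent
intruder.

Species are then classified by sequence count:

* **1 leaf** — flag (green) iff the match level is strictly below
  `flag_level` (default family). If the species is its family's only
  representative in the tree, family-level matching cannot possibly
  succeed, so the check drops to order level (`monotypic_fallback`) instead
  of producing a guaranteed false positive.
* **2 leaves** — clean monophyly (the MRCA of the two leaves contains
  nothing else) passes. Otherwise each leaf's match level is computed with
  its conspecific excluded; if exactly one reaches `flag_level` the other
  is flagged (blue), otherwise both are — two interspersed conspecifics
  cannot be adjudicated from topology alone.
* **≥3 leaves** — clean monophyly passes. Otherwise the *core clade* is the
  largest clade consisting solely of conspecific leaves, ties broken by the
  clade whose neighbourhood matches the species at the highest rank, then
  by preorder position; if no two leaves form a clean clade the core
  degenerates to the single best-placed leaf (ties by smallest accession).
  Every conspecific leaf outside the core is flagged (red).

Monophyly and core-clade computations use node leaf-sets computed once per
tree in postorder, so a full scan is O(n · depth). The flag list is sorted
by (color, species, accession) and is a pure function of tree and config.
Outgroup leaves are excluded from every neighbourhood and never flagged.
Flags serialize to a tab-separated `clustering_anomalies.txt` (group id,
color, type, species, accession, tree file, note) — the column layout is
this package's own, chosen so a curator can delete rows with a text editor
— and each tree renders to a PDF with flagged leaves colored by type via an
inspectable drawing model.

## Review and release

Rows left in the edited flag file are confirmed errors and become the
blacklist (`auto_delete` skips review and confirms everything); groups
moved to `similar.txt` are retained, and each member's FASTA header gains
`similar_to=` followed by one representative accession per *other* species
in its group — RefSeq preferred, else the alphanumerically smallest, listed
in alphanumeric accession order. The emitting record's own species
representative is omitted: the tag answers "what else could this sequence
be?". Accessions match version-insensitively throughout, since curation
files are often written without version suffixes.

A release is a `MitoDB_vYYMMDD` directory (collision is an error, never an
overwrite) holding the curated GenBank database (original entry text
preserved verbatim), the curated FASTA with annotated headers,
`cleanlist.txt`, `blacklist.txt`, a summary, and a per-family table of
error/similar/reliable counts with per-family proportions normalized to 1
and log10-scaled counts for plotting. Released plus blacklisted records
always partition the post-filter input; outputs are byte-stable across runs
on identical inputs.

## Synthetic data

The fixtures module emulates the inputs of every stage: a nested synthetic
taxonomy, per-species sequence counts drawn from a configurable support
(default 1–3), sequences derived from ancestors with divergence tiers of
roughly 0.5 % within species, 3 % within genus and 8 % within family
(arbitrary but fixed; they only matter when the real aligner/tree-builder
path is exercised), GenBank text with realistic DEFINITION lines, feature
tables (12S at 70..1020, 16S, COX1, CYTB, and ND6 on the minus strand),
submitter/geography metadata, configurable fractions of RefSeq accessions,
ambiguous organisms, partial records and identical RefSeq/INSDC twins.

Trees are taxonomy-concordant by construction; anomalies are planted with
known truth. A singleton plant relabels a one-sequence species into a fresh
genus of a family from a *different order*; pairwise and cluster plants
detach one leaf and graft it as the sibling of a whole foreign genus clade,
also in a different order. Grafting beside an entire genus clade (rather
than beside an individual leaf) guarantees no correctly-labelled species
loses its monophyly as a side effect, and the different-order constraint
makes the displaced leaf's best achievable neighbourhood rank "none" for
any neighbourhood below the tree root, so recovery does not depend on walk
depth. Each plant reserves its victim's and host's families, keeping plants
independent. What passing these tests shows is that the detector's
classification logic is exact on trees whose only conflicts are the planted
ones; it does not show robustness to alignment noise, rogue taxa, or real
branch-length effects, which the synthetic trees do not model.

## Problem sizes used in verification

The acceptance script and test suite run the detector on 50
taxonomy-concordant trees of 60–300 leaves (expected flag count 0), 100
trees carrying 1–5 mixed plants (precision and recall of flagged accessions
1.0), 500 random ≤12-leaf trees cross-checked against brute-force clade
enumeration, and 1000 randomized per-species record sets for the
subsampling contracts; release bookkeeping is checked on a 389-record set
with 9 confirmed anomalies (380 released). These sizes exercise every code
path at order-of-magnitude realistic shapes while keeping a full run in
seconds.

## Known limitations

* Order/family ranks are resolved from unranked GenBank lineages by suffix
  heuristics (`-formes`, `-idae`) with a config override table; groups
  whose orders lack the suffix need the override.
* The detector uses topology only — no branch lengths, support values or
  statistical placement tests; subtle misplacements within the correct
  family are invisible at the default flag level.
* Type II adjudication is purely topological; when both conspecifics are
  astray both are flagged, deferring to manual review.
* The submitter/origin collapse can discard genuine intraspecific diversity
  in heavily sampled species; raise `max_sequences` or disable subsampling
  when population-level variation matters.
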