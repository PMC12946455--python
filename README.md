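# mitoref

Phylogeny-guided curation of mitochondrial reference databases for eDNA
taxonomic assignment.

Environmental-DNA metabarcoding is only as reliable as the reference library
the reads are matched against, and public repositories carry misidentified,
mislabelled and contaminated mitochondrial records. `mitoref` builds a
curated library from raw GenBank mitogenome (and gene-fragment) records by
checking each species' sequences against their placement on phylogenetic
trees, instead of trusting the metadata alone — while keeping genuinely
ambiguous sequences (recent radiations, introgression, incomplete lineage
sorting) in the database with an explicit warning tag rather than deleting
them.

## What it does

1. **Filter and subsample** (`preprocess`) — keep complete mitogenomes (or,
   in gene mode, fragments ≥ 400 bp containing a target gene), drop records
   with ambiguous organism qualifiers (`cf.`, `sp.`, `ssp.`, hybrid `x`),
   prefer RefSeq (`NC_`) over byte-identical INSDC duplicates, and cap each
   species at `max_sequences` (default 5) representatives, collapsing
   redundant submissions by submitter and geographic origin first.
2. **Extract genes** (`gene_extraction`) — locate the 13 protein-coding
   genes plus 12S/16S rRNA through synonym-tolerant, boundary-anchored
   pattern matching over the `gene`/`product`/`note` qualifiers, excise them
   strand-corrected, and concatenate in the canonical vertebrate mitogenome
   gene order (12S, 16S, ND1, ND2, COX1, COX2, ATP8, ATP6, COX3, ND3, ND4L,
   ND4, ND5, ND6, CYTB).
3. **Group and build trees** (`grouping_trees`) — partition records by
   taxonomic order under a 2000-sequences-per-file cap (first-fit-decreasing
   packing; oversized orders get their own file), force the declared
   outgroups into every group, drive MAFFT and FastTree through a stubbable
   adapter, and root each tree on the outgroup MRCA.
4. **Detect anomalies** (`anomaly_detection`) — classify each species'
   leaves on each rooted tree:
   * **Type I, green (singleton)** — a single-sequence species whose nearest
     ≥ `min_neighbors` tree neighbours share no rank at or above the flag
     level (default: family);
   * **Type II, blue (pairwise)** — a two-sequence species that is not
     monophyletic; the misplaced leaf is flagged if the other sits with its
     expected relatives, both if neither does;
   * **Type III, red (cluster)** — a ≥3-sequence species that is not
     monophyletic; every leaf outside the largest clean conspecific clade is
     flagged.
5. **Review and release** (`curation_release`) — ingest the manually edited
   `clustering_anomalies.txt` (confirmed errors → blacklist) and
   `similar.txt` (indistinguishable groups → `similar_to=` header tags with
   one representative accession per other species, RefSeq preferred), and
   assemble a versioned `MitoDB_vYYMMDD` release directory with curated
   GenBank + FASTA databases, clean/black lists, and per-family
   error/similar/reliable statistics.

A `fixtures` module generates synthetic GenBank records and rooted trees
with planted anomalies and known ground truth, so the entire pipeline is
testable offline.

## Worked example

```bash
mitoref fixtures --seed 3 --plants "singleton:1,cluster:1" --out-dir fx
# wrote 58 records and a 60-leaf tree to fx

mitoref filter fx/records.gb --out-dir filtered
# kept 58 of 58 records (0 filtered, 0 subsampled away)

mitoref detect fx/tree.nwk --outgroup-ids "$(paste -sd, fx/outgroup_ids.txt)" \
    --out-dir anomalies --no-render
# 2 flags written to anomalies/clustering_anomalies.txt

cat anomalies/clustering_anomalies.txt
# #group_id  color  anomaly_type  species            accession     tree_file   note
# tree       green  singleton     Mudifous_plantae   NC_100011.1   fx/tree.nwk single sequence placed outside expected clade
# tree       red    cluster       Nebabaus_locebai   NC_100007.1   fx/tree.nwk diverges from the species' main clade

mitoref release filtered/retained.gb \
    --anomalies anomalies/clustering_anomalies.txt \
    --date 2025-02-26 --out-dir release
# MitoDB_v250226: 56 sequences, 35 species, 2 blacklisted
```

The two flags are exactly the two anomalies planted by the fixture
generator (`fx/truth.tsv`): a relabelled singleton in the wrong family
(green) and a minority leaf detached from a multi-sequence species (red).
Leaving both rows in `clustering_anomalies.txt` confirms them, so the
release blacklists those two accessions and publishes the remaining 56
sequences under the date-derived version string. In a real run you would
edit that file after inspecting the annotated tree PDFs: delete rows that
are false positives, and move truly indistinguishable groups to
`similar.txt` so they are kept but tagged, e.g.

```text
Microphysogobio_linghensis|NC_086468.1|Concat|o__Cypriniformes|f__Gobionidae|g__Microphysogobio|similar_to= NC_051965.1, NC_086467.1|
```

meaning this sequence cannot be reliably distinguished from the two species
represented by the listed accessions.

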