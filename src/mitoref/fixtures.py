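"""Synthetic GenBank records and rooted trees with planted anomalies.

Every pipeline stage is testable offline against generated data with known
ground truth: a nested synthetic taxonomy (orders -> families -> genera ->
species), GenBank flat-file text that round-trips through the parser, and
taxonomy-concordant rooted trees into which singleton/pairwise/cluster
anomalies are planted at controlled positions.

Plants are grafted as siblings of a whole foreign genus clade in a different
order, so the displaced leaf's neighborhood shares no rank above order with
its label and no correctly-labelled species loses its monophyly as a side
effect. The truth table lists exactly the accessions a perfect detector
should flag, with their colors.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, Reference, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .grouping_trees import LeafInfo, TreeWithTaxa
from .records_io import (
    GeneFeature,
    MitoRecord,
    RecordType,
    Strand,
    Taxonomy,
    accession_base,
    format_header,
)

__all__ = [
    "FixtureSpec",
    "make_records",
    "make_tree",
    "make_random_labeled_tree",
    "records_to_genbank",
    "synthetic_genbank_entry",
]

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "ki", "lo",
    "mu", "ne", "pa", "qui", "ro", "su", "ta", "vi",
)


def _name(index: int, n_syllables: int = 3) -> str:
    parts = []
    for _ in range(n_syllables):
        index, rem = divmod(index, len(_SYLLABLES))
        parts.append(_SYLLABLES[rem])
    return "".join(parts)


@dataclass
class FixtureSpec:
    """Shape and content of one synthetic dataset.

    ``seqs_per_species`` is the support of the per-species sequence-count
    draw (uniform over the tuple); ``planted`` lists (anomaly_type, count)
    pairs with types "singleton", "pairwise", "cluster". Fractions control
    how many records get an NC_ accession, an ambiguous organism qualifier,
    or an identical INSDC twin of a RefSeq record.
    """

    n_orders: int = 3
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 3
    seqs_per_species: tuple[int, ...] = (1, 1, 2, 3)
    seq_length: int = 2400
    planted: tuple[tuple[str, int], ...] = ()
    rng_seed: int = 0
    refseq_fraction: float = 0.5
    ambiguous_fraction: float = 0.0
    twin_fraction: float = 0.0
    partial_fraction: float = 0.0
    n_outgroup: int = 2

    def __post_init__(self) -> None:
        for value in (
            self.n_orders, self.families_per_order, self.genera_per_family,
            self.species_per_genus, self.seq_length,
        ):
            if value < 1:
                raise ValueError("bad_spec: all counts must be >= 1")
        if self.seq_length < 2400:
            raise ValueError("bad_spec: seq_length must cover the fixed feature map (>= 2400)")
        if not self.seqs_per_species or any(
            not (1 <= k <= 8) for k in self.seqs_per_species
        ):
            raise ValueError("bad_spec: seqs_per_species must draw from 1..8")
        for kind, count in self.planted:
            if kind not in ("singleton", "pairwise", "cluster") or count < 1:
                raise ValueError(f"bad_spec: bad plant {(kind, count)!r}")


# Fixed feature map (1-based inclusive): the 12S span reproduces the common
# 70..1020 rRNA placement, ND6 sits on the minus strand.
_FEATURE_MAP = (
    ("12S", "12S ribosomal RNA", "rRNA", 70, 1020, Strand.PLUS),
    ("16S", "16S ribosomal RNA", "rRNA", 1021, 1500, Strand.PLUS),
    ("COX1", "cytochrome c oxidase subunit I", "CDS", 1501, 1900, Strand.PLUS),
    ("CYTB", "cytochrome b", "CDS", 1901, 2200, Strand.PLUS),
    ("ND6", "NADH dehydrogenase subunit 6", "CDS", 2201, 2350, Strand.MINUS),
)

_SUBMITTERS = ("chen,l. and wang,y.", "smith,j.", "tanaka,k. and mori,s.", "garcia,m.")
_GEOS = ("China: Yangtze", "Japan: Okinawa", "Australia: NSW", "")

_BASES = "ACGT"


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


@dataclass
class _Species:
    taxonomy: Taxonomy
    n_seqs: int
    consensus: str


def _build_taxonomy(spec: FixtureSpec, rng: random.Random) -> list[_Species]:
    species_list: list[_Species] = []
    idx = 0
    for o in range(spec.n_orders):
        order = _name(o + 1).capitalize() + "iformes"
        for f in range(spec.families_per_order):
            family = _name(o * 17 + f + 3).capitalize() + "idae"
            family_anc = _random_seq(rng, spec.seq_length)
            for g in range(spec.genera_per_family):
                genus = _name(idx + 7).capitalize() + "us"
                genus_anc = _mutate(rng, family_anc, 0.04)
                for s in range(spec.species_per_genus):
                    epithet = _name(idx * 5 + s + 11) + "i"
                    species = f"{genus}_{epithet}"
                    tax = Taxonomy(order=order, family=family, genus=genus, species=species)
                    species_list.append(
                        _Species(
                            taxonomy=tax,
                            n_seqs=rng.choice(spec.seqs_per_species),
                            consensus=_mutate(rng, genus_anc, 0.015),
                        )
                    )
                idx += 1
    return species_list


def _features_for(length: int, partial: bool) -> list[GeneFeature]:
    feats = []
    for gene, product, kind, begin, end, strand in _FEATURE_MAP:
        if partial and gene != "12S":
            continue
        if end > length:
            continue
        feats.append(
            GeneFeature(
                gene_label=gene,
                product_label=product,
                note_label="",
                spans=((begin, end),),
                strand=strand,
                feature_kind=kind,
            )
        )
    return feats


def make_records(spec: FixtureSpec) -> tuple[list[MitoRecord], dict]:
    """Generate records plus a ground-truth table.

    The truth dict holds ``twin_removals`` (INSDC accessions that
    RefSeq-preferring deduplication must drop), ``ambiguous`` (accessions
    whose organism carries an ambiguous qualifier) and ``partial``
    (accessions with partial-sequence definitions).
    """
    rng = random.Random(spec.rng_seed)
    species_list = _build_taxonomy(spec, rng)
    records: list[MitoRecord] = []
    truth = {"twin_removals": set(), "ambiguous": set(), "partial": set()}
    nc_counter = 100001
    insdc_counter = 500001

    for sp in species_list:
        ambiguous_species = rng.random() < spec.ambiguous_fraction
        tax = sp.taxonomy
        if ambiguous_species:
            tax = Taxonomy(
                order=tax.order, family=tax.family, genus=tax.genus,
                species=f"{tax.genus}_sp.",
            )
        for _ in range(sp.n_seqs):
            is_refseq = rng.random() < spec.refseq_fraction
            if is_refseq:
                accession = f"NC_{nc_counter}.1"
                nc_counter += 1
            else:
                accession = f"AB{insdc_counter}.1"
                insdc_counter += 1
            partial = rng.random() < spec.partial_fraction
            seq = _mutate(rng, sp.consensus, 0.0025)
            if partial:
                seq = seq[: rng.randint(500, 1100)]
                definition = f"{tax.species_spaced} 12S ribosomal RNA gene, partial sequence"
                rtype = RecordType.PARTIAL
                truth["partial"].add(accession)
            else:
                definition = f"{tax.species_spaced} mitochondrion, complete genome"
                rtype = RecordType.COMPLETE
            rec = MitoRecord(
                accession=accession,
                taxonomy=tax,
                definition=definition,
                record_type=rtype,
                sequence=seq,
                features=_features_for(len(seq), partial),
                submitter=rng.choice(_SUBMITTERS),
                geo_origin=rng.choice(_GEOS),
            )
            records.append(rec)
            if ambiguous_species:
                truth["ambiguous"].add(accession)
            if is_refseq and not partial and rng.random() < spec.twin_fraction:
                twin_acc = f"AB{insdc_counter}.1"
                insdc_counter += 1
                records.append(
                    MitoRecord(
                        accession=twin_acc,
                        taxonomy=tax,
                        definition=definition,
                        record_type=rtype,
                        sequence=seq,
                        features=_features_for(len(seq), partial),
                        submitter=rec.submitter,
                        geo_origin=rec.geo_origin,
                    )
                )
                truth["twin_removals"].add(twin_acc)
    return records, truth


# ---------------------------------------------------------------------------
# GenBank serialization of synthetic records
# ---------------------------------------------------------------------------

def _to_bio(rec: MitoRecord) -> BioSeqRecord:
    bio = BioSeqRecord(
        Seq(rec.sequence),
        id=rec.accession,
        name=accession_base(rec.accession)[:16],
        description=rec.definition,
    )
    bio.annotations["molecule_type"] = "DNA"
    bio.annotations["organism"] = rec.taxonomy.species_spaced
    bio.annotations["source"] = rec.taxonomy.species_spaced
    bio.annotations["taxonomy"] = [
        t for t in (rec.taxonomy.order, rec.taxonomy.family) if t
    ]
    ref = Reference()
    ref.authors = rec.submitter
    ref.title = "Direct Submission"
    ref.journal = "Submitted to INSDC"
    bio.annotations["references"] = [ref]
    source_quals = {"organism": [rec.taxonomy.species_spaced]}
    if rec.geo_origin:
        source_quals["geo_loc_name"] = [rec.geo_origin]
    bio.features.append(
        SeqFeature(
            FeatureLocation(0, len(rec.sequence), strand=1),
            type="source",
            qualifiers=source_quals,
        )
    )
    for feat in rec.features:
        begin, end = feat.spans[0]
        bio.features.append(
            SeqFeature(
                FeatureLocation(begin - 1, end, strand=-1 if feat.strand is Strand.MINUS else 1),
                type=feat.feature_kind,
                qualifiers={
                    k: [v]
                    for k, v in (
                        ("gene", feat.gene_label),
                        ("product", feat.product_label),
                        ("note", feat.note_label),
                    )
                    if v
                },
            )
        )
    return bio


def records_to_genbank(records: list[MitoRecord]) -> str:
    """Serialize synthetic records to GenBank flat-file text (Biopython)."""
    out = io.StringIO()
    SeqIO.write([_to_bio(r) for r in records], out, "genbank")
    return out.getvalue()


def synthetic_genbank_entry(
    accession: str,
    organism: str,
    lineage: tuple[str, ...],
    definition: str,
    sequence: str,
    features: tuple[GeneFeature, ...] = (),
    submitter: str = "doe,j.",
    geo: str = "",
) -> str:
    """One hand-specified GenBank entry, for targeted parser tests."""
    parts = organism.split()
    tax = Taxonomy(
        order=next((t for t in lineage if t.endswith("iformes") or t.endswith("formes")), ""),
        family=next((t for t in lineage if t.endswith("idae")), ""),
        genus=parts[0] if parts else "",
        species="_".join(parts[:2]) if len(parts) >= 2 else (parts[0] if parts else ""),
    )
    rec = MitoRecord(
        accession=accession,
        taxonomy=tax,
        definition=definition,
        record_type=RecordType.COMPLETE,
        sequence=sequence,
        features=list(features),
        submitter=submitter,
        geo_origin=geo,
    )
    bio = _to_bio(rec)
    bio.annotations["taxonomy"] = list(lineage)
    out = io.StringIO()
    SeqIO.write(bio, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Trees with planted anomalies
# ---------------------------------------------------------------------------

def _leaf_header(tax: Taxonomy, accession: str,
                 rtype: RecordType = RecordType.COMPLETE) -> str:
    rec = MitoRecord(
        accession=accession, taxonomy=tax, definition="", record_type=rtype,
        sequence="N",
    )
    return format_header(rec)


def _new_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    taxon = tree.taxon_namespace.new_taxon(label)
    node = dendropy.Node(taxon=taxon)
    node.edge.length = 1.0
    return node


def make_tree(
    spec: FixtureSpec, records: list[MitoRecord] | None = None
) -> tuple[TreeWithTaxa, dict[str, str]]:
    """Build a taxonomy-concordant rooted tree, apply plants, return truth.

    The truth dict maps each planted accession to the color a perfect
    detector should assign ("green", "blue", "red"). With no plants the
    tree is fully concordant and the truth dict is empty.

    When ``records`` (e.g. the output of :func:`make_records` for the same
    spec) is given, leaf accessions and per-species counts come from those
    records, so detector flags can be resolved against the generated GenBank
    data downstream.
    """
    rng = random.Random(spec.rng_seed)
    species_list = _build_taxonomy(spec, rng)
    recs_by_species: dict[str, list[MitoRecord]] = {}
    if records is not None:
        for rec in records:
            recs_by_species.setdefault(rec.taxonomy.species, []).append(rec)
        kept = []
        for sp in species_list:
            members = recs_by_species.get(sp.taxonomy.species)
            if members:
                sp.n_seqs = len(members)
                kept.append(sp)
        species_list = kept

    tree = dendropy.Tree()
    tree.is_rooted = True
    leaves: dict[str, LeafInfo] = {}
    acc_counter = 100001

    def next_acc() -> str:
        nonlocal acc_counter
        acc = f"NC_{acc_counter}.1"
        acc_counter += 1
        return acc

    # outgroup clade
    og_tax = Taxonomy(
        order="Zoutiformes", family="Zoutidae", genus="Zoutus", species="Zoutus_rooti"
    )
    og_accessions = []
    og_node = dendropy.Node()
    og_node.edge.length = 1.0
    for i in range(spec.n_outgroup):
        tax = Taxonomy(
            order=og_tax.order, family=og_tax.family, genus=og_tax.genus,
            species=f"Zoutus_rooti{i}",
        )
        acc = f"NC_9{i:05d}.1"  # distinct range, never collides with records
        og_accessions.append(acc)
        label = _leaf_header(tax, acc)
        leaf = _new_leaf(tree, label)
        og_node.add_child(leaf)
        leaves[label] = LeafInfo(accession=acc, taxonomy=tax, record_type=RecordType.COMPLETE)
    if spec.n_outgroup == 1:
        og_node = og_node.child_nodes()[0]

    # nested ingroup clades
    ingroup_node = dendropy.Node()
    ingroup_node.edge.length = 1.0
    genus_nodes: dict[str, dendropy.Node] = {}
    species_nodes: dict[str, dendropy.Node] = {}
    order_nodes: dict[str, dendropy.Node] = {}
    family_nodes: dict[str, dendropy.Node] = {}
    species_leaves: dict[str, list[dendropy.Node]] = {}

    for sp in species_list:
        tax = sp.taxonomy
        if tax.order not in order_nodes:
            node = dendropy.Node()
            node.edge.length = 1.0
            order_nodes[tax.order] = node
            ingroup_node.add_child(node)
        if tax.family not in family_nodes:
            node = dendropy.Node()
            node.edge.length = 1.0
            family_nodes[tax.family] = node
            order_nodes[tax.order].add_child(node)
        if tax.genus not in genus_nodes:
            node = dendropy.Node()
            node.edge.length = 1.0
            genus_nodes[tax.genus] = node
            family_nodes[tax.family].add_child(node)
        members = recs_by_species.get(tax.species) if records is not None else None
        accessions = (
            [m.accession for m in members] if members is not None
            else [next_acc() for _ in range(sp.n_seqs)]
        )
        leaf_nodes = []
        for acc in accessions:
            label = _leaf_header(tax, acc)
            leaf = _new_leaf(tree, label)
            leaf_nodes.append(leaf)
            leaves[label] = LeafInfo(
                accession=acc, taxonomy=tax, record_type=RecordType.COMPLETE
            )
        if len(leaf_nodes) == 1:
            genus_nodes[tax.genus].add_child(leaf_nodes[0])
        else:
            sp_node = dendropy.Node()
            sp_node.edge.length = 1.0
            for leaf in leaf_nodes:
                sp_node.add_child(leaf)
            genus_nodes[tax.genus].add_child(sp_node)
            species_nodes[tax.species] = sp_node
        species_leaves[tax.species] = leaf_nodes

    tree.seed_node.add_child(og_node)
    tree.seed_node.add_child(ingroup_node)

    twt = TreeWithTaxa(
        tree=tree,
        leaves=leaves,
        outgroup_accessions=frozenset(accession_base(a) for a in og_accessions),
    )
    truth = _apply_plants(spec, rng, twt, species_list, species_leaves,
                          genus_nodes, next_acc)
    tree.update_bipartitions(suppress_unifurcations=True)
    return twt, truth


def _graft_sibling_of_genus(
    tree: dendropy.Tree, genus_node: dendropy.Node, leaf: dendropy.Node
) -> None:
    """Insert ``leaf`` as sibling of an entire genus clade."""
    parent = genus_node.parent_node
    joint = dendropy.Node()
    joint.edge.length = 1.0
    parent.remove_child(genus_node)
    parent.add_child(joint)
    joint.add_child(genus_node)
    joint.add_child(leaf)


def _detach_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    # collapse a resulting unifurcation in place
    if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        parent.remove_child(only)
        grand.remove_child(parent)
        grand.add_child(only)


def _apply_plants(
    spec: FixtureSpec,
    rng: random.Random,
    twt: TreeWithTaxa,
    species_list: list[_Species],
    species_leaves: dict[str, list[dendropy.Node]],
    genus_nodes: dict[str, dendropy.Node],
    next_acc,
) -> dict[str, str]:
    truth: dict[str, str] = {}
    used_species: set[str] = set()
    used_families: set[str] = set()
    by_species = {sp.taxonomy.species: sp for sp in species_list}

    def pick_species(pred) -> _Species:
        candidates = sorted(
            (
                sp for sp in species_list
                if pred(sp)
                and sp.taxonomy.species not in used_species
                and sp.taxonomy.family not in used_families
            ),
            key=lambda sp: sp.taxonomy.species,
        )
        if not candidates:
            raise ValueError("bad_spec: no eligible species left for plant")
        chosen = rng.choice(candidates)
        used_species.add(chosen.taxonomy.species)
        used_families.add(chosen.taxonomy.family)
        return chosen

    def pick_host_genus(avoid_order: str) -> str:
        candidates = sorted(
            genus
            for genus, node in genus_nodes.items()
            if node.parent_node is not None
            for sp in [next(s for s in species_list if s.taxonomy.genus == genus)]
            if sp.taxonomy.order != avoid_order
            and sp.taxonomy.family not in used_families
            and sp.taxonomy.species not in used_species
        )
        if not candidates:
            raise ValueError("bad_spec: no eligible host genus for plant")
        genus = rng.choice(candidates)
        fam = next(s for s in species_list if s.taxonomy.genus == genus).taxonomy.family
        used_families.add(fam)
        return genus

    def genus_multi_species(sp: _Species) -> bool:
        return sum(
            1 for other in species_list if other.taxonomy.genus == sp.taxonomy.genus
        ) >= 2

    for kind, count in spec.planted:
        for _ in range(count):
            if kind == "singleton":
                victim = pick_species(lambda sp: sp.n_seqs == 1)
                leaf = species_leaves[victim.taxonomy.species][0]
                # relabel as a brand-new species of a family in another order
                foreign = pick_species(
                    lambda sp: sp.taxonomy.order != victim.taxonomy.order
                )
                new_tax = Taxonomy(
                    order=foreign.taxonomy.order,
                    family=foreign.taxonomy.family,
                    genus=_name(9000 + len(truth)).capitalize() + "us",
                    species=_name(9000 + len(truth)).capitalize() + "us_plantae",
                )
                old_label = leaf.taxon.label
                info = twt.leaves.pop(old_label)
                new_label = _leaf_header(new_tax, info.accession)
                leaf.taxon.label = new_label
                twt.leaves[new_label] = LeafInfo(
                    accession=info.accession, taxonomy=new_tax,
                    record_type=info.record_type,
                )
                del species_leaves[victim.taxonomy.species]
                truth[info.accession] = "green"
            elif kind == "pairwise":
                victim = pick_species(
                    lambda sp: sp.n_seqs == 2 and genus_multi_species(sp)
                )
                moved = species_leaves[victim.taxonomy.species][1]
                host = pick_host_genus(avoid_order=victim.taxonomy.order)
                _detach_leaf(twt.tree, moved)
                _graft_sibling_of_genus(twt.tree, genus_nodes[host], moved)
                truth[twt.leaves[moved.taxon.label].accession] = "blue"
            elif kind == "cluster":
                victim = pick_species(lambda sp: sp.n_seqs >= 3)
                moved = species_leaves[victim.taxonomy.species][-1]
                host = pick_host_genus(avoid_order=victim.taxonomy.order)
                _detach_leaf(twt.tree, moved)
                _graft_sibling_of_genus(twt.tree, genus_nodes[host], moved)
                truth[twt.leaves[moved.taxon.label].accession] = "red"
    return truth


# ---------------------------------------------------------------------------
# Small random labeled trees for oracle tests
# ---------------------------------------------------------------------------

def make_random_labeled_tree(
    n_leaves: int, n_species: int, rng: random.Random
) -> TreeWithTaxa:
    """Random topology with species labels sprinkled arbitrarily over the
    leaves (so monophyly may or may not hold), for brute-force comparisons.

    Every species is guaranteed at least one leaf when
    ``n_leaves >= n_species``. Taxonomy above species level is a small fixed
    pool of genera/families/orders.
    """
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    tree = dendropy.Tree()
    tree.is_rooted = True
    leaves: dict[str, LeafInfo] = {}

    species_pool = []
    for i in range(n_species):
        genus = _name(i // 2 + 1).capitalize() + "us"
        family = _name(i // 4 + 30).capitalize() + "idae"
        order = _name(i // 8 + 60).capitalize() + "iformes"
        species_pool.append(
            Taxonomy(order=order, family=family, genus=genus,
                     species=f"{genus}_{_name(i + 90)}i")
        )

    assignment = [species_pool[i % n_species] for i in range(n_leaves)]
    rng.shuffle(assignment)

    nodes = []
    for i, tax in enumerate(assignment):
        acc = f"NC_{200001 + i}.1"
        label = _leaf_header(tax, acc)
        leaf = _new_leaf(tree, label)
        leaves[label] = LeafInfo(accession=acc, taxonomy=tax, record_type=RecordType.COMPLETE)
        nodes.append(leaf)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        joint = dendropy.Node()
        joint.edge.length = 1.0
        joint.add_child(a)
        joint.add_child(b)
        nodes.append(joint)
    root = nodes[0]
    if root.is_leaf():
        raise ValueError("degenerate")
    tree.seed_node = root
    return TreeWithTaxa(tree=tree, leaves=leaves, outgroup_accessions=frozenset())
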