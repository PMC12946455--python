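"""Order-level grouping, external alignment/tree-inference contract, rooting.

Very large reference libraries cannot be aligned and analysed as one matrix,
so records are partitioned by taxonomic order under a per-file cap (default
2000 sequences). Orders larger than the cap get their own group; the rest are
packed first-fit-decreasing, which is deterministic and near-optimal. The
user-declared outgroup records are forced into every group so each resulting
tree can be rooted consistently.

Alignment and maximum-likelihood inference are external concerns: MAFFT and
FastTree (or any stand-in) are driven through the two-method
:class:`ToolAdapter` contract, and only their I/O contract is validated here
(identical sequence IDs, rectangular alignment, leaf-set preservation).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy

from .records_io import (
    MitoRecord,
    RecordType,
    Taxonomy,
    accession_base,
    format_header,
    parse_header,
)

__all__ = [
    "GroupSpec",
    "TreeWithTaxa",
    "LeafInfo",
    "ToolAdapter",
    "CommandLineTools",
    "ExternalToolError",
    "group_by_order",
    "validate_alignment",
    "align_group",
    "infer_tree",
    "root_tree",
    "write_group_fasta",
]


class ExternalToolError(RuntimeError):
    pass


@dataclass
class GroupSpec:
    """One alignment/tree unit: the records of one or more orders, plus the
    outgroups forced into every group."""

    group_id: str
    member_orders: list[str]
    records: list[MitoRecord]
    outgroups: list[MitoRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        """Ingroup record count (outgroups excluded from the cap)."""
        return len(self.records)


def group_by_order(
    records: Sequence[MitoRecord],
    max_per_file: int = 2000,
    outgroups: Sequence[MitoRecord] = (),
) -> list[GroupSpec]:
    """Partition records into order-level groups under ``max_per_file``.

    Oversized orders become singleton groups (the cap is exceeded by design
    rather than splitting an order); remaining orders are sorted by
    descending count (ties on name) and packed first-fit-decreasing.
    """
    counts: dict[str, int] = {}
    by_order: dict[str, list[MitoRecord]] = {}
    for rec in records:
        if not rec.taxonomy.order:
            raise ValueError(f"unresolved_order: {rec.accession} has no order label")
        counts[rec.taxonomy.order] = counts.get(rec.taxonomy.order, 0) + 1
        by_order.setdefault(rec.taxonomy.order, []).append(rec)

    oversized = sorted(o for o, c in counts.items() if c > max_per_file)
    rest = sorted(
        (o for o, c in counts.items() if c <= max_per_file),
        key=lambda o: (-counts[o], o),
    )

    bins: list[list[str]] = []
    bin_sizes: list[int] = []
    for order in rest:
        for i, used in enumerate(bin_sizes):
            if used + counts[order] <= max_per_file:
                bins[i].append(order)
                bin_sizes[i] += counts[order]
                break
        else:
            bins.append([order])
            bin_sizes.append(counts[order])

    groups: list[GroupSpec] = []
    for orders in [[o] for o in oversized] + bins:
        gid = f"group_{len(groups) + 1:03d}"
        recs = [r for o in orders for r in by_order[o]]
        groups.append(
            GroupSpec(
                group_id=gid,
                member_orders=list(orders),
                records=recs,
                outgroups=list(outgroups),
            )
        )
    return groups


def write_group_fasta(group: GroupSpec, path: Path, sequences: Mapping[str, str] | None = None) -> None:
    """Write a group's FASTA using the pipe-delimited header dialect.

    ``sequences`` optionally overrides the emitted sequence per accession
    (e.g. concatenated multi-locus sequences); defaults to each record's own.
    """
    with open(path, "w") as fh:
        for rec in group.outgroups + group.records:
            seq = (sequences or {}).get(rec.accession, rec.sequence)
            fh.write(f">{format_header(rec)}\n{seq}\n")


class ToolAdapter:
    """Two-method external-tool contract: align a FASTA, infer a tree.

    Implementations receive and return plain strings (FASTA text, Newick
    text) so tests can substitute stubs without touching the filesystem.
    """

    def align(self, fasta_text: str) -> str:
        raise NotImplementedError

    def infer(self, alignment_text: str) -> str:
        raise NotImplementedError


class CommandLineTools(ToolAdapter):
    """Drive MAFFT and FastTree via subprocess.

    ``aligner_args``/``builder_args`` extend the defaults; FastTree runs with
    ``-nt -fastest`` for large nucleotide matrices.
    """

    def __init__(
        self,
        aligner_path: str = "mafft",
        builder_path: str = "fasttree",
        threads: int = 1,
        aligner_args: Sequence[str] = (),
        builder_args: Sequence[str] = ("-nt", "-fastest"),
    ):
        self.aligner_path = aligner_path
        self.builder_path = builder_path
        self.threads = threads
        self.aligner_args = list(aligner_args)
        self.builder_args = list(builder_args)

    def align(self, fasta_text: str) -> str:
        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as tmp:
            tmp.write(fasta_text)
            tmp_path = tmp.name
        cmd = [self.aligner_path, "--thread", str(self.threads), *self.aligner_args, tmp_path]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        Path(tmp_path).unlink(missing_ok=True)
        if proc.returncode != 0:
            raise ExternalToolError(f"aligner_failed: {proc.stderr[-2000:]}")
        return proc.stdout

    def infer(self, alignment_text: str) -> str:
        cmd = [self.builder_path, *self.builder_args]
        proc = subprocess.run(cmd, input=alignment_text, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(f"treebuilder_failed: {proc.stderr[-2000:]}")
        return proc.stdout


def _fasta_ids_and_rows(fasta_text: str) -> dict[str, str]:
    rows: dict[str, str] = {}
    current = None
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            rows[current] = ""
        elif current is not None:
            rows[current] += line.strip()
    return rows


def validate_alignment(input_fasta: str, aligned_fasta: str) -> dict[str, str]:
    """Check the aligner contract: same IDs, rectangular rows."""
    in_ids = set(_fasta_ids_and_rows(input_fasta))
    rows = _fasta_ids_and_rows(aligned_fasta)
    if set(rows) != in_ids:
        raise ExternalToolError("alignment_corrupt: sequence IDs changed")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ExternalToolError("alignment_corrupt: ragged rows")
    return rows


def align_group(group: GroupSpec, aligner: ToolAdapter,
                sequences: Mapping[str, str] | None = None) -> str:
    """Align one group's FASTA through the adapter and validate the result."""
    if not group.records and not group.outgroups:
        raise ValueError("empty group: nothing to align")
    lines = []
    for rec in group.outgroups + group.records:
        seq = (sequences or {}).get(rec.accession, rec.sequence)
        lines.append(f">{format_header(rec)}\n{seq}")
    fasta_text = "\n".join(lines) + "\n"
    aligned = aligner.align(fasta_text)
    validate_alignment(fasta_text, aligned)
    return aligned


def infer_tree(alignment_text: str, builder: ToolAdapter) -> str:
    """Infer a tree from an alignment and check leaf-set preservation."""
    newick = builder.infer(alignment_text)
    ids = set(_fasta_ids_and_rows(alignment_text))
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != ids:
        raise ExternalToolError("tree_corrupt: leaf set differs from alignment IDs")
    return newick


@dataclass(frozen=True)
class LeafInfo:
    """Parsed header attached to one tree leaf."""

    accession: str
    taxonomy: Taxonomy
    record_type: RecordType
    similar_to: tuple[str, ...] = ()


@dataclass
class TreeWithTaxa:
    """A rooted tree whose leaves carry parsed taxonomy, plus the outgroup
    leaf set (by accession base, version-insensitive)."""

    tree: dendropy.Tree
    leaves: dict[str, LeafInfo]  # keyed by leaf label (the full header)
    outgroup_accessions: frozenset[str]  # version-less bases

    def is_outgroup_label(self, label: str) -> bool:
        info = self.leaves[label]
        return accession_base(info.accession) in self.outgroup_accessions

    def ingroup_leaf_nodes(self) -> list[dendropy.Node]:
        return [
            lf for lf in self.tree.leaf_node_iter()
            if not self.is_outgroup_label(lf.taxon.label)
        ]


def root_tree(newick: str | dendropy.Tree, outgroup_accessions: Sequence[str]) -> TreeWithTaxa:
    """Root a tree on the edge subtending the outgroup MRCA.

    Leaf labels must be pipe-delimited headers; they are parsed into
    taxonomy. Outgroup accessions are matched version-insensitively.
    Polytomies are preserved; rooting an already-rooted tree is a no-op on
    topology (idempotent).
    """
    if isinstance(newick, dendropy.Tree):
        tree = newick
    else:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    leaves: dict[str, LeafInfo] = {}
    for lf in tree.leaf_node_iter():
        tax, acc, rtype, similar = parse_header(lf.taxon.label)
        leaves[lf.taxon.label] = LeafInfo(
            accession=acc, taxonomy=tax, record_type=rtype, similar_to=tuple(similar)
        )
    og_bases = frozenset(accession_base(a) for a in outgroup_accessions)
    og_nodes = [
        lf for lf in tree.leaf_node_iter()
        if accession_base(leaves[lf.taxon.label].accession) in og_bases
    ]
    if not og_nodes:
        raise ValueError("outgroup_missing: no outgroup accession found among leaves")
    if len(og_nodes) == 1:
        mrca = og_nodes[0]
    else:
        mrca = tree.mrca(taxa=[n.taxon for n in og_nodes])
    if mrca is not tree.seed_node:
        tree.reroot_at_edge(mrca.edge, update_bipartitions=True,
                            suppress_unifurcations=True)
    tree.is_rooted = True
    return TreeWithTaxa(tree=tree, leaves=leaves, outgroup_accessions=og_bases)
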