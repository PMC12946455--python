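"""Taxonomy-vs-topology anomaly detection on rooted group trees.

Each species' leaves are checked against their placement in the tree and
classified into three flag types, keyed by sequence count:

* **singleton / green** — a species with one sequence whose phylogenetic
  neighborhood shares no rank at or above the configured flag level
  (default: family). Likely an annotation error or isolated misentry.
* **pairwise / blue** — a species with two sequences that do not form a
  clean clade. If exactly one of the two sits with its expected relatives,
  the other is flagged; if neither or both are interspersed among foreign
  species, both are flagged.
* **cluster / red** — a species with three or more sequences that is not
  monophyletic; every leaf outside the largest clean conspecific clade is
  flagged.

"Clusters far from its expected clade" is operationalized deterministically:
walk a leaf's ancestors toward the root and take the first neighborhood of
at least ``min_neighbors`` ingroup, non-conspecific leaves; the best
taxonomic rank shared with any neighbor (genus > family > order > none)
decides the outcome. Outgroup leaves never enter neighborhoods and are never
flagged. Multifurcating trees are handled natively — a clade is any node's
leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .grouping_trees import LeafInfo, TreeWithTaxa

__all__ = [
    "AnomalyFlag",
    "DetectorConfig",
    "TYPE_TO_COLOR",
    "COLOR_TO_TYPE",
    "RANK_VALUE",
    "neighborhood",
    "match_level",
    "species_clean",
    "largest_core_clade",
    "detect_anomalies",
    "TreeDrawing",
    "render_annotated_tree",
]

TYPE_TO_COLOR = {"singleton": "green", "pairwise": "blue", "cluster": "red"}
COLOR_TO_TYPE = {v: k for k, v in TYPE_TO_COLOR.items()}

RANK_VALUE = {"none": 0, "order": 1, "family": 2, "genus": 3}
_COLOR_SORT = {"green": 0, "blue": 1, "red": 2}


@dataclass(frozen=True)
class AnomalyFlag:
    """One typed incongruence attached to a leaf accession."""

    accession: str
    species: str
    anomaly_type: str  # singleton | pairwise | cluster
    group_id: str = ""
    tree_file: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.anomaly_type not in TYPE_TO_COLOR:
            raise ValueError(f"bad_flag: unknown anomaly type {self.anomaly_type!r}")

    @property
    def color(self) -> str:
        return TYPE_TO_COLOR[self.anomaly_type]


@dataclass
class DetectorConfig:
    """Detection parameters.

    ``min_neighbors`` sizes the ancestor-walk neighborhood; ``flag_level``
    is the rank a leaf must share with at least one neighbor to count as
    consistently placed; ``monotypic_fallback`` relaxes singleton checks to
    order level when a species is its family's only representative (a sole
    family member can never find a family-level neighbor, so family-level
    flagging would be a guaranteed false positive).
    """

    min_neighbors: int = 5
    flag_level: str = "family"  # genus | family | order
    monotypic_fallback: bool = True

    def __post_init__(self) -> None:
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if self.flag_level not in ("genus", "family", "order"):
            raise ValueError(f"unknown flag_level {self.flag_level!r}")


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _leafset_map(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set under every node, computed once in postorder."""
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def _excluded_labels(twt: TreeWithTaxa, species: str) -> frozenset[str]:
    """Labels never admitted to a neighborhood for ``species``: its own
    leaves and all outgroup leaves."""
    out = set()
    for label, info in twt.leaves.items():
        if info.taxonomy.species == species or twt.is_outgroup_label(label):
            out.add(label)
    return frozenset(out)


def _walk_neighborhood(
    start: dendropy.Node,
    excluded: frozenset[str],
    min_neighbors: int,
    leafsets: dict[dendropy.Node, frozenset[str]],
) -> frozenset[str]:
    best: frozenset[str] = frozenset()
    node = start.parent_node
    while node is not None:
        collected = leafsets[node] - excluded
        if len(collected) >= min_neighbors:
            return collected
        if len(collected) > len(best):
            best = collected
        node = node.parent_node
    return best


def neighborhood(
    twt: TreeWithTaxa, leaf: dendropy.Node, min_neighbors: int = 5
) -> set[str]:
    """Labels of the nearest >= ``min_neighbors`` ingroup, non-conspecific
    leaves, found by walking the leaf's ancestors toward the root (the
    maximal such set if the tree is too small to reach the threshold)."""
    leafsets = _leafset_map(twt.tree)
    species = twt.leaves[leaf.taxon.label].taxonomy.species
    if len(twt.ingroup_leaf_nodes()) < 2:
        raise ValueError("degenerate_tree: fewer than 2 ingroup leaves")
    excluded = _excluded_labels(twt, species)
    return set(_walk_neighborhood(leaf, excluded, min_neighbors, leafsets))


def match_level(leaf_info: LeafInfo, neighbor_infos: list[LeafInfo]) -> str:
    """Best taxonomic rank the leaf shares with any neighbor."""
    tax = leaf_info.taxonomy
    if any(n.taxonomy.genus == tax.genus for n in neighbor_infos):
        return "genus"
    if any(n.taxonomy.family == tax.family for n in neighbor_infos):
        return "family"
    if any(n.taxonomy.order == tax.order for n in neighbor_infos):
        return "order"
    return "none"


def _species_leaf_nodes(twt: TreeWithTaxa, species: str) -> list[dendropy.Node]:
    return [
        lf for lf in twt.tree.leaf_node_iter()
        if twt.leaves[lf.taxon.label].taxonomy.species == species
        and not twt.is_outgroup_label(lf.taxon.label)
    ]


def _mrca_by_leafsets(
    leafsets: dict[dendropy.Node, frozenset[str]],
    start_leaf: dendropy.Node,
    target_labels: frozenset[str],
) -> dendropy.Node:
    node = start_leaf
    while not target_labels <= leafsets[node]:
        node = node.parent_node
    return node


def _species_clean(
    nodes: list[dendropy.Node],
    leafsets: dict[dendropy.Node, frozenset[str]],
) -> bool:
    labels = frozenset(n.taxon.label for n in nodes)
    mrca = _mrca_by_leafsets(leafsets, nodes[0], labels)
    return leafsets[mrca] == labels


def species_clean(twt: TreeWithTaxa, species: str) -> bool:
    """True iff the species is monophyletic with no intruders: the leaf set
    under the MRCA of its leaves is exactly its own leaves."""
    nodes = _species_leaf_nodes(twt, species)
    if len(nodes) < 2:
        raise ValueError("species_clean requires >= 2 leaves")
    return _species_clean(nodes, _leafset_map(twt.tree))


def _neighborhood_level(
    twt: TreeWithTaxa,
    node: dendropy.Node,
    species: str,
    min_neighbors: int,
    leafsets: dict[dendropy.Node, frozenset[str]],
    excluded: frozenset[str],
) -> int:
    """RANK_VALUE of the best rank shared between ``species`` and the
    neighborhood of ``node`` (a leaf or the root of a conspecific clade)."""
    labels = _walk_neighborhood(node, excluded, min_neighbors, leafsets)
    probe = next(
        info for info in twt.leaves.values() if info.taxonomy.species == species
    )
    infos = [twt.leaves[l] for l in labels]
    return RANK_VALUE[match_level(probe, infos)]


def largest_core_clade(
    twt: TreeWithTaxa, species: str, min_neighbors: int = 5
) -> set[str]:
    """Leaf labels of the species' main clade: the largest clade containing
    only conspecific leaves.

    Ties go to the clade whose neighborhood shares the highest rank with the
    species, then to the earliest node in preorder. When no two conspecific
    leaves form a clean clade the core degenerates to the single leaf with
    the best-matching neighborhood (ties: lexicographically smallest
    accession).
    """
    species_labels = frozenset(
        n.taxon.label for n in _species_leaf_nodes(twt, species)
    )
    if len(species_labels) < 3:
        raise ValueError("largest_core_clade requires >= 3 leaves")
    leafsets = _leafset_map(twt.tree)
    excluded = _excluded_labels(twt, species)

    candidates: list[tuple[int, dendropy.Node, frozenset[str]]] = []
    for idx, node in enumerate(twt.tree.preorder_node_iter()):
        ls = leafsets[node]
        if ls <= species_labels:
            candidates.append((idx, node, ls))
    max_size = max(len(ls) for _, _, ls in candidates)
    if max_size == 1:
        best = min(
            (lf for lf in _species_leaf_nodes(twt, species)),
            key=lambda lf: (
                -_neighborhood_level(twt, lf, species, min_neighbors, leafsets, excluded),
                twt.leaves[lf.taxon.label].accession,
            ),
        )
        return {best.taxon.label}
    top = [c for c in candidates if len(c[2]) == max_size]
    idx, node, ls = min(
        top,
        key=lambda c: (
            -_neighborhood_level(twt, c[1], species, min_neighbors, leafsets, excluded),
            c[0],
        ),
    )
    return set(ls)


# ---------------------------------------------------------------------------
# main classifier
# ---------------------------------------------------------------------------

def detect_anomalies(
    twt: TreeWithTaxa,
    cfg: DetectorConfig | None = None,
    group_id: str = "",
    tree_file: str = "",
) -> list[AnomalyFlag]:
    """Classify every ingroup species on one rooted tree into flags.

    The returned list is sorted by (color, species, accession) and is a pure
    function of the tree and config. Outgroup leaves are never flagged.
    """
    cfg = cfg or DetectorConfig()
    ingroup = twt.ingroup_leaf_nodes()
    if not ingroup:
        raise ValueError("degenerate_tree: no ingroup leaves")
    if len(ingroup) < 2:
        raise ValueError("degenerate_tree: fewer than 2 ingroup leaves")

    leafsets = _leafset_map(twt.tree)
    by_species: dict[str, list[dendropy.Node]] = {}
    species_by_family: dict[str, set[str]] = {}
    for lf in ingroup:
        info = twt.leaves[lf.taxon.label]
        by_species.setdefault(info.taxonomy.species, []).append(lf)
        species_by_family.setdefault(info.taxonomy.family, set()).add(
            info.taxonomy.species
        )

    flag_threshold = RANK_VALUE[cfg.flag_level]
    flags: list[AnomalyFlag] = []

    def leaf_level(lf: dendropy.Node, species: str, excluded: frozenset[str]) -> int:
        labels = _walk_neighborhood(lf, excluded, cfg.min_neighbors, leafsets)
        infos = [twt.leaves[l] for l in labels]
        return RANK_VALUE[match_level(twt.leaves[lf.taxon.label], infos)]

    for species, nodes in by_species.items():
        excluded = _excluded_labels(twt, species)
        info0 = twt.leaves[nodes[0].taxon.label]

        if len(nodes) == 1:
            threshold = flag_threshold
            sole_family_rep = species_by_family[info0.taxonomy.family] == {species}
            if cfg.monotypic_fallback and sole_family_rep:
                threshold = min(threshold, RANK_VALUE["order"])
            if leaf_level(nodes[0], species, excluded) < threshold:
                flags.append(_flag(twt, nodes[0], "singleton", group_id, tree_file,
                                   note="single sequence placed outside expected clade"))
            continue

        if len(nodes) == 2:
            if _species_clean(nodes, leafsets):
                continue
            levels = [leaf_level(n, species, excluded) for n in nodes]
            passing = [lvl >= flag_threshold for lvl in levels]
            if sum(passing) == 1:
                bad = nodes[0] if passing[1] else nodes[1]
                flags.append(_flag(twt, bad, "pairwise", group_id, tree_file,
                                   note="conspecific pair split; this leaf misplaced"))
            else:
                for n in nodes:
                    flags.append(_flag(twt, n, "pairwise", group_id, tree_file,
                                       note="conspecific pair split; placement unclear"))
            continue

        if _species_clean(nodes, leafsets):
            continue
        core = largest_core_clade(twt, species, cfg.min_neighbors)
        for n in nodes:
            if n.taxon.label not in core:
                flags.append(_flag(twt, n, "cluster", group_id, tree_file,
                                   note="diverges from the species' main clade"))

    flags.sort(key=lambda f: (_COLOR_SORT[f.color], f.species, f.accession))
    return flags


def _flag(
    twt: TreeWithTaxa,
    node: dendropy.Node,
    anomaly_type: str,
    group_id: str,
    tree_file: str,
    note: str,
) -> AnomalyFlag:
    info = twt.leaves[node.taxon.label]
    return AnomalyFlag(
        accession=info.accession,
        species=info.taxonomy.species,
        anomaly_type=anomaly_type,
        group_id=group_id,
        tree_file=tree_file,
        note=note,
    )


# ---------------------------------------------------------------------------
# annotated tree rendering
# ---------------------------------------------------------------------------

@dataclass
class TreeDrawing:
    """Inspectable drawing model for one annotated tree.

    ``labels`` holds (text, x, y, color) per leaf; ``segments`` holds the
    branch line coordinates ((x0, y0), (x1, y1)). Rendering to PDF is a
    separate, pure-output step.
    """

    labels: list[tuple[str, float, float, str]] = field(default_factory=list)
    segments: list[tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=list)
    title: str = ""

    def save(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = max(len(self.labels), 1)
        fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * n)))
        for (x0, y0), (x1, y1) in self.segments:
            ax.plot([x0, x1], [y0, y1], color="0.4", linewidth=0.8)
        for text, x, y, color in self.labels:
            ax.text(x, y, " " + text, color=color, fontsize=5, va="center")
        ax.set_title(self.title, fontsize=8)
        ax.axis("off")
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)


def render_annotated_tree(
    twt: TreeWithTaxa, flags: list[AnomalyFlag], title: str = ""
) -> TreeDrawing:
    """Build the drawing model: rectangular layout, flagged leaves colored
    by anomaly type, outgroup leaves marked. Never mutates the flag list."""
    color_by_acc = {f.accession: f.color for f in flags}
    drawing = TreeDrawing(title=title)

    ys: dict[dendropy.Node, float] = {}
    xs: dict[dendropy.Node, float] = {}
    next_y = 0.0
    for node in twt.tree.postorder_node_iter():
        if node.is_leaf():
            ys[node] = next_y
            next_y += 1.0
        else:
            kids = node.child_nodes()
            ys[node] = sum(ys[k] for k in kids) / len(kids)
    for node in twt.tree.preorder_node_iter():
        parent = node.parent_node
        xs[node] = 0.0 if parent is None else xs[parent] + 1.0

    for node in twt.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            drawing.segments.append(((xs[parent], ys[parent]), (xs[parent], ys[node])))
            drawing.segments.append(((xs[parent], ys[node]), (xs[node], ys[node])))
        if node.is_leaf():
            label = node.taxon.label
            info = twt.leaves[label]
            color = color_by_acc.get(info.accession, "black")
            text = label + (" [outgroup]" if twt.is_outgroup_label(label) else "")
            drawing.labels.append((text, xs[node], ys[node], color))
    return drawing
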