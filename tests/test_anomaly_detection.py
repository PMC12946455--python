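"""Neighborhoods, monophyly checks, core clades, and the three flag types."""

import random

import dendropy
import pytest

from mitoref import fixtures as fx
from mitoref.anomaly_detection import (
    DetectorConfig,
    detect_anomalies,
    largest_core_clade,
    match_level,
    neighborhood,
    render_annotated_tree,
    species_clean,
)
from mitoref.grouping_trees import LeafInfo, TreeWithTaxa
from mitoref.records_io import RecordType, Taxonomy, format_header

from conftest import make_record


def _label(species, acc, order="Aiformes", family="Aidae"):
    return format_header(make_record(acc, species=species, order=order, family=family))


def _tree_from_newick(newick: str, outgroups=()) -> TreeWithTaxa:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    leaves = {}
    from mitoref.records_io import parse_header

    for lf in tree.leaf_node_iter():
        tax, acc, rtype, similar = parse_header(lf.taxon.label)
        leaves[lf.taxon.label] = LeafInfo(accession=acc, taxonomy=tax, record_type=rtype)
    return TreeWithTaxa(tree=tree, leaves=leaves,
                        outgroup_accessions=frozenset(outgroups))


def _leaf(twt, accession):
    for lf in twt.tree.leaf_node_iter():
        if twt.leaves[lf.taxon.label].accession == accession:
            return lf
    raise KeyError(accession)


class TestNeighborhood:
    def test_cherry_neighbor(self):
        x = _label("Aus_xi", "NC_1.1")
        y = _label("Aus_yi", "NC_2.1")
        z = _label("Aus_zi", "NC_3.1")
        twt = _tree_from_newick(f"(({x},{y}),{z});")
        assert neighborhood(twt, _leaf(twt, "NC_1.1"), min_neighbors=1) == {y}

    def test_caterpillar_matches_bruteforce(self):
        labels = [_label(f"Aus_sp{i}i", f"NC_{i}.1") for i in range(7)]
        newick = labels[0]
        for lab in labels[1:]:
            newick = f"({newick},{lab})"
        twt = _tree_from_newick(newick + ";")
        target = _leaf(twt, "NC_0.1")
        # brute force: enumerate leaf sets of the target's ancestors
        ancestor_sets = []
        node = target.parent_node
        while node is not None:
            ancestor_sets.append(
                {lf.taxon.label for lf in node.leaf_iter()} - {target.taxon.label}
            )
            node = node.parent_node
        expected = next(s for s in ancestor_sets if len(s) >= 3)
        assert neighborhood(twt, target, min_neighbors=3) == expected

    def test_conspecifics_excluded(self):
        a1 = _label("Aus_xi", "NC_1.1")
        a2 = _label("Aus_xi", "NC_2.1")
        b = _label("Aus_yi", "NC_3.1")
        c = _label("Bus_zi", "NC_4.1")
        twt = _tree_from_newick(f"((({a1},{a2}),{b}),{c});")
        nb = neighborhood(twt, _leaf(twt, "NC_1.1"), min_neighbors=1)
        assert a2 not in nb and nb == {b}


class TestMatchLevel:
    def _info(self, order, family, genus):
        return LeafInfo(
            accession="NC_0.1",
            taxonomy=Taxonomy(order=order, family=family, genus=genus,
                              species=f"{genus}_xi"),
            record_type=RecordType.COMPLETE,
        )

    def test_best_rank_wins(self):
        leaf = self._info("O1", "F1", "G1")
        neighbors = [self._info("O1", "F2", "G9")] * 10 + [self._info("O1", "F1", "G1")]
        assert match_level(leaf, neighbors) == "genus"

    def test_family_mismatch_caps_at_order(self):
        leaf = self._info("Pempheriformes", "Pempheridae", "Pempheris")
        neighbors = [self._info("Pempheriformes", "Cepolidae", "Cepola")]
        assert match_level(leaf, neighbors) == "order"

    def test_truth_table_matches_set_oracle(self):
        ranks = ["O1", "O2"], ["F1", "F2"], ["G1", "G2"]
        leaf = self._info("O1", "F1", "G1")
        for order in ranks[0]:
            for family in ranks[1]:
                for genus in ranks[2]:
                    neighbor = self._info(order, family, genus)
                    got = match_level(leaf, [neighbor])
                    if genus == "G1":
                        assert got == "genus"
                    elif family == "F1":
                        assert got == "family"
                    elif order == "O1":
                        assert got == "order"
                    else:
                        assert got == "none"


def _brute_clean(twt, species):
    species_leaves = {
        lbl for lbl, info in twt.leaves.items() if info.taxonomy.species == species
    }
    all_clades = [
        {lf.taxon.label for lf in node.leaf_iter()}
        for node in twt.tree.preorder_node_iter()
    ]
    return species_leaves in all_clades


def _brute_core_size(twt, species):
    species_leaves = {
        lbl for lbl, info in twt.leaves.items() if info.taxonomy.species == species
    }
    best = 0
    for node in twt.tree.preorder_node_iter():
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade <= species_leaves:
            best = max(best, len(clade))
    return best


class TestSpeciesClean:
    def test_cherry_is_clean(self):
        a1 = _label("Aus_xi", "NC_1.1")
        a2 = _label("Aus_xi", "NC_2.1")
        b = _label("Aus_yi", "NC_3.1")
        twt = _tree_from_newick(f"(({a1},{a2}),{b});")
        assert species_clean(twt, "Aus_xi")

    def test_interleaved_pair_dirty_for_both(self):
        b1 = _label("Epinephelus_bruneusi", "NC_013820.1")
        b2 = _label("Epinephelus_bruneusi", "JQ518289.1")
        m1 = _label("Epinephelus_moarai", "NC_017891.1")
        m2 = _label("Epinephelus_moarai", "KP009977.1")
        twt = _tree_from_newick(f"((({b1},{m1}),{b2}),{m2});")
        assert not species_clean(twt, "Epinephelus_bruneusi")
        assert not species_clean(twt, "Epinephelus_moarai")

    def test_agrees_with_bruteforce_on_small_trees(self):
        rng = random.Random(10)
        checked = 0
        for _ in range(300):
            n = rng.randint(4, 10)
            twt = fx.make_random_labeled_tree(n, rng.randint(2, 4), rng)
            for species in {i.taxonomy.species for i in twt.leaves.values()}:
                leaves = [
                    l for l, i in twt.leaves.items() if i.taxonomy.species == species
                ]
                if len(leaves) >= 2:
                    assert species_clean(twt, species) == _brute_clean(twt, species)
                    checked += 1
        assert checked > 200


class TestLargestCoreClade:
    def test_three_plus_one(self):
        core = [_label("Aus_xi", f"NC_{i}.1") for i in range(3)]
        stray = _label("Aus_xi", "NC_9.1")
        others = [_label(f"Bus_sp{i}i", f"AB{i}.1") for i in range(3)]
        newick = (
            f"((({core[0]},{core[1]}),{core[2]}),"
            f"(({others[0]},{stray}),({others[1]},{others[2]})));"
        )
        twt = _tree_from_newick(newick)
        result = largest_core_clade(twt, "Aus_xi", min_neighbors=2)
        assert {twt.leaves[l].accession for l in result} == {"NC_0.1", "NC_1.1", "NC_2.1"}

    def test_fully_scattered_floor(self):
        mine = [_label("Aus_xi", f"NC_{i}.1") for i in range(3)]
        others = [_label(f"Bus_sp{i}i", f"AB{i}.1") for i in range(3)]
        newick = (
            f"((({mine[0]},{others[0]}),({mine[1]},{others[1]})),"
            f"({mine[2]},{others[2]}));"
        )
        twt = _tree_from_newick(newick)
        result = largest_core_clade(twt, "Aus_xi", min_neighbors=1)
        assert len(result) == 1

    def test_size_agrees_with_bruteforce(self):
        rng = random.Random(11)
        checked = 0
        for _ in range(300):
            n = rng.randint(5, 12)
            twt = fx.make_random_labeled_tree(n, rng.randint(2, 3), rng)
            for species in {i.taxonomy.species for i in twt.leaves.values()}:
                leaves = [
                    l for l, i in twt.leaves.items() if i.taxonomy.species == species
                ]
                if len(leaves) >= 3 and not species_clean(twt, species):
                    core = largest_core_clade(twt, species, min_neighbors=2)
                    assert len(core) == _brute_core_size(twt, species)
                    assert core <= set(leaves)
                    checked += 1
        assert checked > 100


class TestDetectAnomalies:
    def test_concordant_tree_yields_no_flags(self):
        twt, truth = fx.make_tree(fx.FixtureSpec(rng_seed=42))
        assert truth == {}
        assert detect_anomalies(twt) == []

    def test_planted_singleton_recovered(self):
        spec = fx.FixtureSpec(rng_seed=1, planted=(("singleton", 1),))
        twt, truth = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        assert {(f.accession, f.color) for f in flags} == set(truth.items())
        assert all(f.color == "green" for f in flags)

    def test_displaced_pair_member_flagged_blue(self):
        spec = fx.FixtureSpec(rng_seed=2, planted=(("pairwise", 1),))
        twt, truth = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        assert len(flags) == 1
        assert flags[0].color == "blue"
        assert {flags[0].accession} == set(truth)

    def test_cluster_minority_flagged_red(self):
        spec = fx.FixtureSpec(rng_seed=3, planted=(("cluster", 1),))
        twt, truth = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        assert {(f.accession, f.color) for f in flags} == set(truth.items())
        assert all(f.color == "red" for f in flags)

    def test_both_pair_members_flagged_when_both_astray(self):
        # two conspecific leaves, each inside a different foreign genus
        a1 = _label("Aus_xi", "NC_1.1", family="F1idae")
        a2 = _label("Aus_xi", "NC_2.1", family="F1idae")
        g1 = [_label(f"Bus_sp{i}i", f"AB1{i}.1", family="F2idae") for i in range(3)]
        g2 = [_label(f"Cus_sp{i}i", f"AB2{i}.1", family="F3idae") for i in range(3)]
        newick = (
            f"((({g1[0]},{a1}),({g1[1]},{g1[2]})),"
            f"(({g2[0]},{a2}),({g2[1]},{g2[2]})));"
        )
        twt = _tree_from_newick(newick)
        cfg = DetectorConfig(min_neighbors=2)
        flags = detect_anomalies(twt, cfg)
        blue = {f.accession for f in flags if f.color == "blue"}
        assert blue == {"NC_1.1", "NC_2.1"}

    def test_outgroups_never_flagged(self):
        spec = fx.FixtureSpec(rng_seed=4, planted=(("singleton", 1), ("cluster", 1)))
        twt, truth = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        og = twt.outgroup_accessions
        from mitoref.records_io import accession_base

        assert all(accession_base(f.accession) not in og for f in flags)

    def test_flag_list_sorted_and_deterministic(self):
        spec = fx.FixtureSpec(
            rng_seed=5, n_orders=4, families_per_order=3,
            planted=(("singleton", 2), ("cluster", 1)),
        )
        twt, _ = fx.make_tree(spec)
        flags1 = detect_anomalies(twt)
        flags2 = detect_anomalies(twt)
        assert flags1 == flags2
        order = {"green": 0, "blue": 1, "red": 2}
        keys = [(order[f.color], f.species, f.accession) for f in flags1]
        assert keys == sorted(keys)


class TestRendering:
    def test_no_flags_no_colored_leaves(self):
        twt, _ = fx.make_tree(fx.FixtureSpec(rng_seed=6))
        drawing = render_annotated_tree(twt, [])
        assert all(color == "black" for _, _, _, color in drawing.labels)
        assert len(drawing.labels) == len(twt.leaves)

    def test_three_colors_in_drawing_model(self):
        spec = fx.FixtureSpec(
            rng_seed=7, n_orders=4, families_per_order=3,
            planted=(("singleton", 1), ("pairwise", 1), ("cluster", 1)),
        )
        twt, _ = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        drawing = render_annotated_tree(twt, flags)
        colors = {c for _, _, _, c in drawing.labels}
        assert {"green", "blue", "red"} <= colors

    def test_rendering_is_pure(self):
        spec = fx.FixtureSpec(rng_seed=8, planted=(("cluster", 1),))
        twt, _ = fx.make_tree(spec)
        flags = detect_anomalies(twt)
        before = list(flags)
        render_annotated_tree(twt, flags)
        assert flags == before

    def test_pdf_written(self, tmp_path):
        twt, _ = fx.make_tree(fx.FixtureSpec(rng_seed=9, n_orders=1,
                                             families_per_order=1))
        drawing = render_annotated_tree(twt, [], title="g1")
        out = tmp_path / "g1.pdf"
        drawing.save(out)
        assert out.stat().st_size > 0
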