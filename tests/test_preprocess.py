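"""Record-level filtering and species-level subsampling contracts."""

import random

import pytest

from mitoref.preprocess import (
    FilterConfig,
    RejectReason,
    filter_records,
    has_ambiguous_qualifier,
    is_complete_definition,
    refseq_dedup,
    subsample_species,
)

from conftest import feature_12s, make_record


class TestCompleteDefinition:
    @pytest.mark.parametrize(
        "definition,expected",
        [
            ("Pempheris schwenkii mitochondrion, complete genome", True),
            ("Carassius auratus 12S ribosomal RNA gene, partial sequence", False),
            ("COMPLETE MITOCHONDRIAL GENOME", True),
            ("Salmo salar whole mitochondrion sequence", True),
            ("", False),
        ],
    )
    def test_keyword_match(self, definition, expected):
        assert is_complete_definition(definition) is expected

    def test_extensible_keywords(self):
        assert not is_complete_definition("mitogenomic assembly, finished")
        assert is_complete_definition("mitogenomic assembly, finished", ["finished"])


class TestAmbiguousQualifier:
    @pytest.mark.parametrize(
        "organism,expected",
        [
            ("Epinephelus sp. BH-2014", "sp."),
            ("Carassius auratus x Cyprinus carpio", "hybrid-x"),
            ("Pempheris schwenkii", None),
            ("Pogona spilota", None),          # "sp." must be a standalone token
            ("Sebastes cf. mentella A-12", "cf."),
            ("Salvelinus alpinus ssp. oquassa", "ssp."),
            ("Xiphias gladius", None),          # leading X is not a hybrid marker
        ],
    )
    def test_token_matching(self, organism, expected):
        assert has_ambiguous_qualifier(organism) == expected

    def test_keep_override_suppresses(self):
        cfg = FilterConfig(keep_sp=True)
        assert has_ambiguous_qualifier("Epinephelus sp. BH-2014", cfg) is None


class TestRefseqDedup:
    def test_refseq_twin_wins(self):
        nc = make_record("NC_000001.1", sequence="ACGT" * 100)
        twin = make_record("AB123456.1", sequence="ACGT" * 100)
        outcome = refseq_dedup([nc, twin])
        assert outcome.kept == [nc]
        assert outcome.rejected == [(twin, RejectReason.DUPLICATE_OF_REFSEQ)]

    def test_identical_non_refseq_pair_kept_here(self):
        a = make_record("AB000001.1", sequence="ACGT" * 50)
        b = make_record("AB000002.1", sequence="ACGT" * 50)
        outcome = refseq_dedup([a, b])
        assert len(outcome.kept) == 2

    def test_no_kept_nonrefseq_shadows_a_refseq(self):
        rng = random.Random(3)
        seqs = ["".join(rng.choice("ACGT") for _ in range(40)) for _ in range(5)]
        records = [
            make_record(
                ("NC_%06d.1" if rng.random() < 0.5 else "AB%06d.1") % i,
                sequence=rng.choice(seqs),
            )
            for i in range(60)
        ]
        outcome = refseq_dedup(records)
        refseq_seqs = {r.sequence for r in outcome.kept if r.is_refseq}
        assert not any(
            r.sequence in refseq_seqs for r in outcome.kept if not r.is_refseq
        )
        assert len(outcome.kept) + len(outcome.rejected) == len(records)


def _ten_record_mix():
    records = [
        make_record(f"NC_{i:06d}.1", species=f"Testus_sp{i}i") for i in range(6)
    ]
    for i, length in ((6, 800), (7, 500)):
        seq = "ACGT" * (length // 4)
        records.append(
            make_record(
                f"AB{i:06d}.1", species=f"Testus_sp{i}i",
                definition=f"Testus sp{i}i 12S ribosomal RNA gene, partial sequence",
                sequence=seq, features=(feature_12s(1, length),),
            )
        )
    records.append(
        make_record(
            "AB000008.1", species="Testus_sp8i",
            definition="Testus sp8i 12S ribosomal RNA gene, partial sequence",
            sequence="ACGT" * 37 + "AC", features=(feature_12s(1, 150),),
        )
    )
    records.append(make_record("AB000009.1", species="Testus_sp."))
    return records


class TestFilterRecords:
    def test_complete_vs_gene_mode(self):
        records = _ten_record_mix()
        complete = filter_records(records, FilterConfig(mode="complete"))
        assert len(complete.kept) == 6
        gene = filter_records(records, FilterConfig(mode="gene", target_genes=("12S",)))
        assert len(gene.kept) == 8
        for outcome in (complete, gene):
            reasons = {r.accession: reason for r, reason in outcome.rejected}
            assert reasons["AB000009.1"] is RejectReason.AMBIGUOUS_QUALIFIER

    def test_short_fragment_rejected(self):
        records = _ten_record_mix()
        gene = filter_records(records, FilterConfig(mode="gene", target_genes=("12S",)))
        reasons = {r.accession: reason for r, reason in gene.rejected}
        assert reasons["AB000008.1"] is RejectReason.TOO_SHORT

    def test_399bp_fragment_under_default_threshold(self):
        frag = make_record(
            "AB999999.1", definition="Testus alphai 12S rRNA gene, partial sequence",
            sequence="A" * 399, features=(feature_12s(1, 399),),
        )
        outcome = filter_records([frag], FilterConfig(mode="gene", target_genes=("12S",)))
        assert outcome.rejected[0][1] is RejectReason.TOO_SHORT

    def test_unannotated_record_retained_in_gene_mode(self):
        bare = make_record(
            "AB777777.1", definition="Testus alphai partial sequence",
            sequence="A" * 450, features=(),
        )
        outcome = filter_records([bare], FilterConfig(mode="gene", target_genes=("12S",)))
        assert outcome.kept == [bare]

    def test_empty_input(self):
        outcome = filter_records([], FilterConfig())
        assert outcome.kept == [] and outcome.rejected == []

    def test_contradictory_config_rejected(self):
        with pytest.raises(ValueError, match="bad_config"):
            FilterConfig(mode="gene", target_genes=())


class TestSubsample:
    def test_under_quota_keeps_all(self):
        group = [make_record(f"AB{i}.1", species="Testus_alphai") for i in range(3)]
        kept, overflow, pre = subsample_species(group, FilterConfig())
        assert len(kept) == 3 and overflow == [] and pre == 3

    def test_origin_collapse_and_determinism(self):
        keys = [("lab_a", "China"), ("lab_b", "Japan"), ("lab_c", "")]
        group = [
            make_record(
                f"AB{i:03d}.1", species="Testus_alphai",
                submitter=keys[i % 3][0], geo=keys[i % 3][1],
            )
            for i in range(9)
        ]
        cfg = FilterConfig(rng_seed=11)
        kept, overflow, pre = subsample_species(group, cfg)
        assert pre == 9
        assert len(kept) <= 5
        surviving_keys = {(r.submitter, r.geo_origin) for r in kept}
        assert surviving_keys == set(keys)
        again, _, _ = subsample_species(list(reversed(group)), cfg)
        assert [r.accession for r in again] == [r.accession for r in kept]

    def test_gene_mode_ranks_fragments_by_target_length(self):
        completes = [
            make_record(f"NC_{i}.1", species="Testus_alphai")
            for i in range(2)
        ]
        frags = []
        for i, length in enumerate((950, 900, 800, 400, 400)):
            rng = random.Random(f"frag{i}")
            frags.append(
                make_record(
                    f"AB{i:03d}.1", species="Testus_alphai",
                    definition="Testus alphai 12S rRNA gene, partial sequence",
                    sequence="".join(rng.choice("ACGT") for _ in range(length)),
                    features=(feature_12s(1, length),),
                )
            )
        cfg = FilterConfig(mode="gene", target_genes=("12S",))
        kept, overflow, _ = subsample_species(completes + frags, cfg)
        assert len(kept) == 5
        kept_accs = {r.accession for r in kept}
        assert {c.accession for c in completes} <= kept_accs
        assert {"AB000.1", "AB001.1", "AB002.1"} <= kept_accs

    def test_random_sets_hold_contracts(self):
        rng = random.Random(5)
        for trial in range(200):
            n = rng.randint(1, 12)
            group = [
                make_record(
                    f"AB{trial:03d}{i:02d}.1", species="Testus_alphai",
                    submitter=rng.choice(["a", "b", "c"]),
                    geo=rng.choice(["x", "y", ""]),
                    sequence="".join(rng.choice("ACGT") for _ in range(50)),
                )
                for i in range(n)
            ]
            cfg = FilterConfig(rng_seed=trial)
            kept, overflow, pre = subsample_species(group, cfg)
            assert pre == n
            assert len(kept) <= cfg.max_sequences
            assert len(kept) + len(overflow) == n
            kept_accs = {r.accession for r in kept}
            over_accs = {r.accession for r, _ in overflow}
            assert kept_accs.isdisjoint(over_accs)

    def test_min_length_monotonicity(self):
        rng = random.Random(6)
        records = []
        for i in range(40):
            length = rng.randint(100, 1200)
            records.append(
                make_record(
                    f"AB{i:04d}.1", species=f"Testus_sp{i}i",
                    definition="Testus 12S rRNA gene, partial sequence",
                    sequence="A" * length, features=(feature_12s(1, length),),
                )
            )
        kept_sets = []
        for threshold in (200, 400, 800):
            cfg = FilterConfig(mode="gene", target_genes=("12S",), min_gene_length=threshold)
            kept_sets.append({r.accession for r in filter_records(records, cfg).kept})
        assert kept_sets[2] <= kept_sets[1] <= kept_sets[0]
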