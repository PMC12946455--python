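"""Synonym-tolerant gene location, excision and multi-locus concatenation.

Mitochondrial gene annotations in public records are notoriously inconsistent:
the small-subunit rRNA alone appears as "12S", "12S rRNA", "s-rRNA" or
"small subunit ribosomal RNA", and cytochrome c oxidase subunit I as "COI",
"CO1", "COX1" or its full product name. Matching therefore runs a table of
case-insensitive, boundary-anchored patterns against the gene, product and
note qualifiers of every CDS/rRNA feature.

Excised genes are strand-corrected (minus-strand features are
reverse-complemented) and concatenated in the canonical vertebrate
mitogenome gene order. When nothing can be extracted from a record, the full
sequence is carried forward instead so the record is never silently lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .records_io import GeneFeature, MitoRecord, Strand

__all__ = [
    "CANONICAL_GENE_ORDER",
    "DEFAULT_SYNONYMS",
    "GeneSynonymTable",
    "ExtractionResult",
    "match_gene",
    "find_feature",
    "extract_gene",
    "concat_genes",
    "validate_table",
]

# Standard vertebrate mitochondrial gene order used for concatenation.
CANONICAL_GENE_ORDER = (
    "12S", "16S", "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6",
    "COX3", "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

# Alphanumeric boundary guards: "ND4" must not fire inside "ND4L", "COX1"
# not inside "COX13", "subunit I" not inside "subunit III".
_B = r"(?<![A-Za-z0-9])"
_E = r"(?![A-Za-z0-9])"

DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "12S": ("12S", "12S rRNA", "12S ribosomal RNA", "s-rRNA", "srRNA",
            "small subunit ribosomal RNA", "rrnS"),
    "16S": ("16S", "16S rRNA", "16S ribosomal RNA", "l-rRNA", "lrRNA",
            "large subunit ribosomal RNA", "rrnL"),
    "ND1": ("ND1", "NAD1", "NADH1", "NADH dehydrogenase subunit 1"),
    "ND2": ("ND2", "NAD2", "NADH2", "NADH dehydrogenase subunit 2"),
    "ND3": ("ND3", "NAD3", "NADH3", "NADH dehydrogenase subunit 3"),
    "ND4": ("ND4", "NAD4", "NADH4", "NADH dehydrogenase subunit 4"),
    "ND4L": ("ND4L", "NAD4L", "NADH4L", "NADH dehydrogenase subunit 4L"),
    "ND5": ("ND5", "NAD5", "NADH5", "NADH dehydrogenase subunit 5"),
    "ND6": ("ND6", "NAD6", "NADH6", "NADH dehydrogenase subunit 6"),
    "COX1": ("COI", "CO1", "COX1", "COXI", "cytochrome c oxidase subunit I",
             "cytochrome oxidase subunit I", "cytochrome oxidase subunit 1",
             "cytochrome c oxidase subunit 1"),
    "COX2": ("COII", "CO2", "COX2", "COXII", "cytochrome c oxidase subunit II",
             "cytochrome oxidase subunit II", "cytochrome oxidase subunit 2",
             "cytochrome c oxidase subunit 2"),
    "COX3": ("COIII", "CO3", "COX3", "COXIII", "cytochrome c oxidase subunit III",
             "cytochrome oxidase subunit III", "cytochrome oxidase subunit 3",
             "cytochrome c oxidase subunit 3"),
    "ATP6": ("ATP6", "ATPase6", "ATPase 6", "ATP synthase F0 subunit 6",
             "ATPase subunit 6", "ATP synthase subunit 6"),
    "ATP8": ("ATP8", "ATPase8", "ATPase 8", "ATP synthase F0 subunit 8",
             "ATPase subunit 8", "ATP synthase subunit 8"),
    "CYTB": ("CYTB", "cyt b", "cytb", "cob", "cytochrome b"),
}


class GeneSynonymTable:
    """Compiled, case-insensitive, boundary-anchored pattern table.

    ``overrides`` merges user patterns on top of the built-in defaults
    (replacing that gene's pattern set).
    """

    def __init__(self, overrides: Mapping[str, Sequence[str]] | None = None):
        raw = dict(DEFAULT_SYNONYMS)
        if overrides:
            for gene, patterns in overrides.items():
                raw[gene] = tuple(patterns)
        self._patterns: dict[str, list[re.Pattern[str]]] = {}
        for gene, patterns in raw.items():
            if not patterns:
                raise ValueError(f"gene {gene!r} has no patterns")
            self._patterns[gene] = [
                re.compile(_B + re.escape(p) + _E, re.IGNORECASE) for p in patterns
            ]
        self._raw = raw

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self._patterns)

    def patterns_for(self, gene: str) -> list[re.Pattern[str]]:
        try:
            return self._patterns[gene]
        except KeyError:
            raise KeyError(f"unknown_gene: {gene}") from None

    def raw_patterns(self, gene: str) -> tuple[str, ...]:
        return tuple(self._raw[gene])


def validate_table(table: GeneSynonymTable) -> None:
    """Check that no built-in label is claimed by two distinct genes.

    Guards the confusable pairs (COX1/COX3, ND4/ND4L, ATP6/ATP8, 12S/16S):
    every raw pattern string must match its own gene and no other.
    """
    for gene in table.genes:
        for label in table.raw_patterns(gene):
            owners = [
                g for g in table.genes
                if any(p.search(label) for p in table.patterns_for(g))
            ]
            if owners != [gene]:
                raise ValueError(
                    f"pattern {label!r} of {gene} also matches {set(owners) - {gene}}"
                )


def match_gene(feature: GeneFeature, gene: str, table: GeneSynonymTable) -> bool:
    """True iff any of the feature's gene/product/note labels names ``gene``."""
    patterns = table.patterns_for(gene)
    return any(
        p.search(label) for label in feature.labels() if label for p in patterns
    )


def find_feature(record: MitoRecord, gene: str, table: GeneSynonymTable) -> GeneFeature | None:
    """First feature (in feature-table order) matching ``gene``, else None."""
    for feat in record.features:
        if feat.is_matchable() and match_gene(feat, gene, table):
            return feat
    return None


def extract_gene(record: MitoRecord, gene: str, table: GeneSynonymTable) -> str | None:
    """Excise the strand-corrected nucleotide sequence of ``gene``.

    Compound (join) locations concatenate their parts in listed order before
    reverse-complementing minus-strand features. Returns None when the record
    has no matching feature.
    """
    feat = find_feature(record, gene, table)
    if feat is None:
        return None
    n = len(record.sequence)
    parts = []
    for begin, end in feat.spans:
        if not (1 <= begin <= end <= n):
            raise ValueError(f"bad_span: {begin}..{end} outside 1..{n} in {record.accession}")
        parts.append(record.sequence[begin - 1 : end])
    seq = "".join(parts)
    if feat.strand is Strand.MINUS:
        seq = str(Seq(seq).reverse_complement())
    return seq


@dataclass
class ExtractionResult:
    """Per-gene excisions plus the concatenated and full-length sequences."""

    per_gene: dict[str, str] = field(default_factory=dict)
    concat: str = ""
    full_length: str = ""
    fallback_used: bool = False


def concat_genes(
    record: MitoRecord,
    targets: Sequence[str],
    table: GeneSynonymTable | None = None,
) -> ExtractionResult:
    """Extract ``targets`` and join them in canonical mitogenome gene order.

    Missing targets are skipped; if none can be extracted the full sequence
    stands in for the concatenation (``fallback_used``), so unannotated
    records are preserved rather than dropped.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    table = table or GeneSynonymTable()
    per_gene: dict[str, str] = {}
    for gene in targets:
        seq = extract_gene(record, gene, table)
        if seq is not None:
            per_gene[gene] = seq
    ordered = [g for g in CANONICAL_GENE_ORDER if g in per_gene]
    # targets outside the canonical order (user-defined genes) go last, in
    # the order requested
    ordered += [g for g in targets if g in per_gene and g not in CANONICAL_GENE_ORDER]
    if ordered:
        concat = "".join(per_gene[g] for g in ordered)
        fallback = False
    else:
        concat = record.sequence
        fallback = True
    return ExtractionResult(
        per_gene=per_gene,
        concat=concat,
        full_length=record.sequence,
        fallback_used=fallback,
    )
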