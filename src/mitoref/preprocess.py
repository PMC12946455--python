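"""Record-level filtering and species-level subsampling.

Filtering runs in a fixed stage order — ambiguous-qualifier screen, then the
completeness/gene-content mode screen, then RefSeq-preferring deduplication —
and every rejected record carries exactly one primary reason, so the output
partitions the input and the pipeline stays auditable.

Subsampling caps each species at ``max_sequences`` representatives (default
5), first removing byte-identical duplicates, then collapsing redundant
submissions by (submitter, geographic origin), and finally drawing at random
with a per-species seed so adding one species never perturbs another's draw.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from . import gene_extraction
from .records_io import MitoRecord

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "RejectReason",
    "COMPLETE_KEYWORDS",
    "is_complete_definition",
    "has_ambiguous_qualifier",
    "refseq_dedup",
    "filter_records",
    "subsample_species",
    "group_by_species",
]

COMPLETE_KEYWORDS = (
    "complete mitochondrial genome",
    "mitochondrion, complete genome",
    "whole mitochondrion",
    "complete mitogenome",
    "mitochondrial DNA, complete",
)


class RejectReason(str, Enum):
    NOT_COMPLETE = "not_complete"
    TOO_SHORT = "too_short"
    NO_TARGET_GENE = "no_target_gene"
    AMBIGUOUS_QUALIFIER = "ambiguous_qualifier"
    DUPLICATE_OF_REFSEQ = "duplicate_of_refseq"
    DUPLICATE_IDENTICAL = "duplicate_identical"
    SUBSAMPLE_OVERFLOW = "subsample_overflow"


@dataclass
class FilterConfig:
    """Filtering and subsampling parameters.

    ``mode`` selects between retaining only complete mitogenomes
    ("complete") or additionally keeping fragments that contain a target
    gene and meet the length threshold ("gene").
    """

    mode: str = "complete"  # "complete" | "gene"
    target_genes: tuple[str, ...] = ()
    min_gene_length: int = 400
    keep_cf: bool = False
    keep_sp: bool = False
    keep_ssp: bool = False
    keep_hybrid: bool = False
    max_sequences: int = 5
    rng_seed: int = 0
    extra_complete_keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("complete", "gene"):
            raise ValueError(f"bad_config: unknown mode {self.mode!r}")
        if self.min_gene_length <= 0:
            raise ValueError("bad_config: min_gene_length must be > 0")
        if self.max_sequences < 1:
            raise ValueError("bad_config: max_sequences must be >= 1")
        if self.mode == "gene" and not self.target_genes:
            raise ValueError("bad_config: mode=gene requires target_genes")


@dataclass
class FilterOutcome:
    """Kept/rejected partition of one filtering stage (or their composition)."""

    kept: list[MitoRecord] = field(default_factory=list)
    rejected: list[tuple[MitoRecord, RejectReason]] = field(default_factory=list)

    def extend_rejects(self, other: "FilterOutcome") -> None:
        self.rejected.extend(other.rejected)


def is_complete_definition(
    definition: str, extra_keywords: Sequence[str] = ()
) -> bool:
    """Case-insensitive substring match of completeness phrases in a
    DEFINITION line."""
    text = definition.lower()
    return any(k.lower() in text for k in (*COMPLETE_KEYWORDS, *extra_keywords))


_QUALIFIER_TOKENS = {
    "cf.": ("cf.", "keep_cf"),
    "sp.": ("sp.", "keep_sp"),
    "ssp.": ("ssp.", "keep_ssp"),
}


def has_ambiguous_qualifier(organism: str, cfg: FilterConfig | None = None) -> str | None:
    """First ambiguous qualifier ("cf.", "sp.", "ssp.", hybrid "x") in an
    organism string, or None.

    Matching is on standalone whitespace tokens, so "Pogona spilota" never
    trips the "sp." rule; "x" only counts between name parts (a hybrid
    cross). ``keep_*`` config switches suppress individual qualifiers.
    """
    cfg = cfg or FilterConfig()
    tokens = organism.split()
    for i, tok in enumerate(tokens):
        low = tok.lower()
        if low in _QUALIFIER_TOKENS:
            qual, keep_attr = _QUALIFIER_TOKENS[low]
            if not getattr(cfg, keep_attr):
                return qual
        elif low == "x" and 0 < i < len(tokens) - 1:
            if not cfg.keep_hybrid:
                return "hybrid-x"
    return None


def refseq_dedup(records: Sequence[MitoRecord]) -> FilterOutcome:
    """Drop non-RefSeq records whose sequence is byte-identical to a RefSeq
    record; RefSeq (NC_) members are always kept at this stage."""
    refseq_seqs = {r.sequence for r in records if r.is_refseq}
    outcome = FilterOutcome()
    for rec in records:
        if not rec.is_refseq and rec.sequence in refseq_seqs:
            outcome.rejected.append((rec, RejectReason.DUPLICATE_OF_REFSEQ))
        else:
            outcome.kept.append(rec)
    return outcome


def _passes_mode(
    rec: MitoRecord, cfg: FilterConfig, table: gene_extraction.GeneSynonymTable
) -> RejectReason | None:
    complete = is_complete_definition(rec.definition, cfg.extra_complete_keywords)
    if cfg.mode == "complete":
        return None if complete else RejectReason.NOT_COMPLETE
    if complete:
        return None
    if not rec.features:
        # unannotated record: retain to avoid unintentional data loss
        return None
    if not any(
        gene_extraction.find_feature(rec, g, table) is not None
        for g in cfg.target_genes
    ):
        return RejectReason.NO_TARGET_GENE
    if len(rec) < cfg.min_gene_length:
        return RejectReason.TOO_SHORT
    return None


def filter_records(
    records: Sequence[MitoRecord],
    cfg: FilterConfig,
    table: gene_extraction.GeneSynonymTable | None = None,
) -> FilterOutcome:
    """Apply the record-level screens in order: qualifier -> mode -> dedup."""
    table = table or gene_extraction.GeneSynonymTable()
    outcome = FilterOutcome()
    survivors: list[MitoRecord] = []
    for rec in records:
        if has_ambiguous_qualifier(rec.taxonomy.species_spaced, cfg) is not None:
            outcome.rejected.append((rec, RejectReason.AMBIGUOUS_QUALIFIER))
            continue
        reason = _passes_mode(rec, cfg, table)
        if reason is not None:
            outcome.rejected.append((rec, reason))
            continue
        survivors.append(rec)
    dedup = refseq_dedup(survivors)
    outcome.kept = dedup.kept
    outcome.rejected.extend(dedup.rejected)
    return outcome


def group_by_species(records: Iterable[MitoRecord]) -> dict[str, list[MitoRecord]]:
    groups: dict[str, list[MitoRecord]] = {}
    for rec in records:
        groups.setdefault(rec.taxonomy.species, []).append(rec)
    return groups


def _dedup_identical(records: Sequence[MitoRecord]) -> tuple[list[MitoRecord], list[MitoRecord]]:
    """Keep one record per distinct sequence: RefSeq preferred, then smallest
    accession."""
    by_seq: dict[str, list[MitoRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)
    kept, dropped = [], []
    for twins in by_seq.values():
        twins_sorted = sorted(twins, key=lambda r: (not r.is_refseq, r.accession))
        kept.append(twins_sorted[0])
        dropped.extend(twins_sorted[1:])
    kept.sort(key=lambda r: r.accession)
    return kept, dropped


def _collapse_by_origin(records: Sequence[MitoRecord]) -> tuple[list[MitoRecord], list[MitoRecord]]:
    """One representative per (submitter, geo_origin) key: RefSeq preferred,
    then longest, then smallest accession."""
    by_key: dict[tuple[str, str], list[MitoRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.submitter, rec.geo_origin), []).append(rec)
    kept, dropped = [], []
    for members in by_key.values():
        members_sorted = sorted(
            members, key=lambda r: (not r.is_refseq, -len(r), r.accession)
        )
        kept.append(members_sorted[0])
        dropped.extend(members_sorted[1:])
    kept.sort(key=lambda r: r.accession)
    return kept, dropped


def _target_gene_length(
    rec: MitoRecord, targets: Sequence[str], table: gene_extraction.GeneSynonymTable
) -> int:
    total = 0
    for gene in targets:
        seq = gene_extraction.extract_gene(rec, gene, table)
        if seq:
            total += len(seq)
    return total


def subsample_species(
    records: Sequence[MitoRecord],
    cfg: FilterConfig,
    table: gene_extraction.GeneSynonymTable | None = None,
) -> tuple[list[MitoRecord], list[tuple[MitoRecord, RejectReason]], int]:
    """Cap one species' records at ``cfg.max_sequences`` representatives.

    Returns ``(retained, overflow, pre_subsample_count)``. The pre-subsample
    count (records available before any within-species reduction) is what the
    per-species summary logs.
    """
    if not records:
        return [], [], 0
    species = records[0].taxonomy.species
    if any(r.taxonomy.species != species for r in records):
        raise ValueError("subsample_species requires a single-species group")
    pre_count = len(records)
    table = table or gene_extraction.GeneSynonymTable()

    overflow: list[tuple[MitoRecord, RejectReason]] = []
    pool, dup_dropped = _dedup_identical(records)
    overflow.extend((r, RejectReason.DUPLICATE_IDENTICAL) for r in dup_dropped)

    if len(pool) <= cfg.max_sequences:
        return pool, overflow, pre_count

    if cfg.mode == "gene":
        completes = [r for r in pool if is_complete_definition(r.definition, cfg.extra_complete_keywords)]
        complete_accs = {r.accession for r in completes}
        fragments = [r for r in pool if r.accession not in complete_accs]
        if len(completes) >= cfg.max_sequences:
            retained = _reduce_complete(completes, cfg, species, overflow)
            overflow.extend((r, RejectReason.SUBSAMPLE_OVERFLOW) for r in fragments)
            return retained, overflow, pre_count
        quota_left = cfg.max_sequences - len(completes)
        ranked = sorted(
            fragments,
            key=lambda r: (-_target_gene_length(r, cfg.target_genes, table), r.accession),
        )
        retained = completes + ranked[:quota_left]
        overflow.extend((r, RejectReason.SUBSAMPLE_OVERFLOW) for r in ranked[quota_left:])
        retained.sort(key=lambda r: r.accession)
        return retained, overflow, pre_count

    retained = _reduce_complete(pool, cfg, species, overflow)
    return retained, overflow, pre_count


def _reduce_complete(
    pool: Sequence[MitoRecord],
    cfg: FilterConfig,
    species: str,
    overflow: list[tuple[MitoRecord, RejectReason]],
) -> list[MitoRecord]:
    """Collapse by (submitter, origin), then draw the quota at random with a
    per-species seed."""
    collapsed, dropped = _collapse_by_origin(pool)
    overflow.extend((r, RejectReason.SUBSAMPLE_OVERFLOW) for r in dropped)
    if len(collapsed) <= cfg.max_sequences:
        return collapsed
    rng = random.Random(f"{cfg.rng_seed}:{species}")
    chosen = rng.sample(sorted(collapsed, key=lambda r: r.accession), cfg.max_sequences)
    chosen_set = {r.accession for r in chosen}
    overflow.extend(
        (r, RejectReason.SUBSAMPLE_OVERFLOW)
        for r in collapsed
        if r.accession not in chosen_set
    )
    return sorted(chosen, key=lambda r: r.accession)
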