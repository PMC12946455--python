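"""Manual-review ingestion, similar_to annotation and versioned release.

After the detector writes its flag report, a curator edits two text files:
entries left in ``clustering_anomalies.txt`` are confirmed errors (their
accessions are blacklisted), removed entries are false positives, and groups
of sequences that genuinely cannot be told apart on the tree move to
``similar.txt``. Members of a similar group stay in the database but their
FASTA headers gain a ``similar_to=`` tag listing one representative
accession per other species in the group (RefSeq preferred, else the
alphanumerically first), warning downstream assignment tools about residual
ambiguity.

The release itself is a versioned directory (``MitoDB_vYYMMDD``) holding the
curated GenBank and FASTA databases, clean/black lists, and summary tables
including the per-family error/similar/reliable breakdown.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .anomaly_detection import AnomalyFlag
from .records_io import (
    MitoRecord,
    SimilarGroup,
    accession_base,
    format_header,
    write_genbank,
)

__all__ = [
    "ReviewDecision",
    "ReleaseManifest",
    "apply_review",
    "select_representatives",
    "annotate_similar_to",
    "assemble_release",
    "family_quality_table",
    "removal_percentage",
    "version_string",
]


@dataclass
class ReviewDecision:
    """Outcome of manual review: confirmed flags and similar groups.

    ``auto_delete`` skips review and treats every detector flag as
    confirmed.
    """

    confirmed_flags: list[AnomalyFlag] = field(default_factory=list)
    similar_groups: list[SimilarGroup] = field(default_factory=list)
    auto_delete: bool = False

    def __post_init__(self) -> None:
        flagged = {accession_base(f.accession) for f in self.confirmed_flags}
        grouped = {
            accession_base(m) for g in self.similar_groups for m in g.members
        }
        overlap = flagged & grouped
        if overlap:
            raise ValueError(
                f"accessions both confirmed-erroneous and similar: {sorted(overlap)}"
            )


@dataclass
class ReleaseManifest:
    version: str
    cleanlist: list[str]
    blacklist: list[str]
    sequence_count: int
    species_count: int
    family_stats: pd.DataFrame


def version_string(date: _dt.date) -> str:
    return f"MitoDB_v{date:%y%m%d}"


def _index_records(records: Sequence[MitoRecord]) -> dict[str, MitoRecord]:
    return {accession_base(r.accession): r for r in records}


def apply_review(
    flags: Sequence[AnomalyFlag],
    review: ReviewDecision,
    records: Sequence[MitoRecord],
) -> tuple[list[str], list[MitoRecord], dict[str, SimilarGroup]]:
    """Split records into blacklist and clean set per the review decision.

    Returns ``(blacklist accessions, clean records, similar map)`` where the
    similar map keys retained accession bases to their group. Accessions are
    matched version-insensitively throughout.
    """
    index = _index_records(records)
    confirmed = list(flags) if review.auto_delete else list(review.confirmed_flags)
    blacklist: list[str] = []
    black_bases: set[str] = set()
    for fl in confirmed:
        base = accession_base(fl.accession)
        if base not in index:
            raise ValueError(f"unknown_accession: {fl.accession}")
        if base not in black_bases:
            black_bases.add(base)
            blacklist.append(index[base].accession)
    clean = [r for r in records if accession_base(r.accession) not in black_bases]
    similar_map: dict[str, SimilarGroup] = {}
    for group in review.similar_groups:
        for member in group.members:
            base = accession_base(member)
            if base in index and base not in black_bases:
                similar_map[base] = group
    return blacklist, clean, similar_map


def select_representatives(
    group: SimilarGroup, records: Sequence[MitoRecord] | Mapping[str, MitoRecord]
) -> list[str]:
    """One representative accession per species in the group: the NC_
    accession when one exists, else the alphanumerically smallest. The list
    is returned in alphanumeric accession order (the order the curated
    headers print)."""
    index = records if isinstance(records, Mapping) else _index_records(records)
    by_species: dict[str, list[str]] = {}
    for member in group.members:
        base = accession_base(member)
        rec = index.get(base)
        if rec is None:
            raise ValueError(f"unknown_accession: {member}")
        by_species.setdefault(rec.taxonomy.species, []).append(rec.accession)
    reps = []
    for accs in by_species.values():
        refseq = sorted(a for a in accs if a.startswith("NC_"))
        reps.append(refseq[0] if refseq else min(accs))
    return sorted(reps)


def annotate_similar_to(
    record: MitoRecord,
    similar_map: Mapping[str, SimilarGroup],
    records: Sequence[MitoRecord] | Mapping[str, MitoRecord],
) -> str:
    """FASTA header for a retained record, with its group's representatives.

    The record's own species' representative is omitted: the tag names only
    the *other* species the record cannot be distinguished from. Records in
    no group get a plain six-field header.
    """
    index = records if isinstance(records, Mapping) else _index_records(records)
    group = similar_map.get(accession_base(record.accession))
    if group is None:
        return format_header(record)
    reps = select_representatives(group, index)
    own_species = record.taxonomy.species
    reps = [
        a for a in reps
        if index[accession_base(a)].taxonomy.species != own_species
    ]
    return format_header(record, reps)


def assemble_release(
    clean_records: Sequence[MitoRecord],
    blacklist: Sequence[str],
    similar_map: Mapping[str, SimilarGroup],
    date: _dt.date,
    out_dir: str | Path,
) -> ReleaseManifest:
    """Write the versioned curated database directory and its manifest.

    Produces ``curated.gb`` (original annotations preserved), ``curated.fa``
    (annotated headers), ``cleanlist.txt``, ``blacklist.txt``,
    ``summary.txt`` and ``family_quality.tsv`` under
    ``<out_dir>/MitoDB_vYYMMDD``. Fails rather than overwriting an existing
    version directory.
    """
    version = version_string(date)
    release_dir = Path(out_dir) / version
    if release_dir.exists():
        raise FileExistsError(f"version_exists: {release_dir}")
    release_dir.mkdir(parents=True)

    index = _index_records(clean_records)
    ordered = sorted(clean_records, key=lambda r: r.accession)
    with open(release_dir / "curated.fa", "w") as fh:
        for rec in ordered:
            fh.write(f">{annotate_similar_to(rec, similar_map, index)}\n{rec.sequence}\n")
    with open(release_dir / "curated.gb", "w") as fh:
        write_genbank(ordered, fh)

    cleanlist = [r.accession for r in ordered]
    blacklist_sorted = sorted(blacklist)
    (release_dir / "cleanlist.txt").write_text("\n".join(cleanlist) + ("\n" if cleanlist else ""))
    (release_dir / "blacklist.txt").write_text(
        "\n".join(blacklist_sorted) + ("\n" if blacklist_sorted else "")
    )

    species = sorted({r.taxonomy.species for r in ordered})
    stats = family_quality_table(ordered, blacklist=[], similar_map=similar_map, top_n=10)
    stats.to_csv(release_dir / "family_quality.tsv", sep="\t", index=False)

    summary = [
        f"version\t{version}",
        f"sequences\t{len(cleanlist)}",
        f"species\t{len(species)}",
        f"blacklisted\t{len(blacklist_sorted)}",
        f"similar_annotated\t{sum(1 for r in ordered if accession_base(r.accession) in similar_map)}",
    ]
    (release_dir / "summary.txt").write_text("\n".join(summary) + "\n")

    return ReleaseManifest(
        version=version,
        cleanlist=cleanlist,
        blacklist=blacklist_sorted,
        sequence_count=len(cleanlist),
        species_count=len(species),
        family_stats=stats,
    )


def family_quality_table(
    records: Sequence[MitoRecord],
    blacklist: Sequence[str],
    similar_map: Mapping[str, SimilarGroup],
    top_n: int = 10,
) -> pd.DataFrame:
    """Per-family quality breakdown for the ``top_n`` largest families.

    For each family: ``error_seq`` (blacklisted), ``similar_seq`` (retained
    but similar-annotated), ``others_seq`` (the reliable remainder), the
    per-family proportions normalized to 1.0, and log10-scaled counts for
    plotting.
    """
    black_bases = {accession_base(a) for a in blacklist}
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        fam = rec.taxonomy.family
        if not fam:
            raise ValueError(f"record {rec.accession} has no family label")
        row = rows.setdefault(fam, {"error_seq": 0, "similar_seq": 0, "others_seq": 0})
        base = accession_base(rec.accession)
        if base in black_bases:
            row["error_seq"] += 1
        elif base in similar_map:
            row["similar_seq"] += 1
        else:
            row["others_seq"] += 1
    df = pd.DataFrame(
        [
            {"family": fam, **counts, "total": sum(counts.values())}
            for fam, counts in rows.items()
        ]
    )
    if df.empty:
        return df
    df = df.sort_values(["total", "family"], ascending=[False, True]).head(top_n)
    for col in ("error_seq", "similar_seq", "others_seq"):
        df[f"{col}_prop"] = df[col] / df["total"]
        df[f"{col}_log"] = df[col].map(lambda c: math.log10(c + 1))
    return df.reset_index(drop=True)


def removal_percentage(removed: int, total: int) -> float:
    """Share of removed records as a percentage, rounded to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * removed / total, 2)
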