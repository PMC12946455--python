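"""Record formats and codecs for the curation pipeline.

This module owns every textual format the pipeline reads or writes:

* GenBank flat files (parsed with Biopython, one entry at a time so a single
  malformed entry is reported rather than aborting the stream);
* the pipe-delimited FASTA header dialect
  ``Genus_species|Accession|RecordType|o__Order|f__Family|g__Genus`` with an
  optional trailing ``similar_to=`` segment;
* the curation text files ``similar.txt`` and ``clustering_anomalies.txt``;
* NCBI Entrez query strings for species-name retrieval.

Network retrieval is hidden behind :class:`FetchClient`; tests and offline
runs use :class:`FixtureFetchClient`, which serves canned GenBank text.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

__all__ = [
    "Taxonomy",
    "GeneFeature",
    "Strand",
    "RecordType",
    "MitoRecord",
    "SimilarGroup",
    "ParseReject",
    "HeaderError",
    "CurationFileError",
    "parse_genbank",
    "write_genbank",
    "build_entrez_query",
    "parse_header",
    "format_header",
    "read_similar_file",
    "write_similar_file",
    "read_anomaly_file",
    "write_anomaly_file",
    "accession_base",
    "FetchClient",
    "FixtureFetchClient",
    "read_id_list",
]


class RecordType(str, Enum):
    COMPLETE = "Complete"
    PARTIAL = "Partial"
    CONCAT = "Concat"
    USER_SEQUENCE = "User_sequence"


class Strand(str, Enum):
    PLUS = "plus"
    MINUS = "minus"


@dataclass(frozen=True)
class Taxonomy:
    """Order/family/genus/species labels attached to one record.

    ``species`` is the binomial with an underscore (``Genus_species``) as used
    in headers; GenBank organism lines use a space instead.
    """

    order: str
    family: str
    genus: str
    species: str

    @property
    def species_spaced(self) -> str:
        return self.species.replace("_", " ")

    def is_complete(self) -> bool:
        return bool(self.order and self.family and self.genus and self.species)


@dataclass(frozen=True)
class GeneFeature:
    """One CDS/rRNA feature with its raw qualifier labels and location.

    ``spans`` are 1-based inclusive (begin, end) pairs as printed in GenBank
    flat files; a compound (``join``) location contributes several spans in
    listed order. ``strand`` applies to the whole location.
    """

    gene_label: str = ""
    product_label: str = ""
    note_label: str = ""
    spans: tuple[tuple[int, int], ...] = ()
    strand: Strand = Strand.PLUS
    feature_kind: str = "other"  # "CDS", "rRNA" or "other"

    def labels(self) -> tuple[str, str, str]:
        return (self.gene_label, self.product_label, self.note_label)

    def is_matchable(self) -> bool:
        return any(self.labels())


@dataclass
class MitoRecord:
    """One GenBank-derived (or user-supplied) sequence with its metadata."""

    accession: str
    taxonomy: Taxonomy
    definition: str
    record_type: RecordType
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    submitter: str = ""
    geo_origin: str = ""
    raw_text: str = ""  # original GenBank entry text when parsed from a flat file

    @property
    def is_refseq(self) -> bool:
        return self.accession.startswith("NC_")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarGroup:
    """Accessions declared mutually indistinguishable on the tree."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise CurationFileError("group_too_small: a similar group needs >= 2 members")


@dataclass(frozen=True)
class ParseReject:
    """One GenBank entry that could not be parsed, with the reason."""

    entry_excerpt: str
    reason: str


class HeaderError(ValueError):
    """Raised for malformed pipe-delimited headers or incomplete taxonomy."""


class CurationFileError(ValueError):
    """Raised for malformed similar.txt / clustering_anomalies.txt content."""


def accession_base(accession: str) -> str:
    """Accession without its version suffix (``NC_026237.1`` -> ``NC_026237``)."""
    return accession.split(".", 1)[0]


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

# Rank-suffix heuristics for unranked GenBank lineages; fish-centric defaults,
# overridable per call with an explicit lookup table.
_ORDER_SUFFIXES = ("formes", "iformes")
_FAMILY_SUFFIX = "idae"


def _resolve_ranks(
    lineage: Sequence[str],
    organism: str,
    order_lookup: Mapping[str, str] | None = None,
    family_lookup: Mapping[str, str] | None = None,
) -> Taxonomy:
    order = family = ""
    for token in lineage:
        tok = token.strip()
        if order_lookup and tok in order_lookup:
            order = order_lookup[tok]
        elif not order and any(tok.endswith(s) for s in _ORDER_SUFFIXES):
            order = tok
        if family_lookup and tok in family_lookup:
            family = family_lookup[tok]
        elif not family and tok.endswith(_FAMILY_SUFFIX):
            family = tok
    parts = organism.split()
    genus = parts[0] if parts else ""
    species = "_".join(parts[:2]) if len(parts) >= 2 else genus
    return Taxonomy(order=order, family=family, genus=genus, species=species)


def _split_entries(text: str) -> list[str]:
    """Split a GenBank flat-file stream into individual entry texts."""
    entries: list[str] = []
    current: list[str] = []
    for line in text.splitlines(keepends=True):
        current.append(line)
        if line.rstrip() == "//":
            entries.append("".join(current))
            current = []
    leftover = "".join(current).strip()
    if leftover:
        entries.append("".join(current))
    return entries


def _features_from_biopython(bio_record) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for f in bio_record.features:
        if f.type not in ("CDS", "rRNA"):
            continue
        spans = tuple(
            (int(part.start) + 1, int(part.end)) for part in f.location.parts
        )
        strand = Strand.MINUS if f.location.strand == -1 else Strand.PLUS
        feats.append(
            GeneFeature(
                gene_label=f.qualifiers.get("gene", [""])[0],
                product_label=f.qualifiers.get("product", [""])[0],
                note_label=f.qualifiers.get("note", [""])[0],
                spans=spans,
                strand=strand,
                feature_kind=f.type,
            )
        )
    return feats


def _classify_definition(definition: str) -> RecordType:
    # Local import to avoid a cycle: preprocess owns the completeness keywords.
    from .preprocess import is_complete_definition

    return RecordType.COMPLETE if is_complete_definition(definition) else RecordType.PARTIAL


def parse_genbank(
    stream: TextIO | str,
    order_lookup: Mapping[str, str] | None = None,
    family_lookup: Mapping[str, str] | None = None,
) -> tuple[list[MitoRecord], list[ParseReject]]:
    """Parse GenBank flat-file text into records plus a rejects report.

    Each entry is parsed independently so one malformed entry yields a
    :class:`ParseReject` (reason ``"parse_error"``) without losing the rest.
    Taxonomic ranks are resolved from the ORGANISM lineage by suffix
    heuristics (``-formes`` -> order, ``-idae`` -> family), optionally
    overridden by explicit lookup tables keyed on lineage tokens.
    """
    text = stream if isinstance(stream, str) else stream.read()
    records: list[MitoRecord] = []
    rejects: list[ParseReject] = []
    for entry in _split_entries(text):
        try:
            bio = SeqIO.read(io.StringIO(entry), "genbank")
            organism = bio.annotations.get("organism", "")
            lineage = bio.annotations.get("taxonomy", [])
            taxonomy = _resolve_ranks(lineage, organism, order_lookup, family_lookup)
            definition = bio.description
            submitter = ""
            refs = bio.annotations.get("references", [])
            if refs:
                submitter = " ".join((refs[0].authors or refs[0].consrtm or "").split()).lower()
            geo = ""
            for f in bio.features:
                if f.type == "source":
                    for key in ("geo_loc_name", "country"):
                        if key in f.qualifiers:
                            geo = f.qualifiers[key][0]
                            break
                    break
            seq = str(bio.seq).upper()
            if not seq:
                raise ValueError("empty sequence")
            records.append(
                MitoRecord(
                    accession=bio.id,
                    taxonomy=taxonomy,
                    definition=definition,
                    record_type=_classify_definition(definition),
                    sequence=seq,
                    features=_features_from_biopython(bio),
                    submitter=submitter,
                    geo_origin=geo,
                    raw_text=entry,
                )
            )
        except Exception:
            rejects.append(ParseReject(entry_excerpt=entry[:120], reason="parse_error"))
    return records, rejects


def write_genbank(records: Iterable[MitoRecord], handle: TextIO) -> int:
    """Write records back out as GenBank text, preserving original entries.

    Records parsed from a flat file carry their source text verbatim
    (annotations preserved); synthetic records without ``raw_text`` are
    emitted as minimal valid entries.
    """
    n = 0
    for rec in records:
        if rec.raw_text:
            handle.write(rec.raw_text)
            if not rec.raw_text.endswith("\n"):
                handle.write("\n")
        else:
            handle.write(_minimal_genbank_entry(rec))
        n += 1
    return n


def _minimal_genbank_entry(rec: MitoRecord) -> str:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord

    bio = BioSeqRecord(
        Seq(rec.sequence),
        id=rec.accession,
        name=accession_base(rec.accession)[:16],
        description=rec.definition,
        annotations={
            "molecule_type": "DNA",
            "organism": rec.taxonomy.species_spaced,
            "taxonomy": [t for t in (rec.taxonomy.order, rec.taxonomy.family) if t],
        },
    )
    out = io.StringIO()
    SeqIO.write(bio, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Entrez queries
# ---------------------------------------------------------------------------

_ENTREZ_SUFFIX = " AND mitochondrion[filter] AND complete genome[title]"


def build_entrez_query(species_name: str) -> str:
    """Standardized Entrez query for one species' complete mitogenome records."""
    name = species_name.replace("_", " ").strip()
    if not name:
        raise ValueError("empty_species")
    return f'"{name}"{_ENTREZ_SUFFIX}'


# ---------------------------------------------------------------------------
# Pipe-delimited FASTA header dialect
# ---------------------------------------------------------------------------

_SIMILAR_PREFIX = "similar_to= "


def parse_header(header: str) -> tuple[Taxonomy, str, RecordType, list[str]]:
    """Parse ``Genus_species|Acc|Type|o__O|f__F|g__G[|similar_to= a, b|]``.

    A trailing pipe on a plain six-field header is tolerated on input (it is
    never emitted); the ``similar_to=`` segment always carries one.
    """
    parts = header.strip().split("|")
    similar: list[str] = []
    if len(parts) == 8 and parts[6].startswith("similar_to=") and parts[7] == "":
        similar = [a.strip() for a in parts[6].split("=", 1)[1].split(",") if a.strip()]
        parts = parts[:6]
    elif len(parts) == 7 and parts[6] == "":
        parts = parts[:6]
    if len(parts) != 6:
        raise HeaderError(f"bad_header: expected 6 fields, got {len(parts)}: {header!r}")
    species, accession, rtype, o_seg, f_seg, g_seg = parts
    if not (o_seg.startswith("o__") and f_seg.startswith("f__") and g_seg.startswith("g__")):
        raise HeaderError(f"bad_header: missing rank prefixes in {header!r}")
    try:
        record_type = RecordType(rtype)
    except ValueError as exc:
        raise HeaderError(f"bad_header: unknown record type {rtype!r}") from exc
    taxonomy = Taxonomy(
        order=o_seg[3:], family=f_seg[3:], genus=g_seg[3:], species=species
    )
    return taxonomy, accession, record_type, similar


def format_header(record: MitoRecord, similar_to: Sequence[str] = ()) -> str:
    """Emit the header dialect; ``similar_to`` accessions get their own segment.

    The similar segment reproduces the reference layout exactly: a single
    space after ``similar_to=``, accessions joined by ``", "``, and a
    terminal pipe.
    """
    tax = record.taxonomy
    if not tax.is_complete():
        raise HeaderError(f"bad_taxonomy: incomplete ranks for {record.accession}")
    head = (
        f"{tax.species}|{record.accession}|{record.record_type.value}"
        f"|o__{tax.order}|f__{tax.family}|g__{tax.genus}"
    )
    if similar_to:
        head += f"|{_SIMILAR_PREFIX}" + ", ".join(similar_to) + "|"
    return head


# ---------------------------------------------------------------------------
# Curation text files
# ---------------------------------------------------------------------------

def _content_lines(stream: TextIO | str) -> list[str]:
    text = stream if isinstance(stream, str) else stream.read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_similar_file(stream: TextIO | str) -> list[SimilarGroup]:
    """Read similar.txt: one comma-separated accession group per line."""
    groups: list[SimilarGroup] = []
    seen: set[str] = set()
    for line in _content_lines(stream):
        members = tuple(a.strip() for a in line.split(",") if a.strip())
        if len(members) < 2:
            raise CurationFileError(f"group_too_small: {line!r}")
        for m in members:
            base = accession_base(m)
            if base in seen:
                raise CurationFileError(f"duplicate accession across groups: {m}")
            seen.add(base)
        groups.append(SimilarGroup(members=members))
    return groups


def write_similar_file(groups: Iterable[SimilarGroup], handle: TextIO) -> None:
    for g in groups:
        handle.write(", ".join(g.members) + "\n")


_ANOMALY_COLUMNS = ("group_id", "color", "anomaly_type", "species", "accession", "tree_file", "note")
_VALID_COLORS = ("green", "blue", "red")


def read_anomaly_file(stream: TextIO | str) -> list["AnomalyFlag"]:
    """Read clustering_anomalies.txt (TSV: group_id, color, anomaly_type,
    species, accession, tree_file, note)."""
    from .anomaly_detection import COLOR_TO_TYPE, AnomalyFlag

    text = stream if isinstance(stream, str) else stream.read()
    flags: list[AnomalyFlag] = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\r\n").split("\t")
        if len(parts) != len(_ANOMALY_COLUMNS):
            raise CurationFileError(f"bad_flag: expected {len(_ANOMALY_COLUMNS)} columns: {line!r}")
        group_id, color, anomaly_type, species, accession, tree_file, note = parts
        if color not in _VALID_COLORS:
            raise CurationFileError(f"bad_flag: unknown color {color!r}")
        if COLOR_TO_TYPE[color] != anomaly_type:
            raise CurationFileError(
                f"bad_flag: color {color!r} does not match type {anomaly_type!r}"
            )
        flags.append(
            AnomalyFlag(
                accession=accession,
                species=species,
                anomaly_type=anomaly_type,
                group_id=group_id,
                tree_file=tree_file,
                note=note,
            )
        )
    return flags


def write_anomaly_file(flags: Iterable["AnomalyFlag"], handle: TextIO) -> None:
    handle.write("#" + "\t".join(_ANOMALY_COLUMNS) + "\n")
    for fl in flags:
        handle.write(
            "\t".join(
                (fl.group_id, fl.color, fl.anomaly_type, fl.species, fl.accession, fl.tree_file, fl.note)
            )
            + "\n"
        )


def read_id_list(stream: TextIO | str, n_outgroups: int = 0) -> tuple[list[str], list[str]]:
    """Read a plain-text species/accession list, one per line.

    The first ``n_outgroups`` lines (conventionally one or two) are outgroup
    identifiers. Returns ``(outgroups, remaining_ids)``.
    """
    lines = _content_lines(stream)
    return lines[:n_outgroups], lines[n_outgroups:]


# ---------------------------------------------------------------------------
# Fetch adapter
# ---------------------------------------------------------------------------

class FetchClient:
    """Interface for GenBank retrieval; implementations return flat-file text."""

    def fetch_by_query(self, query: str) -> str:
        raise NotImplementedError

    def fetch_by_accessions(self, accessions: Sequence[str]) -> str:
        raise NotImplementedError


class FixtureFetchClient(FetchClient):
    """Offline client serving canned GenBank text, for tests and demos.

    ``store`` maps version-less accessions to entry text; queries match the
    quoted species name at the start of the query string.
    """

    def __init__(self, store: Mapping[str, str], by_species: Mapping[str, str] | None = None):
        self._store = dict(store)
        self._by_species = dict(by_species or {})

    def fetch_by_query(self, query: str) -> str:
        m = re.match(r'"([^"]+)"', query)
        if not m:
            return ""
        return self._by_species.get(m.group(1), "")

    def fetch_by_accessions(self, accessions: Sequence[str]) -> str:
        return "".join(
            self._store.get(accession_base(a), "") for a in accessions
        )
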