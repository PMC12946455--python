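import random

import pytest
from hypothesis import settings

from mitoref.records_io import GeneFeature, MitoRecord, RecordType, Strand, Taxonomy

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(
    accession: str,
    species: str = "Testus_alphai",
    order: str = "Testiformes",
    family: str = "Testidae",
    definition: str | None = None,
    sequence: str | None = None,
    features: tuple[GeneFeature, ...] = (),
    submitter: str = "doe,j.",
    geo: str = "Atlantis",
    record_type: RecordType = RecordType.COMPLETE,
) -> MitoRecord:
    genus = species.split("_")[0]
    if definition is None:
        definition = f"{species.replace('_', ' ')} mitochondrion, complete genome"
    if sequence is None:
        rng = random.Random(accession)
        sequence = "".join(rng.choice("ACGT") for _ in range(600))
    return MitoRecord(
        accession=accession,
        taxonomy=Taxonomy(order=order, family=family, genus=genus, species=species),
        definition=definition,
        record_type=record_type,
        sequence=sequence,
        features=list(features),
        submitter=submitter,
        geo_origin=geo,
    )


def feature_12s(begin: int = 70, end: int = 1020) -> GeneFeature:
    return GeneFeature(
        gene_label="12S",
        product_label="12S ribosomal RNA",
        spans=((begin, end),),
        strand=Strand.PLUS,
        feature_kind="rRNA",
    )


@pytest.fixture
def rec_factory():
    return make_record
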