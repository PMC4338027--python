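"""Shared fixtures: one deterministic synthetic universe per session."""

import pytest

from adviser.annotation_engine import AnnotationSourceSet
from adviser.fixtures import (FixtureSpec, generate_catalogs,
                              generate_reference, generate_trio,
                              generate_variant_file)
from adviser.predictors import ConservationRulePredictor

SEED = 1


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def reference(spec):
    return generate_reference(spec)


@pytest.fixture(scope="session")
def genome(reference):
    return reference.genome


@pytest.fixture(scope="session")
def ref_genome(reference):
    """Mapping-style reference as the validator consumes it."""
    return {reference.chrom: reference.genome}


@pytest.fixture(scope="session")
def trio(spec, reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("trio") / "trio.vcf"
    manifest = generate_trio(spec, reference, path)
    return path, manifest


@pytest.fixture(scope="session")
def catalogs(spec, reference, trio):
    _, manifest = trio
    positions = [k[1] for ks in manifest.values() for k in ks]
    return generate_catalogs(spec, reference, positions)


@pytest.fixture(scope="session")
def sources(reference, catalogs):
    return AnnotationSourceSet(
        transcripts=reference.transcripts,
        af_tables=catalogs.af_tables,
        pathogenicity=catalogs.pathogenicity,
        risk=catalogs.risk,
        gene_catalog=catalogs.gene_catalog,
        regions={"tfbs": reference.tfbs},
        pssms=reference.pssms,
        splice_pwms=reference.splice_pwms,
        missense_predictor=ConservationRulePredictor(),
    )


@pytest.fixture(scope="session")
def variant_file(spec, reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("variants") / "variants.tsv"
    labels = generate_variant_file(spec, reference, path)
    return path, labels
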