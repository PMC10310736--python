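import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

from cnvscore.acmg_engine import EngineOptions, Registries
from cnvscore.annotation_db import (
    BenignRegistry,
    DosageRegistry,
    FunctionalElementRegistry,
    GeneRegistry,
    PopulationRegistry,
    PredictorRegistry,
    build_benign_db,
)
from cnvscore.fixtures import FixtureSpec, generate_annotation_bundle, generate_cnv_sets
from cnvscore.intervals import CNVCall, CNVType, GenomicInterval
from cnvscore.scoring import load_scoring_table


@pytest.fixture(scope="session")
def table():
    return load_scoring_table()


@pytest.fixture(scope="session")
def default_options():
    return EngineOptions()


def make_registries(bundle, options: EngineOptions) -> Registries:
    return Registries(
        genes=GeneRegistry(bundle.genes),
        functional=FunctionalElementRegistry(bundle.functional),
        dosage=DosageRegistry(bundle.dosage),
        benign=build_benign_db(
            bundle.benign,
            maf_threshold=options.maf_threshold,
            type_filter=options.benign_type_filter,
            flavor=options.benign_flavor,
            source=options.benign_source,
        ),
        population=PopulationRegistry(bundle.population),
        predictors=PredictorRegistry(bundle.predictors),
    )


@pytest.fixture(scope="session")
def bundle11():
    """The seeded bundle used for engine-vs-oracle equality tests."""
    return generate_annotation_bundle(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def registries11(bundle11, default_options):
    return make_registries(bundle11, default_options)


@pytest.fixture(scope="session")
def random_cnvs11(bundle11):
    """200 unconstrained random CNVs across the seed-11 toy genome."""
    spec = bundle11.spec
    rng = np.random.default_rng(11)
    cnvs = []
    for i in range(200):
        chrom = spec.chroms()[int(rng.integers(0, spec.n_chromosomes))]
        length = int(rng.integers(5_000, 2_000_000))
        start = int(rng.integers(0, spec.chrom_length - length))
        cnv_type = CNVType.LOSS if rng.integers(0, 2) == 0 else CNVType.GAIN
        cnvs.append(
            CNVCall(GenomicInterval(chrom, start, start + length), cnv_type, id=f"rnd-{i}")
        )
    return cnvs


@pytest.fixture(scope="session")
def planted_sets(bundle11):
    return generate_cnv_sets(bundle11.spec, bundle11)
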