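"""Shared fixtures: a small ingested cohort store and a planted trio store.

Both are built once per session from the synthetic-data generator; all
fixture data is created at test time, nothing is read from the repository.
"""

from __future__ import annotations

import pytest
from pyfaidx import Fasta

from atavlite.annotation import AnnotationTable, GeneModel, KnownVar
from atavlite.ped import read_ped
from atavlite.simulate import CohortSpec, generate_cohort, generate_trio
from atavlite.store import VariantStore

COHORT_SEED = 20240901
TRIO_SEED = 424242

TRIO_PLANTED = [
    {"category": "de_novo", "gene": "GENE0001"},
    {"category": "newly_comphet", "gene": "GENE0002"},
    {"category": "newly_hom", "gene": "GENE0003"},
    {"category": "mosaic_transmission", "gene": "GENE0004"},
]


@pytest.fixture(scope="session")
def cohort_paths(tmp_path_factory):
    spec = CohortSpec(
        n_cases=25,
        n_controls=25,
        n_genes=10,
        variants_per_gene=3,
        baseline_carrier_rate=0.10,
        enriched_genes={"GENE0001": 5.0, "GENE0002": 5.0},
        seed=COHORT_SEED,
    )
    return generate_cohort(spec, tmp_path_factory.mktemp("cohort"))


def build_store(paths):
    store = VariantStore(gene_model=GeneModel.load(paths.gene_model))
    reference = Fasta(paths.reference_fasta)
    for sid in sorted(paths.vcfs):
        store.ingest_sample_vcf(paths.vcfs[sid], reference, sample_id=sid)
        store.coverage.load_depth_file(paths.depths[sid], sid, "bed")
    store.attach_annotation(AnnotationTable.load(paths.external_af_tsv, "variant"))
    store.attach_annotation(AnnotationTable.load(paths.intolerance_tsv, "gene"))
    return store


@pytest.fixture(scope="session")
def cohort_store(cohort_paths):
    return build_store(cohort_paths)


@pytest.fixture(scope="session")
def cohort_samples(cohort_paths):
    return read_ped(cohort_paths.ped)


@pytest.fixture(scope="session")
def trio_paths(tmp_path_factory):
    return generate_trio(TRIO_PLANTED, tmp_path_factory.mktemp("trio"), seed=TRIO_SEED)


@pytest.fixture(scope="session")
def trio_store(trio_paths):
    return build_store(trio_paths)


@pytest.fixture(scope="session")
def trio_samples(trio_paths):
    return read_ped(trio_paths.ped)
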