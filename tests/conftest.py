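"""Shared fixtures: one session-scoped synthetic cohort bundle.

The bundle is the package's own fixture generator output (2 groups x 3
replicates x 2000 variants with planted truth); building it once keeps the
suite fast while letting every module test against the same manifest.
"""

import pytest

from vcfcohort.annotate import annotate_cohort, load_gene_models
from vcfcohort.simulate import simulate_all
from vcfcohort.vcf_io import assemble_cohort


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_bundle")
    genome, models, cohort_fx = simulate_all(outdir, seed=7)
    return {"genome": genome, "models": models, "cohort_fx": cohort_fx}


@pytest.fixture(scope="session")
def cohort(bundle):
    return assemble_cohort(bundle["cohort_fx"].vcf_manifest)


@pytest.fixture(scope="session")
def manifest(bundle):
    return bundle["cohort_fx"].manifest


@pytest.fixture(scope="session")
def gene_index(bundle):
    return load_gene_models(bundle["models"].gtf_path)


@pytest.fixture(scope="session")
def annotations(cohort, gene_index):
    return annotate_cohort(cohort, gene_index)
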