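import pytest
from hypothesis import settings

import hbbkit as hk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return hk.load_catalog()


@pytest.fixture(scope="session")
def reference_cohort(catalog):
    """The deterministic study-structured cohort as SampleRecords."""
    geno, pheno = hk.paper_cohort_fixture(catalog)
    return hk.to_sample_records(geno, pheno, catalog)


@pytest.fixture(scope="session")
def reference_calls(reference_cohort, catalog):
    return [hk.call_hb_genotype(s, catalog) for s in reference_cohort]


@pytest.fixture(scope="session")
def reference_phasing(reference_cohort, catalog):
    """(FrequencyEstimate, diplotype calls, excluded) for the reference cohort."""
    return hk.em_phase(reference_cohort, catalog)
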