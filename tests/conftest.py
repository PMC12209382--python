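import pytest

import osteomark as om


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameters (published point estimates plus synthetic
    stand-ins for the unpublished tables)."""
    return om.default_parameters()


@pytest.fixture(scope="session")
def no_fracture_params(params):
    """Base case with all fracture incidence set to zero."""
    p = params.copy()
    for site in p.incidence.rates:
        p.incidence.rates[site] = {a: 0.0 for a in p.incidence.rates[site]}
    return p


@pytest.fixture(scope="session")
def immortal_params(params):
    """Base case with all-cause mortality set to zero."""
    p = params.copy()
    p.mortality.q_female = {a: 0.0 for a in p.mortality.q_female}
    return p
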