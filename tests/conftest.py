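import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gpdikit as g

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def drug_a():
    return g.SingleDrugPD("A", emax=1.0, ec50=1.0, hill=2.0)


@pytest.fixture
def drug_b():
    return g.SingleDrugPD("B", emax=1.0, ec50=2.0, hill=1.5)


@pytest.fixture
def null_model(drug_a, drug_b):
    return g.InteractionModel(drugs=(drug_a, drug_b), terms=(), criterion="bliss")


@pytest.fixture
def asymmetric_model(drug_a, drug_b):
    """B antagonises A (shift at B's EC50 = 3*2/(2+2) = 1.5); A leaves B alone."""
    return g.InteractionModel(
        drugs=(drug_a, drug_b),
        terms=(
            g.GPDITerm("B", "A", int_value=3.0, ec50_int=2.0),
            g.GPDITerm("A", "B", int_value=0.0, ec50_int=1.0),
        ),
        criterion="bliss",
    )


@pytest.fixture
def design():
    return g.CheckerboardDesign.log2()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
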