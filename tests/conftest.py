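import pytest

from aquarisk import synthetic_data
from aquarisk.data_model import WaterSample, load_config


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def cohort():
    """Default 69-sample synthetic cohort (seed 1), shared across tests."""
    return synthetic_data.generate_cohort(synthetic_data.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def sample_table(cohort):
    return cohort.table


def make_sample(sample_id="S1", ph=7.2, ec=800.0, tds=500.0, th=300.0,
                ions=None, ptes=None, **kwargs):
    base_ions = {"Ca": 60.0, "Mg": 20.0, "Na": 50.0, "K": 5.0,
                 "Cl": 80.0, "SO4": 60.0, "HCO3": 200.0, "CO3": 0.0,
                 "NO3": 10.0}
    base_ptes = {"Fe": 0.1, "Mn": 0.05, "Cu": 0.01, "Zn": 0.02}
    if ions:
        base_ions.update(ions)
    if ptes:
        base_ptes.update(ptes)
    return WaterSample(sample_id=sample_id, ph=ph, ec=ec, tds=tds, th=th,
                       ions=base_ions, ptes=base_ptes, **kwargs)


@pytest.fixture
def sample():
    return make_sample()
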