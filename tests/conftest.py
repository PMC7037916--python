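import numpy as np
import pytest

from duotox import composite as ci
from duotox import dataset as ds
from duotox import synthetic as syn
from duotox.prepare import PrepConfig, prepare_from_smiles

CIP_SMILES = "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"
MOX_SMILES = "COc1c(N2C[C@@H]3CCCN[C@@H]3C2)c(F)cc2c(=O)c(C(=O)O)cn(C3CC3)c12"


@pytest.fixture(scope="session")
def table1():
    return ds.load_table1_fixture()


@pytest.fixture(scope="session")
def shared_config(table1):
    return ci.calibrate_standard(table1.records, ci.MODE_SHARED)


@pytest.fixture(scope="session")
def prep_config():
    return PrepConfig()


@pytest.fixture(scope="session")
def cip(prep_config):
    return prepare_from_smiles(CIP_SMILES, "CIP", prep_config)


@pytest.fixture(scope="session")
def mox(prep_config):
    return prepare_from_smiles(MOX_SMILES, "MOX", prep_config)


@pytest.fixture(scope="session")
def synth_spec():
    return syn.SyntheticSpec(n_molecules=40, seed=7)


@pytest.fixture(scope="session")
def synth_molecules(synth_spec):
    return syn.generate_molecule_set(synth_spec)


@pytest.fixture(scope="session")
def recovery_activities(synth_molecules, synth_spec):
    """Noiseless planted activities in the identifiable (full-rank) regime."""
    return syn.plant_activities(synth_molecules, synth_spec, syn.recovery_field_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
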