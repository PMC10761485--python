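from importlib import resources

import pytest

import mmdt
from mmdt import synthetic

#: seed of the shared synthetic study database
WORLD_SEED = 2025


@pytest.fixture(scope="session")
def ref_kb():
    return mmdt.load_reference_kb()


@pytest.fixture(scope="session")
def regimens():
    return mmdt.load_regimens()


@pytest.fixture(scope="session")
def profiles():
    return mmdt.default_profiles()


@pytest.fixture(scope="session")
def table2_path(tmp_path_factory):
    data = resources.files("mmdt.data").joinpath("table2_patient.json").read_text()
    path = tmp_path_factory.mktemp("fixtures") / "table2_patient.json"
    path.write_text(data)
    return path


@pytest.fixture(scope="session")
def table2_profile(ref_kb, table2_path):
    return mmdt.read_patient(table2_path, ref_kb)


@pytest.fixture(scope="session")
def synthetic_world(regimens):
    """One shared generated + curated study database with its ground truth."""
    config = synthetic.GeneratorConfig(n_cases=5000, seed=WORLD_SEED)
    db, truth = synthetic.generate(config)
    curated, log = synthetic.curate(db, regimens)
    return {"config": config, "db": db, "curated": curated, "truth": truth, "log": log}
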