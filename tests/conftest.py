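import shutil
from importlib import resources
from pathlib import Path

import pytest

from khscm.facility import load_facility_ledger
from khscm.reporting import load_published_matrix
from khscm.synthetic import default_config, generate_sample


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory) -> Path:
    """Bundled 3-centre toy ledger, copied to a writable location."""
    dest = tmp_path_factory.mktemp("toy_fixture") / "toy"
    with resources.as_file(resources.files("khscm.data").joinpath("toy")) as src:
        shutil.copytree(src, dest)
    return dest


@pytest.fixture(scope="session")
def toy_record(toy_dir):
    return load_facility_ledger(toy_dir)


@pytest.fixture(scope="session")
def published():
    """(matrix, grouping) of the bundled national summary."""
    return load_published_matrix()


@pytest.fixture(scope="session")
def sample42():
    """Default-plan synthetic sample, seed 42."""
    return generate_sample(default_config(seed=42))


@pytest.fixture(scope="session")
def sample_dir42(tmp_path_factory, sample42):
    from khscm.synthetic import write_sample

    out = tmp_path_factory.mktemp("sample42") / "sample"
    write_sample(sample42, out)
    return out
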