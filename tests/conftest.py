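import pytest

from phagepatch.fixtures import coexistence_params
from phagepatch.params import dump_params


@pytest.fixture(scope="session")
def desk_params():
    """Packaged reduced-scale parameter set with stable coexistence."""
    return coexistence_params()


@pytest.fixture
def desk_params_file(tmp_path, desk_params):
    path = tmp_path / "desk.yaml"
    dump_params(desk_params, path)
    return path
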