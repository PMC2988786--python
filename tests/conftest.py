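import numpy as np
import pytest

from zfclass.parsimony_scenarios import default_scenario_inputs


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def metazoan_scenario():
    """Bundled ladder species tree, zic presence map and origin candidates."""
    return default_scenario_inputs()


@pytest.fixture
def write_text_file(tmp_path):
    def _write(text, name="in.txt"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
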