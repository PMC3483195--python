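import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from famdomevo.trees import species_tree, table2_events


@pytest.fixture(scope="session")
def fixture_tree():
    return species_tree()


@pytest.fixture(scope="session")
def fixture_events():
    return table2_events()


@pytest.fixture(scope="session")
def mini_obo_path(tmp_path_factory):
    from famdomevo.simulate import MINI_OBO

    p = tmp_path_factory.mktemp("obo") / "mini.obo"
    p.write_text(MINI_OBO)
    return p
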