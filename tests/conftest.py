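from pathlib import Path

import pytest

from ringkit.fixtures import FIXTURES, named_fixture

DATA = Path(__file__).parent / "data"


@pytest.fixture(params=FIXTURES)
def fixture_molecule(request):
    return named_fixture(request.param)


def graph_of(name):
    return named_fixture(name).graph


@pytest.fixture
def barrelene():
    return graph_of("barrelene")


@pytest.fixture
def naphthalene():
    return graph_of("naphthalene")


@pytest.fixture
def anthracene():
    return graph_of("anthracene")


@pytest.fixture
def cyclohexane():
    return graph_of("cyclohexane")
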