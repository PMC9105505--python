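import pytest

from helpers import make_atom, random_rotation, random_structure


@pytest.fixture
def atom_factory():
    return make_atom


@pytest.fixture
def random_structure_factory():
    return random_structure


@pytest.fixture
def random_rotation_factory():
    return random_rotation
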