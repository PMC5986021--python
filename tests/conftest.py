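import pytest

import protatether as pt


@pytest.fixture(scope="session")
def toy_vector():
    """A no-linker toy fusion vector with the canonical junction arms."""
    return pt.make_toy_vector(pt.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def vector_primers(toy_vector):
    vlr = toy_vector.feature("downstream_gene").start
    return pt.design_vector_primers(toy_vector, vlr)


@pytest.fixture(scope="session")
def vector_amplicon(toy_vector, vector_primers):
    return pt.amplify_vector(toy_vector, vector_primers)


@pytest.fixture(scope="session")
def motif_panel():
    return list(pt.MOTIFS.values())
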