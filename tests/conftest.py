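import numpy as np
import pytest

from cubicdock import fixtures as fx


@pytest.fixture(scope="session")
def helix16():
    return fx.make_toy_subunit(fx.ToySpec(n_res=16, motif="helix"))


@pytest.fixture(scope="session")
def hairpin():
    return fx.make_toy_subunit(fx.ToySpec(n_res=22, motif="hairpin"))


@pytest.fixture(scope="session")
def toy_native():
    """Factory: (kind, fold) -> (subunit, assembly, symdef), memoized."""

    def build(kind, fold):
        return fx.cached_toy_native(kind, fold)

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
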