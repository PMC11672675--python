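import numpy as np
import pytest

import igentropy as ig
from igentropy.schemes import AMINO_ACIDS
from igentropy.simulate import _simplex


@pytest.fixture(scope="session")
def heavy_spec():
    return ig.default_spec("H", "kabat", "human")


@pytest.fixture(scope="session")
def light_spec():
    return ig.default_spec("L", "kabat", "human")


@pytest.fixture(scope="session")
def heavy_rep(heavy_spec):
    """A moderately sized heavy-chain repertoire shared across tests."""
    return ig.sample_repertoire(heavy_spec, 500, seed=11)


@pytest.fixture(scope="session")
def light_rep(light_spec):
    return ig.sample_repertoire(light_spec, 500, seed=12)


def random_simplex(rng: np.random.Generator, alpha: float = 1.0,
                   k: int = 20) -> np.ndarray:
    return rng.dirichlet(np.full(k, alpha))


def shifted_delta(spec: ig.RepertoireSpec, label: str) -> np.ndarray:
    """A planted replacement distribution guaranteed to differ from the
    original: 0.9 mass on the amino acid after the original mode."""
    tpl = next(iter(spec.templates.values()))
    orig = next(ps for ps in tpl.positions if ps.position.label == label)
    mode = int(np.argmax(orig.distribution))
    return _simplex({AMINO_ACIDS[(mode + 1) % 20]: 0.9})
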