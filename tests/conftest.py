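import numpy as np
import pytest

from floretgen.fixtures import make_fixtures
from floretgen.morphology import Floret, Segment


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return make_fixtures()


def random_topology(rng: np.random.Generator, n_internal: int,
                    lengths: str = "random") -> Floret:
    """A random binary tree with ``n_internal`` bifurcations.

    Grown by repeatedly expanding a uniformly chosen terminal into a
    bifurcation.  ``lengths``: "random" (uniform on [0.5, 20]), "equal"
    (all 1) or a float.
    """
    def draw_len() -> float:
        if lengths == "random":
            return float(rng.uniform(0.5, 20.0))
        if lengths == "equal":
            return 1.0
        return float(lengths)

    segments = {1: Segment(1, None, draw_len())}
    terminals = [1]
    next_id = 2
    for _ in range(n_internal):
        parent = terminals.pop(int(rng.integers(len(terminals))))
        for _ in range(2):
            segments[next_id] = Segment(next_id, parent, draw_len())
            terminals.append(next_id)
            next_id += 1
    return Floret(segments.values())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
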