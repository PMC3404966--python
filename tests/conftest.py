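import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirantag.io import PairedExpressionSet
from mirantag.simulate import simulate_pair

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_planted_set(
    n_mirna: int = 3,
    n_gene: int = 4,
    n_samples: int = 60,
    seed: int = 0,
    planted: tuple[str, str] | None = ("mir0", "g0"),
) -> PairedExpressionSet:
    """Independent uniform expression rows, optionally with one antagonistic pair.

    The planted (miRNA, gene) pair replaces the corresponding rows with a
    noise-free triangular synthetic pair.
    """
    g = np.random.default_rng(seed)
    mirna = pd.DataFrame(
        g.random((n_mirna, n_samples)),
        index=[f"mir{i}" for i in range(n_mirna)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    mrna = pd.DataFrame(
        g.random((n_gene, n_samples)),
        index=[f"g{i}" for i in range(n_gene)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    if planted is not None:
        pair = simulate_pair(n_samples, 0.0, seed=g)
        mirna.loc[planted[0]] = pair.x
        mrna.loc[planted[1]] = pair.y
    return PairedExpressionSet(mirna, mrna)


@pytest.fixture
def planted_set() -> PairedExpressionSet:
    return make_planted_set()
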