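import numpy as np
import pytest

from kappameta import CrossTab, QUIS_SCALE, SCHEME_NAMES, named_scheme
from kappameta.datasets import (
    quis_collapsed_table,
    quis_highest_period_table,
    quis_lowest_period_table,
)


@pytest.fixture
def collapsed_tab() -> CrossTab:
    """Published cross-tab collapsed over all 18 observation periods (n=354)."""
    return quis_collapsed_table()


@pytest.fixture
def lowest_tab() -> CrossTab:
    """Published cross-tab of the period with the lowest unweighted kappa."""
    return quis_lowest_period_table()


@pytest.fixture
def highest_tab() -> CrossTab:
    """Published cross-tab of the period with the highest unweighted kappa."""
    return quis_highest_period_table()


def random_table(rng: np.random.Generator, k: int = 5,
                 max_n: int = 50) -> CrossTab:
    """A random k x k table with at least 2 interactions, non-degenerate.

    Rejects tables whose margins are fully concentrated in weight-1 cells
    (where chance-corrected agreement is undefined).
    """
    scale = QUIS_SCALE if k == 5 else _generic_scale(k)
    while True:
        n = int(rng.integers(2, max_n + 1))
        probs = rng.dirichlet(np.ones(k * k) * rng.uniform(0.2, 2.0))
        counts = rng.multinomial(n, probs).reshape(k, k)
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)
        # Non-degenerate: margins must not all sit on one category.
        if np.count_nonzero(row) > 1 or np.count_nonzero(col) > 1:
            return CrossTab(scale, counts)


def _generic_scale(k: int):
    from kappameta import CategoryScale

    return CategoryScale(tuple(f"c{i + 1}" for i in range(k)))


def random_scheme(rng: np.random.Generator):
    """One of the built-in five-category schemes, chosen at random."""
    return named_scheme(SCHEME_NAMES[rng.integers(len(SCHEME_NAMES))])
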