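import numpy as np
import pytest

from zonecell.lattice import UnitCell


def make_random_cell(rng: np.random.Generator, lo: float = 5.0, hi: float = 20.0) -> UnitCell:
    """A random, reasonably non-degenerate triclinic cell."""
    while True:
        a, b, c = rng.uniform(lo, hi, 3)
        al, be, ga = rng.uniform(70.0, 110.0, 3)
        try:
            cell = UnitCell(a, b, c, al, be, ga)
        except ValueError:
            continue
        if cell.volume > 0.3 * a * b * c:  # avoid nearly flat cells
            return cell


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def random_cells(rng):
    return [make_random_cell(rng) for _ in range(50)]
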