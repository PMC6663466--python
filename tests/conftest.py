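import numpy as np
import pytest

from asorpipe.solutions import load_recipes
from asorpipe.synth import GeneEffect, QuenchModel, ScreenDesign, simulate_screen


@pytest.fixture(scope="session")
def recipes():
    return load_recipes()


@pytest.fixture(scope="session")
def small_screen():
    """A 300-gene single-plate screen with one strong planted hit.

    Seed chosen once; the planted gene survives the viability filter in this
    realization, so end-to-end ranking behavior is deterministic.
    """
    design = ScreenDesign(n_genes=300, seed=1)
    data, truth = simulate_screen(
        design, QuenchModel(), [GeneEffect("GENE42", 0.8)], seed=7
    )
    return design, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
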