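import numpy as np
import pytest

import ecomorph as em


@pytest.fixture(scope="session")
def paper_design_radiation():
    """A radiation at the emulated study design: 95 species, 4 islands,
    6 ecomorphs with 3 absences, ~2.7 individuals per species."""
    params = em.RadiationParams(seed=11)
    tree = em.simulate_tree(params.n_species, seed=11)
    return em.simulate_radiation(tree, params)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete raw study (landmarks, linear table, tree)."""
    return em.simulate_study(em.RadiationParams(n_species=24, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
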