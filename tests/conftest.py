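import numpy as np
import pandas as pd
import pytest

import mireqtl as m


@pytest.fixture(scope="session")
def simpson_exact():
    """Default exact-mode Simpson-masking dataset (180 individuals)."""
    return m.make_simpson_dataset(m.SimpsonDesign(), seed=7)


@pytest.fixture(scope="session")
def nontransitivity_exact():
    """Default exact-mode non-transitivity dataset (60 individuals)."""
    return m.make_nontransitivity_dataset(m.NonTransitivityDesign(), seed=7)


@pytest.fixture(scope="session")
def cohort_default():
    """One default multi-population cohort realization."""
    return m.simulate_cohort(m.CohortDesign(), seed=11)


def random_small_dataset(rng):
    """A random small (n<=30) expression/genotype/population dataset with a
    full-rank design, for oracle comparisons."""
    while True:
        n = int(rng.integers(8, 31))
        g = rng.integers(0, 3, size=n).astype(float)
        pop = rng.choice(["A", "B", "C"][: int(rng.integers(2, 4))], size=n)
        y = rng.standard_normal(n) + 0.3 * g + (pop == "A") * 1.5
        # full rank: genotype varies overall and at least 2 pops present
        if len(np.unique(g)) >= 2 and len(np.unique(pop)) >= 2:
            df = pd.DataFrame({"y": y, "g": g, "pop": pop})
            # require genotype variation not fully confounded with population
            X = np.column_stack([np.ones(n), g] +
                                [(pop == p).astype(float) for p in np.unique(pop)[1:]])
            if np.linalg.matrix_rank(X) == X.shape[1]:
                return df
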