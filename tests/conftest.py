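import warnings

import numpy as np
import pandas as pd
import pytest

from climbmet import preprocess as pp
from climbmet import synthetic as syn

warnings.filterwarnings("ignore", category=UserWarning, module="climbmet")


@pytest.fixture(scope="session")
def default_metabolome():
    """Study-conditions metabolome, preprocessed through the QC chain."""
    spec = syn.default_metabolome_spec(seed=101)
    mat, meta = syn.simulate_metabolome(spec)
    mm = pp.MetabolomeMatrix(mat, meta, "centered")
    mm = pp.residualize_run_order(pp.correct_batch(mm))
    mm, _ = pp.remove_outliers(mm)
    return mm


@pytest.fixture(scope="session")
def default_graph():
    return syn.simulate_hetero_graph(syn.GraphSpec(seed=7))


@pytest.fixture(scope="session")
def default_path_index(default_graph):
    from climbmet import keggnet as kn

    return kn.build_path_index(default_graph)


@pytest.fixture()
def toy_survival():
    """Three flies: deaths at 1 and 3, a censor at 2 (entry 0)."""
    return pd.DataFrame(
        {"entry_age": [0.0, 0.0, 0.0], "exit_age": [1.0, 2.0, 3.0],
         "event": [1, 0, 1]}
    )


def random_survival_table(rng: np.random.Generator, max_n: int = 5) -> pd.DataFrame:
    """A small random survival table with integer-ish times (shared by the
    brute-force estimator property tests)."""
    n = int(rng.integers(1, max_n + 1))
    entry = np.zeros(n)
    exit_ = entry + rng.integers(1, 8, size=n)
    event = rng.integers(0, 2, size=n)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return pd.DataFrame({"entry_age": entry, "exit_age": exit_.astype(float),
                         "event": event})
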