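import numpy as np
import pandas as pd
import pytest

import clonoscope as cs


def make_clone_table(spec: dict, arm: str = "arm1", batch: str = "batch1") -> pd.DataFrame:
    """Clone table from {clone_id: [class, class, ...]}."""
    rows = []
    i = 0
    for clone, classes in spec.items():
        for cls in classes:
            rows.append((f"cell{i:04d}", clone, cls, arm, batch))
            i += 1
    return pd.DataFrame(rows, columns=["cell_id", "clone_id", "cell_class", "arm", "batch"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    return cs.SimConfig(n_progenitors=25, n_batches=2, reads_per_cell=6, n_genes=60,
                        n_informative_genes=8, seed=11)
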