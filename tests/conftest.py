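import numpy as np
import pytest

import merfishpipe as mp


@pytest.fixture
def small_config():
    """Two cell types, two rectangular domains, planted age/LPS/gradient effects."""
    genes = [f"g{i}" for i in range(30)]
    means_a = np.full(30, 2.0)
    means_a[:5] = 8.0
    means_b = np.full(30, 2.0)
    means_b[5:10] = 8.0
    return mp.SyntheticConfig(
        genes=genes,
        cell_types=[
            mp.CellTypeSpec("astro", means_a, 10.0),
            mp.CellTypeSpec("micro", means_b, 10.0),
        ],
        n_cells_per_type=100,
        layout=[
            mp.DomainSpec("cortex", 0, 0, 500, 500, {"astro": 0.7, "micro": 0.3}, n_cells=300),
            mp.DomainSpec("striatum", 520, 0, 1000, 500, {"astro": 0.2, "micro": 0.8}, n_cells=300),
        ],
        age_effects={"g0": ("astro", float(np.log(4)))},
        activation_gradient=mp.ActivationGradient("astro", "micro", 5.0, 20.0, ("g3", "g4")),
        lps_effects={"g1": ("micro", 1.0)},
        seed=3,
    )


@pytest.fixture
def normalized_section(small_config):
    """One simulated section, QC'd and fully normalized."""
    import warnings

    table = mp.simulate_merfish(small_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = mp.qc_merfish(table, min_counts=5)
    return mp.normalize_expression(table)
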