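import numpy as np
import pandas as pd
import pytest

import regulokit as rk


@pytest.fixture(scope="session")
def small_regulome():
    """A modest regulome with branch-specific closures, shared across tests."""
    return rk.simulate_regulome(
        n_tfs=6, n_targets=40, n_obs=300, noise_sd=0.1, seed=11, closed_fraction=0.15
    )


@pytest.fixture(scope="session")
def small_grn(small_regulome):
    truth, data, regions, genes, motifs, genome = small_regulome
    pairs = rk.assign_regions_to_genes(regions, genes)
    grn, modules = rk.infer_grn(data, rk.truth_sites(truth), pairs)
    return grn, modules


@pytest.fixture(scope="session")
def screen_sim():
    return rk.simulate_screen(
        n_cells=1200,
        targets=[f"T{i}" for i in range(6)],
        effect_sizes={"T0": ("ventral", 2.5)},
        seed=5,
    )


def region_set(*records):
    return rk.RegionSet.from_records(list(records))
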