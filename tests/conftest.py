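import numpy as np
import pandas as pd
import pytest

from tnhomeo.counts_io import CountMatrix, SampleDesign
from tnhomeo.simdata import TruthConfig, default_design, simulate_experiment


@pytest.fixture(scope="session")
def one_strain_design() -> SampleDesign:
    """wt strain, 3 stresses x 3 levels + control, 4 reps, 2 batches."""
    return default_design(strains=("wt",))


@pytest.fixture(scope="session")
def two_group_design() -> SampleDesign:
    """Control vs heat-low, 4 replicates each, single batch."""
    rows = []
    for j in range(1, 5):
        rows.append({"sample_id": f"c{j}", "strain": "wt", "stress": "control",
                     "level": "none", "replicate": j, "batch": "b1"})
        rows.append({"sample_id": f"h{j}", "strain": "wt", "stress": "heat",
                     "level": "low", "replicate": j, "batch": "b1"})
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_experiment(one_strain_design):
    """L=120 simulated two-channel experiment with planted classes."""
    cfg = TruthConfig(L=120, K_true=2, dispersion_range=(2.0, 5.0))
    return simulate_experiment(one_strain_design, cfg, seed=101)


@pytest.fixture()
def counts_3x2() -> CountMatrix:
    return CountMatrix(["gA", "gB", "gC"], ["s1", "s2"],
                       np.array([[0, 1], [5, 2], [0, 7]]), "unique")
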