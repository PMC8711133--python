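import numpy as np
import pytest

import torsionkit as tk
from torsionkit.model import DihedralSeries, DihedralTerm


@pytest.fixture(scope="session")
def paper_series():
    """The published two-term benzamidine torsion correction."""
    return tk.fixtures.paper_series()


@pytest.fixture(scope="session")
def benz_profile():
    """Synthetic benzamidine-like scan (4.5 / 2.5 kcal/mol barriers)."""
    return tk.fixtures.make_benzamidine_like_scan()


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(-np.pi, np.pi, 2000, endpoint=False)


@pytest.fixture(scope="session")
def double_well_metad_run():
    """One full WT-MetaD run on a 4.5 kcal/mol double well.

    Bias settings mirror the validation protocol (hill height 0.1 kJ/mol,
    sigma 0.05 rad, biasfactor 15, one hill per 1,000 steps); 5e7 steps at
    the 2 fs-equivalent timestep correspond to the 100 ns over which such
    runs converge.  Session-scoped: the run is shared by the sampler tests
    and the acceptance checks.
    """
    potential = DihedralSeries((DihedralTerm(2.25, 2, 0.0),))
    config = tk.MetaDConfig(height_kj=0.1, sigma=0.05, biasfactor=15.0,
                            pace=1000, n_steps=50_000_000, seed=7,
                            record_stride=1000)
    traj, hills = tk.run_wtmetad(potential, config)
    return potential, config, traj, hills
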