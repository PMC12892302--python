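import numpy as np
import pandas as pd
import pytest

from deepsuvr import centiloid as cc
from deepsuvr import natural_history as nh
from deepsuvr import phantom as ph
from deepsuvr import training as tr


@pytest.fixture(scope="session")
def grid16():
    return ph.make_brain_grid((16, 16, 16), voxel_size_mm=6.0)


@pytest.fixture(scope="session")
def grid_desk():
    return ph.make_brain_grid()


@pytest.fixture(scope="session")
def transforms_desk(grid_desk):
    return cc.default_transforms(grid_desk)


@pytest.fixture(scope="session")
def small_cohort(grid_desk):
    """60 subjects, 2-3 visits, default biased acquisition conditions."""
    return ph.generate_cohort(n_subjects=60, seed=7, grid=grid_desk)


@pytest.fixture(scope="session")
def small_data(small_cohort, transforms_desk):
    return tr.prepare_training_data(small_cohort, transforms_desk)


@pytest.fixture(scope="session")
def small_pairs(small_data):
    return tr.select_pairs(small_data.table)


@pytest.fixture(scope="session")
def pib_curve(small_data, small_pairs):
    """Static natural-history curve from standard-quantification PIB pairs."""
    a = small_pairs["idx_a"].to_numpy()
    b = small_pairs["idx_b"].to_numpy()
    trc = np.array(small_data.tracer)
    pib = (trc[a] == "PIB") & (trc[b] == "PIB")
    stats = nh.compute_pair_stats(
        pd.DataFrame(
            {
                "CL0": small_data.cl_std[a][pib],
                "T0": small_data.time_years[a][pib],
                "CL1": small_data.cl_std[b][pib],
                "T1": small_data.time_years[b][pib],
            }
        )
    )
    return nh.fit_rate_curve(stats)
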