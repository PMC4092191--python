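import numpy as np
import pytest

from epirepair.abm import ModelParams, Sheet, run_simulation

S = 6.7  # default lattice pitch, µm


def make_free_sheet(positions):
    """Ad-hoc open planar configuration: no anchors, no wrap, no tether."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    return Sheet(
        positions=pos.copy(),
        anchored=np.zeros(n, dtype=bool),
        over_threshold_run=np.zeros(n, dtype=int),
        born_at=np.zeros(n, dtype=int),
        gap=(0.0, 0.0),
        axial_extent=float(np.ptp(pos[:, 0])) if n else 0.0,
        transverse_extent=float(np.ptp(pos[:, 1])) if n else 0.0,
        anchor_margin=0.0,
        transverse_period=None,
        adhesion_ref=None,
    )


@pytest.fixture
def passive_params():
    """Interaction-only parameters: no motility, no crawling, no tether."""
    return ModelParams(motility_sigma=0.0, edge_speed=0.0, k_sub=0.0)


@pytest.fixture(scope="session")
def long_run():
    """One seeded long-ablation run at the calibrated defaults."""
    return run_simulation(ModelParams(seed=1), rows=10, cols=80,
                          gap_length=90.0, record_positions=False)


@pytest.fixture(scope="session")
def short_run():
    """One seeded short-ablation run at the calibrated defaults."""
    return run_simulation(ModelParams(seed=1), rows=10, cols=80,
                          gap_length=20.1, record_positions=False)
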