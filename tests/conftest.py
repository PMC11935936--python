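import numpy as np
import pytest

from opmflow.geometry import ChannelGeometry
from opmflow.scene import CellSpec, KinematicState, PhaseLabel, ScenePopulation


@pytest.fixture
def geometry():
    return ChannelGeometry()


def make_cell(center, radius=5.0, phase=PhaseLabel.INTERPHASE,
              orientation=(0.0, 0.0, 0.0, 1.0), budgets=None, cell_id=0,
              partner_id=None):
    return CellSpec(
        id=cell_id,
        center=np.asarray(center, dtype=float),
        cell_radius=radius,
        phase=phase,
        orientation=np.asarray(orientation, dtype=float),
        budgets=budgets or {"cyto": 2e4, "dna": 1e4, "mitotic_marker": 150.0},
        partner_id=partner_id,
    )


def make_flowing_population(cells, geometry=None, speeds=None):
    geometry = geometry or ChannelGeometry(height_h=200.0, width_w=2000.0,
                                           length_l=500.0)
    pop = ScenePopulation(list(cells), geometry, 0.0, 0)
    n = len(pop)
    speeds = np.full(n, 500.0) if speeds is None else np.asarray(speeds, float)
    pop.kinematics = KinematicState(
        z=pop.positions[:, 2] if n else np.zeros(0),
        speed_u=speeds,
        spin_omega=np.zeros(n),
    )
    return pop
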