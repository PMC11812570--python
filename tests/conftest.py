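import numpy as np
import pytest

from smolsensor.kinetics import KineticParams
from smolsensor.simulate import MonomerModel, SceneSpec


@pytest.fixture
def monomer_model() -> MonomerModel:
    return MonomerModel()


@pytest.fixture
def scene() -> SceneSpec:
    return SceneSpec()


@pytest.fixture
def single_molecule_params() -> KineticParams:
    """Two-phase parameters with k_syn = 1.09 and k_deg = 0.13 per minute."""
    return KineticParams(F_max=1.0, n_syn=2.0, tau_syn=1 / 1.09, n_deg=2.0, tau_deg=1 / 0.13)


@pytest.fixture
def half_minute_grid() -> np.ndarray:
    """Stimulus at t = 0; one sample per 30 s out to 15 min, 2 min baseline."""
    return np.arange(-2.0, 15.25, 0.5)


def match_detections(table, positions, tol_um):
    """Greedy one-to-one matching of detections to ground-truth positions.

    Returns (n_matched, rms_error_um) for matches within ``tol_um``.
    """
    xy = table[["x", "y"]].to_numpy()
    used: set[int] = set()
    errs = []
    for i in range(len(xy)):
        d = np.hypot(positions[:, 0] - xy[i, 0], positions[:, 1] - xy[i, 1])
        j = int(np.argmin(d))
        if d[j] < tol_um and j not in used:
            used.add(j)
            errs.append(d[j])
    rms = float(np.sqrt(np.mean(np.square(errs)))) if errs else np.inf
    return len(errs), rms
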