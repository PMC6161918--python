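import numpy as np
import pandas as pd
import pytest

from oculoflow.config import ExclusionConfig, SimulationConfig
from oculoflow.preprocess import preprocess_samples
from oculoflow.simulate import simulate_session

MM_PER_PX = 531.0 / 1920.0


def make_samples(lx, ly=None, rx=None, ry=None, l_pupil=None, r_pupil=None,
                 participant=0, trial=0, step_ms=4):
    """Build a sample table from plain arrays (defaults: right = left,
    pupil 4 mm, y at screen center)."""
    lx = np.asarray(lx, dtype=float)
    n = lx.size
    ly = np.full(n, 540.0) if ly is None else np.asarray(ly, dtype=float)
    rx = lx.copy() if rx is None else np.asarray(rx, dtype=float)
    ry = ly.copy() if ry is None else np.asarray(ry, dtype=float)
    l_pupil = np.full(n, 4.0) if l_pupil is None else np.asarray(l_pupil, float)
    r_pupil = l_pupil.copy() if r_pupil is None else np.asarray(r_pupil, float)
    return pd.DataFrame({
        "participant": participant, "trial": trial,
        "time_ms": np.arange(n, dtype=np.int64) * step_ms,
        "lx_px": lx, "ly_px": ly, "rx_px": rx, "ry_px": ry,
        "l_pupil_mm": l_pupil, "r_pupil_mm": r_pupil,
    })


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def session_data(small_sim_config):
    """One simulated participant session plus its preprocessing outputs."""
    samples, trials, truth = simulate_session(small_sim_config, participant=0)
    mask, blinks, summary = preprocess_samples(
        samples, ExclusionConfig(), MM_PER_PX)
    return {"samples": samples, "trials": trials, "truth": truth,
            "mask": mask, "blinks": blinks, "summary": summary,
            "config": small_sim_config}
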