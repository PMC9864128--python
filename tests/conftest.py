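import warnings

import numpy as np
import pandas as pd
import pytest

from armabehave import synthetic
from armabehave import track_preprocess as prep

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def landscape():
    return synthetic.make_landscape(n_rows=300, n_cols=300, seed=3)


@pytest.fixture(scope="session")
def small_fixture():
    return synthetic.emit_fixture_small()


@pytest.fixture(scope="session")
def default_dataset(landscape):
    """Default 4-state preset, simulated once and preprocessed."""
    cfg = synthetic.GeneratorConfig()
    gps, acts, truth = synthetic.simulate_tracks(cfg, landscape, seed=3)
    obs, report = prep.preprocess(gps, acts)
    obs = obs.merge(truth, on=["individual_id", "timestamp"], how="left")
    return {"gps": gps, "acts": acts, "truth": truth, "obs": obs, "report": report}


def random_gps(rng, n=40, individual="a"):
    """A sorted synthetic GPS table with varied artifacts."""
    t0 = pd.Timestamp("2019-07-01 21:00:00", tz="UTC")
    dts = rng.choice([300.0, 420.0, 430.0, 500.0], size=n - 1)
    times = [t0]
    for dt in dts:
        times.append(times[-1] + pd.Timedelta(seconds=float(dt)))
    steps = rng.choice([20.0, 100.0, 900.0], p=[0.6, 0.3, 0.1], size=n - 1)
    angles = rng.uniform(-np.pi, np.pi, size=n - 1)
    xy = np.zeros((n, 2))
    xy[1:, 0] = np.cumsum(steps * np.cos(angles))
    xy[1:, 1] = np.cumsum(steps * np.sin(angles))
    return pd.DataFrame(
        {
            "individual_id": individual,
            "timestamp": times,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "n_satellites": rng.integers(3, 12, size=n),
        }
    )
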