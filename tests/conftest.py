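import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import sealhab as sh

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def world():
    return sh.default_world(seed=0)


@pytest.fixture(scope="session")
def domain(world):
    return sh.build_domain(world.front_line, world.ice_line, world.stack)


def make_segment(times_hours, x, y, lc="3", t0="2003-06-01"):
    """Assemble a projected CTCRW segment DataFrame."""
    times_hours = np.asarray(times_hours, dtype=float)
    lc = [lc] * len(times_hours) if isinstance(lc, str) else list(lc)
    return pd.DataFrame({
        "timestamp": pd.Timestamp(t0, tz="UTC") + pd.to_timedelta(times_hours, unit="h"),
        "x_km": np.asarray(x, dtype=float),
        "y_km": np.asarray(y, dtype=float),
        "lc": lc,
    })


def make_records(times_hours, lon, lat, lc=None, animal="A1", t0="1999-06-01"):
    """Assemble an ARGOS record DataFrame."""
    n = len(times_hours)
    return pd.DataFrame({
        "animal_id": animal,
        "timestamp": pd.Timestamp(t0, tz="UTC") + pd.to_timedelta(np.asarray(times_hours, float), unit="h"),
        "lon": np.asarray(lon, dtype=float),
        "lat": np.asarray(lat, dtype=float),
        "lc": lc if lc is not None else ["1"] * n,
    })


@pytest.fixture(scope="session")
def pipeline_products(world):
    """One moderate pipeline run shared by several tests (seed 0)."""
    tracks = sh.simulate_seal_tracks(world, 3, duration_days=90, seed=1)
    em = sh.ArgosErrorModel(spike_rate=0.02)
    obs = pd.concat([sh.argosify(t, em, seed=100 + i) for i, t in enumerate(tracks)],
                    ignore_index=True)
    segs, log = sh.clean_tracks(obs, world.stack)
    regs = sh.regularize_segments(segs)
    dom = sh.build_domain(world.front_line, world.ice_line, world.stack)
    table = sh.build_dataset(regs, dom, world.stack, world.colonies, seed=7)
    return {"tracks": tracks, "obs": obs, "segments": segs, "regs": regs,
            "domain": dom, "table": table, "log": log}
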