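import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from redoxcyto import AgingSimConfig, CalibrationModel, RedoxGates


@pytest.fixture(scope="session")
def paper_cal() -> CalibrationModel:
    """Calibration with the published control slopes and equal 488 anchors."""
    return CalibrationModel(
        i405_red_mean=60.0,
        i488_red_mean=100.0,
        i405_ox_mean=357.0,
        i488_ox_mean=100.0,
        r_red=0.6,
        r_ox=3.57,
        n_red=100,
        n_ox=100,
    )


@pytest.fixture(scope="session")
def sim_cfg() -> AgingSimConfig:
    return AgingSimConfig(seed=7)


@pytest.fixture(scope="session")
def gates() -> RedoxGates:
    return RedoxGates()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_events(i405, i488, pi=None, marker=None, **attrs) -> pd.DataFrame:
    """Small helper to assemble an event table by hand."""
    i405 = np.asarray(i405, dtype=float)
    df = pd.DataFrame(
        {
            "i405": i405,
            "i488": np.asarray(i488, dtype=float),
            "pi": np.zeros_like(i405) if pi is None else np.asarray(pi, dtype=float),
        }
    )
    if marker is not None:
        df["marker"] = np.asarray(marker, dtype=float)
    df.attrs.update(attrs)
    return df
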