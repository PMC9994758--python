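import numpy as np
import pandas as pd
import pytest

from phenofcm.simulate import SimConfig, simulate_season


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_fields=8, seed=7)


@pytest.fixture(scope="session")
def small_season(small_config):
    return simulate_season(small_config)


@pytest.fixture(scope="session")
def clean_season():
    """Noise-free, gap-free small season for sharp structural checks."""
    cfg = SimConfig(n_fields=6, reflectance_sd=0.0, temp_sd=0.0, cloud_gap_prob=0.0, seed=11)
    return simulate_season(cfg)


@pytest.fixture()
def tiny_bands():
    """Two fields x three acquisitions with hand-set reflectances."""
    rows = []
    for fid in ("a", "b"):
        for doy, b08, b04 in ((100, 0.2, 0.1), (110, 0.4, 0.08), (120, 0.5, 0.05)):
            rows.append(
                {
                    "field_id": fid,
                    "doy": doy,
                    "B02": 0.05,
                    "B03": 0.07,
                    "B04": b04,
                    "B06": 0.3,
                    "B08": b08 if fid == "a" else b08 + 0.1,
                    "B11": 0.25,
                    "B12": 0.2,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_weather():
    """Daily weather DoY 100..120 for the two tiny fields, GDD = 5/day."""
    rows = []
    for fid in ("a", "b"):
        for doy in range(100, 121):
            rows.append(
                {
                    "field_id": fid,
                    "doy": doy,
                    "t2m_min": 15.6,
                    "t2m_max": 25.6,
                    "tsurf_min": 16.0,
                    "tsurf_max": 27.0,
                    "tsoil_min": 14.0,
                    "tsoil_max": 20.0,
                    "soilmoist_min": 0.18,
                    "soilmoist_max": 0.22,
                    "precip": 1.0,
                    "swrad": 200.0,
                }
            )
    return pd.DataFrame(rows)
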