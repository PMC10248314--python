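import pandas as pd
import pytest

from erdodi import SimulationParams, default_battery, simulate_cohort


@pytest.fixture(scope="session")
def ei5():
    return default_battery()


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-examinee synthetic cohort."""
    return simulate_cohort(SimulationParams(n=60, seed=42))


@pytest.fixture()
def toy_cohort(ei5) -> pd.DataFrame:
    """Three hand-recodeable rows with totals 0, 3 and 9.

    Row 0: all scores pass every cutoff -> levels (0,0,0,0,0), total 0.
    Row 1: CD=6 (1), RCFT=28.0 (1), FMS=3 (1), RDS=8 (0), RH=13 (0) -> 3.
    Row 2: CD=5 (2), RCFT=24.0 (2), FMS=4 (2), RDS=6 (2), RH=11 (2)
           minus one: RH=12 (1) -> 2+2+2+2+1 = 9.
    """
    return pd.DataFrame(
        {
            "CD": [10, 6, 5],
            "RCFT_Copy": [34.0, 28.0, 24.0],
            "FMS_WCST": [0, 3, 4],
            "RDS": [12, 8, 6],
            "RH_CVLT": [15, 13, 12],
        }
    )
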