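import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cytodose import AberrationTally, MetaphaseRecord, fit_lq
from cytodose.dose_response import points_from_tallies
from cytodose.synthetic_cohort import make_cohort_spec, simulate_tallies


@pytest.fixture
def worked_tally() -> AberrationTally:
    """Mixed-class tally whose DSB total is worked out by hand (13)."""
    return AberrationTally(
        group_id="g", dose_gy=1.0, n_cells=10,
        n_dicentric=2, n_centric_ring=1, n_ace_4tel=3,
        n_ace_2tel=3, n_ace_0tel=1, n_tel_deletion=2,
    )


def make_record(centromeres: int = 46, **counts) -> MetaphaseRecord:
    return MetaphaseRecord(
        donor_id="d1", group_id="g", dose_gy=1.0,
        centromere_count=centromeres, **counts,
    )


@pytest.fixture(scope="session")
def senegal_calibration_curve():
    """Dicentric curve fitted to a large simulated Senegal-preset cohort."""
    spec = make_cohort_spec(
        "senegal_africa", cells_per_dose=2000, seed=7, dispersion=1.0
    )
    return fit_lq(points_from_tallies(simulate_tallies(spec), "dicentrics"))
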