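import numpy as np
import pytest

from tregmap import TissueSchedule, load_scenario, simulate_cohort


@pytest.fixture(scope="session")
def scenario():
    """Bundled study scenario (calibration is cached per schedule)."""
    return load_scenario()


@pytest.fixture(scope="session")
def ontogeny_cohort(scenario):
    """One simulated ontogeny cohort at a fixed seed (session-wide)."""
    return simulate_cohort(scenario, "ontogeny", seed=123)


def make_schedule(
    horizon=100,
    influx=None,
    division=0.0,
    loss_resident=0.0,
    loss_flux=0.0,
    residency_cutoff_day=0,
    name="toy",
    sampled_cells=2000,
    kappa=50.0,
):
    """Small helper: constant-or-custom vectors for toy tissues."""
    if influx is None:
        influx_vec = np.zeros(horizon)
        influx_vec[0] = 1.0
    elif np.isscalar(influx):
        influx_vec = np.full(horizon, float(influx))
    else:
        influx_vec = np.asarray(influx, dtype=float)
    division_vec = (
        np.full(horizon, float(division)) if np.isscalar(division) else np.asarray(division)
    )
    return TissueSchedule(
        name=name,
        horizon_days=horizon,
        influx=influx_vec,
        division=division_vec,
        loss_resident=loss_resident,
        loss_flux=loss_flux,
        residency_cutoff_day=residency_cutoff_day,
        sampled_cells=sampled_cells,
        overdispersion_kappa=kappa,
    )


@pytest.fixture
def toy_schedule():
    return make_schedule()
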