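import numpy as np
import pytest

import antreg as A


@pytest.fixture(scope="session")
def schedule():
    return A.SignalSchedule(t0=0.0, t1=6.0, t2=12.0, s1_level=1.0, s2_level=1.0)


@pytest.fixture(scope="session")
def base_params():
    return A.default_parameters()


@pytest.fixture(scope="session")
def fitness_params():
    return A.FitnessParams(E_max=5.0, Km_T2=1.0, c0=0.05)


# ---------------------------------------------------------------------------
# expensive sweep results shared between the acceptance tests

@pytest.fixture(scope="session")
def kd_sweep_b(schedule, base_params, fitness_params):
    """Default 25-point kd sweep, promoter-strength mode."""
    cfg = A.SearchConfig(mode=A.SearchMode.PROMOTER_STRENGTH, seed=11)
    return A.sweep_kd(
        A.default_kd_grid(25),
        schedule=schedule,
        base_params=base_params,
        bounds=A.default_bounds(cfg.mode),
        fp=fitness_params,
        cfg=cfg,
    )


@pytest.fixture(scope="session")
def kd_sweep_kon(schedule, base_params, fitness_params):
    """Default 25-point kd sweep, binding-affinity mode."""
    cfg = A.SearchConfig(mode=A.SearchMode.BINDING_AFFINITY, seed=11)
    return A.sweep_kd(
        A.default_kd_grid(25),
        schedule=schedule,
        base_params=base_params,
        bounds=A.default_bounds(cfg.mode),
        fp=fitness_params,
        cfg=cfg,
    )


@pytest.fixture(scope="session")
def emax_kd_sweep(schedule, base_params, fitness_params):
    """Reduced 5x15 (E_max, kd) phase map."""
    cfg = A.SearchConfig(seed=11)
    return A.sweep_emax_kd(
        np.geomspace(0.5, 10.0, 5),
        np.geomspace(1e-3, 10.0, 15),
        schedule=schedule,
        base_params=base_params,
        bounds=A.default_bounds(cfg.mode),
        fp=fitness_params,
        cfg=cfg,
    )
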