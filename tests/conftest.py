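import numpy as np
import pytest

import lumispan as ls


@pytest.fixture
def four_point_series() -> ls.SurvivalSeries:
    """Small worked series: 20 worms scored at days 5/10/15/20."""
    return ls.SurvivalSeries(
        timepoints=[5.0, 10.0, 15.0, 20.0],
        n_scored=[20, 20, 20, 20],
        n_alive=[19, 15, 8, 2],
        treatment="worked",
    )


@pytest.fixture
def cubic_curve() -> ls.TrueSurvivalCurve:
    """Reference cubic-logit curve with 50% crossing near day 18."""
    return ls.default_cubic_curve()


@pytest.fixture
def simulated_series(cubic_curve) -> ls.SurvivalSeries:
    design = ls.LifespanDesign(seed=42)
    return ls.simulate_lifespan_series(cubic_curve, design)


@pytest.fixture
def linear_curve() -> ls.TrueSurvivalCurve:
    """Linear-logit curve whose closed-form median is 20 days."""
    return ls.TrueSurvivalCurve(
        coefficients=(5.0, -0.25), time_window=(0.0, 40.0), true_median=20.0
    )


def make_plate_config(seed: int, **overrides) -> ls.PlateSimConfig:
    kwargs = dict(
        treatment_effects={"DMSO": 1.0, "SSE": 0.55},
        seed=seed,
        noise_cv=0.1,
        wells_per_replicate=8,
    )
    kwargs.update(overrides)
    return ls.PlateSimConfig(**kwargs)


@pytest.fixture
def plate_records():
    config = make_plate_config(seed=123)
    return ls.simulate_plate(config, n_wells_per_treatment=24, timepoint_h=4.0)
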