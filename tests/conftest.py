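import numpy as np
import pytest

from mycometry import PlateTraces, SimulationConfig


@pytest.fixture
def noise_free_config():
    """Two organisms, one substrate, no lab/plate/trace noise."""
    return SimulationConfig(
        organisms=["A", "B"],
        substrates=["s"],
        intrinsic_rate={"A": 3.0, "B": 6.0},
        substrate_factor={"s": 1.0},
        n_labs=2,
        lab_effect_sd=0.0,
        plate_effect_sd=0.0,
        trace_noise_sd=0.0,
        n_plates=2,
        n_days=5,
        seed=0,
    )


@pytest.fixture
def lab_effect_config():
    """Multiplicative lab effects only (omega > 0, tau = s = 0)."""
    return SimulationConfig(
        organisms=["A", "B"],
        substrates=["s"],
        intrinsic_rate={"A": 3.0, "B": 6.0},
        substrate_factor={"s": 1.0},
        n_labs=5,
        lab_effect_sd=0.3,
        plate_effect_sd=0.0,
        trace_noise_sd=0.0,
        n_plates=3,
        n_days=5,
        seed=11,
    )


def make_plate(radii_by_axis, days=None, key=("lab1", "orgA", "subS", "local", "p1"),
               contaminated=False):
    """PlateTraces from {axis_id: [r_day1, r_day2, ...]}."""
    obs = []
    for axis, radii in radii_by_axis.items():
        ds = days if days is not None else range(1, len(radii) + 1)
        obs.extend((axis, float(d), float(r)) for d, r in zip(ds, radii))
    return PlateTraces(*key, observations=obs, contaminated=contaminated)


def pooled_ols_oracle(day, radius):
    """Textbook normal-equations slope/intercept, independent of scipy."""
    x = np.asarray(day, float)
    y = np.asarray(radius, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb
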