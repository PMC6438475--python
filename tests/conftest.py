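import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cytocascade import AnalysisConfig, CytokineSeries


@pytest.fixture
def config():
    return AnalysisConfig()


def piecewise_linear_series(knots, *, step=1.0, t_first=-30.0, t_last=300.0,
                            cytokine="TNF-a", animal="r1", subgroup="SubD-Sham"):
    """Series sampled at `step` resolution from a piecewise-linear shape.

    `knots` is a list of (time, value); the shape is 0 outside the knot
    span. Sampling at the analysis resolution makes the fitted curve
    reproduce the shape exactly on its grid, so analytic onset/AUC
    expectations apply.
    """
    kt = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    t = np.arange(t_first, t_last + 0.5 * step, step)
    y = np.interp(t, kt, kv, left=0.0, right=kv[-1] if kt[-1] >= t_last else 0.0)
    return CytokineSeries(animal_id=animal, subgroup=subgroup, cytokine=cytokine,
                          times=t, conc=np.clip(y, 0, None))


@pytest.fixture
def triangle_series():
    """0 on [-30, 100], linear rise to 100 at t=200, back to 0 at t=300."""
    return piecewise_linear_series([(100, 0), (200, 100), (300, 0)])
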