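import numpy as np
import pandas as pd
import pytest

from scotomap.field_geometry import build_grid, build_ladder, paper_grid
from scotomap.psychometrics import PsychometricParams, detection_probability


@pytest.fixture(scope="session")
def study_grid():
    """The 247-location nominal test grid of the study region."""
    return paper_grid()


@pytest.fixture(scope="session")
def ladder():
    return build_ladder()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bernoulli_observer(params: PsychometricParams, rng):
    """Stochastic observer responding from the frequency-of-seeing curve."""

    def observer(loc, contrast):
        return bool(rng.random() < detection_probability(params, contrast))

    return observer


@pytest.fixture
def flat_trials(rng):
    """Trials from a spatially uniform observer (alpha=-0.1, beta=3.5) on a
    small grid, with slightly jittered inferred locations."""
    grid = build_grid(0, 4, 0, 4, 0.5)
    p = PsychometricParams(alpha=-0.1, beta=3.5)
    rows = []
    for loc in grid:
        for c in np.linspace(-0.5, 0.3, 6):
            rows.append(
                dict(
                    inferred_x_deg=loc.x + rng.normal(0, 0.1),
                    inferred_y_deg=loc.y + rng.normal(0, 0.1),
                    log_contrast=c,
                    seen=bool(rng.random() < detection_probability(p, c)),
                )
            )
    return grid, pd.DataFrame(rows)
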