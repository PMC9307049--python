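import numpy as np
import pytest

from mycouptake.growth import GrowthParams
from mycouptake.synthetic import WEEK_S


@pytest.fixture
def study_params() -> GrowthParams:
    """Destructive-measurement-scale tip kinetics used as generator truth."""
    return GrowthParams(k=4.66e-4, v=1.64e-5, b_branch=2.07e-6, d=0.0)


@pytest.fixture
def dense_design():
    """A dense observation design that identifies (k, v, b) well."""
    return {
        "positions_cm": np.linspace(0.5, 4.5, 10),
        "times_s": np.linspace(1.0, 5.0, 5) * WEEK_S,
    }


@pytest.fixture
def sparse_design():
    """The imaging design: three heights, two harvests."""
    return {
        "positions_cm": (1.35, 2.85, 4.35),
        "times_s": (2 * WEEK_S, 4 * WEEK_S),
    }
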