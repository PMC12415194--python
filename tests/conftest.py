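import numpy as np
import pytest

from transleak import QuenchParams, SigmoidResponse, UnifiedParams


@pytest.fixture
def quench():
    """Default ANTS/DPX chemistry used throughout the suite."""
    return QuenchParams()


@pytest.fixture
def graded_params(quench):
    """Generating parameters of the graded-dominated (PC:PG-like) system."""
    return UnifiedParams(
        pleak=SigmoidResponse(c1=3.0, c2=0.4),
        foutv=SigmoidResponse(c1=10.0, c2=0.7),
        quench=quench,
    )


@pytest.fixture
def mixed_params(quench):
    """Generating parameters of the mixed (lysoPC-like) system."""
    return UnifiedParams(
        pleak=SigmoidResponse(c1=10.0, c2=0.7),
        foutv=SigmoidResponse(c1=10.0, c2=0.6),
        quench=quench,
    )


@pytest.fixture
def cp_grid():
    return np.linspace(0.02, 0.98, 25)
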