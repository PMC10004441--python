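import numpy as np
import pytest

from pmmkinetics.rates import RateConstants


@pytest.fixture
def published_rates() -> RateConstants:
    """The printed rate-constant set used as fixed numeric input."""
    return RateConstants(
        kA=0.056, kD=0.0056, k1=0.030, k_minus1=0.0049, k2=0.007,
        chi_eq=0.860, KR=1.85e-15,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
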