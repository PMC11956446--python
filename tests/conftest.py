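import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from splinetrial import (BetaPrior, DesignConfig, ElicitedQuantiles,
                         grid_posterior)

LEVELS5 = (0.05, 0.25, 0.5, 0.75, 0.95)


@pytest.fixture(scope="session")
def beta_4_16_quantiles() -> ElicitedQuantiles:
    """Exact quantiles of Beta(4, 16) at the standard elicitation levels."""
    values = tuple(beta_dist.ppf(LEVELS5, 4, 16))
    return ElicitedQuantiles(levels=LEVELS5, values=values, label="beta_4_16")


@pytest.fixture(scope="session")
def beta_4_8_grid():
    """Grid posterior equal to Beta(4, 8): uniform prior, 3 successes of 10."""
    return grid_posterior(BetaPrior(1, 1), 3, 10)


@pytest.fixture
def default_config() -> DesignConfig:
    return DesignConfig(n_total=100)


@pytest.fixture
def hdi_config() -> DesignConfig:
    return DesignConfig(n_total=100, rule_family="hdi")
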