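import math

import numpy as np
import pytest

from receptoire.rules import RuleThresholds
from receptoire.simulate import (
    SimulationConfig,
    make_reference_panel,
    simulate_counts,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def thresholds():
    return RuleThresholds()


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel(seed=11)


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast cohort: a handful of receptors per family per species."""
    return SimulationConfig(
        n_species=6,
        log_rates=(
            math.log(10.0), math.log(5.0), math.log(2.0), math.log(1.0),
            math.log(8.0),
        ),
        loadings=(0.3, 0.3, 0.1, 0.1, 0.3),
        proteome_size_range=(120, 140),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_species(small_cfg):
    """One simulated species proteome with planted truth (session-cached)."""
    rng = np.random.default_rng(7)
    counts, totals, _ = simulate_counts(small_cfg, rng=rng)
    sp = counts.index[0]
    return simulate_proteome(
        counts.loc[sp], small_cfg, rng=rng, total=int(totals.loc[sp])
    )
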