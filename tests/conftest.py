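import numpy as np
import pandas as pd
import pytest

import frip


@pytest.fixture
def embryo_trials():
    """Published-scale embryo-design trial table (Type II generating model)."""
    cfg = frip.SimulationConfig(
        attack_coefficient=0.85,
        handling_time=0.258,
        duration=1.0,
        densities=frip.EMBRYO_DENSITIES,
        replicates_per_density=25,
        seed=101,
        predator_label="large_invader",
        prey_label="embryo",
    )
    return frip.generate_trials(cfg)


@pytest.fixture
def larva_trials():
    """Published-scale larval-design trial table (48 h trials)."""
    cfg = frip.SimulationConfig(
        attack_coefficient=0.392,
        handling_time=0.988,
        duration=2.0,
        densities=frip.LARVA_DENSITIES,
        replicates_per_density=11,
        seed=202,
        predator_label="large_invader",
        prey_label="larva",
    )
    return frip.generate_trials(cfg)


@pytest.fixture
def mixed_survey():
    """Two-group quadrat survey at contrasting densities."""
    q1 = frip.generate_quadrat_survey(
        83.28, 2.0, 30, seed=11, group="intermediate_invader"
    )
    q2 = frip.generate_quadrat_survey(17.378, 2.0, 30, seed=12, group="native")
    return pd.concat([q1, q2], ignore_index=True)


@pytest.fixture
def table3_effects():
    """Feeding-rate and abundance summaries for the three predator groups."""
    return {
        "large_invader": frip.EffectSummary("large_invader", 1.099, 0.047, 14.760, 2.955),
        "intermediate_invader": frip.EffectSummary(
            "intermediate_invader", 0.469, 0.063, 83.280, 15.710
        ),
        "native": frip.EffectSummary("native", 0.157, 0.012, 17.378, 4.486),
    }
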