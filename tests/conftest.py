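import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import pnampkit as pk


@pytest.fixture(scope="session")
def two_origin_simulation():
    """A 50-kb chromosome with a strong and a moderate origin, simulated
    once per session at the depth/cell numbers the recovery checks use."""
    cfg = pk.SimConfig(n_cells=2000, depth=200, fork_speed=1000, seed=11)
    origins = [
        pk.OriginSpec(15_000, 0.9, firing_time_mean=10, firing_time_sd=3),
        pk.OriginSpec(35_000, 0.6, firing_time_mean=12, firing_time_sd=3),
    ]
    field = pk.simulate_replication(50_000, origins, cfg)
    counts = pk.simulate_puseq_counts(field, cfg)
    usage = pk.usage_from_counts(
        counts.eps_watson, counts.eps_crick,
        counts.delta_watson, counts.delta_crick,
        counts.control_watson, counts.control_crick,
    )
    return {"cfg": cfg, "origins": origins, "field": field,
            "counts": counts, "usage": usage}


@pytest.fixture(scope="session")
def tandem_read_parts():
    """Random unit and flanks shared by the duplication-detection tests."""
    rng = np.random.default_rng(2024)
    return {
        "unit": pk.random_sequence(1500, rng),
        "flank_left": pk.random_sequence(2500, rng),
        "flank_right": pk.random_sequence(2500, rng),
    }
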