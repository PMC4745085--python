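import numpy as np
import pytest

import conscan as cs


@pytest.fixture(scope="session")
def xbox_pwm() -> cs.PWM:
    """The package's 14-column X-box-like demonstration matrix."""
    return cs.xbox_demo_pwm()


@pytest.fixture(scope="session")
def toy_pwm() -> cs.PWM:
    """Small asymmetric 4-column matrix with hand-checkable log-odds."""
    counts = np.array(
        [
            [8, 0, 2, 1],
            [1, 6, 2, 1],
            [0, 1, 4, 1],
            [1, 1, 0, 5],
        ],
        dtype=float,
    )
    return cs.PWM(counts, name="toy", pseudocount=0.25)


@pytest.fixture(scope="session")
def small_sim_config() -> cs.SimulationConfig:
    """A fast simulation: short promoters, few genes, all defaults otherwise."""
    return cs.SimulationConfig(
        seed=11,
        n_genes=16,
        n_targets=5,
        promoter_upstream_bp=1500,
        promoter_downstream_bp=1000,
        conserved_total_bp=1000,
        n_conserved_blocks=2,
        negative_control_total_bp=60_000,
    )


@pytest.fixture(scope="session")
def small_pair(small_sim_config, xbox_pwm):
    return cs.simulate_genome_pair(small_sim_config, xbox_pwm)
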