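import pytest

from huddlesim import SimulationConfig, run_both_conditions, run_development


@pytest.fixture(scope="session")
def dev_runs():
    """Paired default developmental runs: (control, learning), 10 replicates.

    The paired conditions share per-replicate seeding, matching how the
    divergence of the two traces is assessed.
    """
    return run_both_conditions(seed=1, replicates=10)


@pytest.fixture(scope="session")
def high_rate_learning():
    """Learning run at a high encounter rate (20000 encounters/day).

    At this rate the closed loop between behaviour and learning amplifies
    early differences into strongly positive and negative associations.
    """
    cfg = SimulationConfig(
        condition="learning", iters_per_day=20000, replicates=10, seed=1
    )
    return run_development(cfg)
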