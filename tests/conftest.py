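import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fatiguelag import synthetic as syn


@pytest.fixture(scope="session")
def exp1_small():
    """A small Experiment-1 dataset (4 participants, 3 blocks) with truth."""
    cfg = syn.experiment1_config(n_participants=4, blocks=3, seed=42)
    cohort, truth = syn.make_cohort(cfg, seed=42)
    trials = syn.build_dataset(cfg, cohort, truth, seed=42)
    return cfg, cohort, truth, trials


@pytest.fixture(scope="session")
def exp1_full():
    """Experiment-1 at study scale (14 participants, 15 blocks)."""
    cfg = syn.experiment1_config(n_participants=14, blocks=15, seed=7)
    cohort, truth = syn.make_cohort(cfg, seed=7)
    trials = syn.build_dataset(cfg, cohort, truth, seed=7)
    return cfg, cohort, truth, trials


@pytest.fixture(scope="session")
def exp2_small():
    cfg = syn.experiment2_config(n_participants=4, blocks=3, seed=42)
    cohort, truth = syn.make_cohort(cfg, seed=42)
    trials = syn.build_dataset(cfg, cohort, truth, seed=42)
    return cfg, cohort, truth, trials
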