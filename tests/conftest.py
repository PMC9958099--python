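import numpy as np
import pytest

from turntap.cli import analyze_dataset, config_for_study
from turntap.simulate import simulate_experiment
from turntap.types import TapEvent, Trial, TrialMeta


@pytest.fixture(scope="session")
def study1_dataset():
    """A full synthetic study-1 experiment (A-B turn taking, split
    predictability), shared read-only across tests."""
    cfg = config_for_study("study1", seed=11)
    dataset, manifest = simulate_experiment(cfg)
    return dataset, manifest


@pytest.fixture(scope="session")
def study1_analysis(study1_dataset):
    dataset, _ = study1_dataset
    return analyze_dataset(dataset, between="predictability")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_joint_trial(performers: list[str], pair_id: str = "pair01",
                     turn_pattern: str = "AB", block: int = 1,
                     trial_index: int = 1, start_ms: float = 0.0,
                     iti_ms: float = 500.0, starting_performer: str = "A",
                     flagged_online: bool = False) -> Trial:
    """Joint trial with an explicit performer sequence and constant ITIs."""
    meta = TrialMeta(pair_id=pair_id, subject_id=None, task="Joint",
                     block=block, trial_index=trial_index,
                     predictability="Random", turn_pattern=turn_pattern,
                     starting_performer=starting_performer,
                     flagged_online=flagged_online)
    events = [TapEvent(time_ms=start_ms + k * iti_ms, pitch=60, velocity=80,
                       performer=p) for k, p in enumerate(performers)]
    return Trial(meta=meta, events=events)
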