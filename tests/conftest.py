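"""Shared fixtures: small synthetic trials and the trained end-to-end detector.

The end-to-end detector (20 healthy subjects x 8 trials, participant-level
80/20 split) is expensive to train, so it is built once per session and
shared by every test that needs a calibrated model.
"""

from __future__ import annotations

import numpy as np
import pytest

import dystonia_screen as ds


@pytest.fixture(scope="session")
def task4() -> ds.TaskSpec:
    """The arpeggio-with-black-keys task (the best-separating task class)."""
    return ds.TASKS[4]


@pytest.fixture(scope="session")
def healthy_trial(task4):
    return ds.gen_healthy_trial(task4, seed=101, subject_id="H00")


@pytest.fixture(scope="session")
def healthy_tensor(healthy_trial):
    return ds.trial_to_tensor(*healthy_trial)


@pytest.fixture(scope="session")
def healthy_cohort_tensors(task4):
    """20 healthy subjects x 8 trials of the arpeggio task, tensorized."""
    trials = ds.gen_kinematic_cohort(task4, n_subjects=20, trials_per_subject=8,
                                     seed=11)
    return ds.trials_to_tensors(trials)


@pytest.fixture(scope="session")
def trained_detector(healthy_cohort_tensors):
    """Per-task detector trained once for the whole session (minutes of CPU)."""
    artifact, validation = ds.fit_task_detector(
        healthy_cohort_tensors, split_seed=0, init_seed=0, task_id=4)
    return artifact, validation


@pytest.fixture(scope="session")
def md_cohort_tensors(task4):
    """16 dystonic subjects x 8 trials at severity 0.8 (clinical pattern mix)."""
    trials = ds.gen_kinematic_cohort(task4, n_subjects=16, trials_per_subject=8,
                                     group="md", severity=0.8, seed=77)
    return ds.trials_to_tensors(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
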