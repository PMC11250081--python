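"""Convenience wrappers chaining the per-module operations.

These helpers express the canonical path from raw trial files to the
detector's fixed-shape sample: validate the triple, delimit the trial window
from the key kinematics, cut the landmark segment, and time-normalize it to
the 21 x 3 x 128 tensor.
"""

from __future__ import annotations

from .io import KeyTrace, LandmarkTrajectory, TrialMeta, validate_trial
from .preprocessing import (
    PRESS_THRESHOLD_MM,
    RELEASE_THRESHOLD_MM,
    TrialTensor,
    detect_trial_window,
    extract_segment,
    time_normalize,
)


def trial_to_tensor(
    traj: LandmarkTrajectory,
    keys: KeyTrace,
    meta: TrialMeta,
    press_threshold_mm: float = PRESS_THRESHOLD_MM,
    release_threshold_mm: float = RELEASE_THRESHOLD_MM,
    mirror_left: bool = True,
) -> TrialTensor:
    """Raw trial triple -> validated, windowed, time-normalized trial tensor."""
    trial = validate_trial(traj, keys, meta)
    window = detect_trial_window(trial.keys, press_threshold_mm, release_threshold_mm)
    segment = extract_segment(trial.trajectory, window)
    return time_normalize(segment, meta=trial.meta, mirror_left=mirror_left)


def trials_to_tensors(trials, **kwargs) -> list[TrialTensor]:
    """Map :func:`trial_to_tensor` over (trajectory, keys, meta) triples."""
    return [trial_to_tensor(traj, keys, meta, **kwargs)
            for traj, keys, meta in trials]


def save_tensor(tensor: TrialTensor, path) -> None:
    """Persist a trial tensor (npz container; exact binary round-trip)."""
    import json

    import numpy as np

    meta_json = "" if tensor.meta is None else json.dumps(tensor.meta.model_dump())
    np.savez(path, values=tensor.values, meta=np.array(meta_json))


def load_tensor(path) -> TrialTensor:
    import json

    import numpy as np

    with np.load(path) as payload:
        values = payload["values"]
        meta_json = str(payload["meta"])
    meta = TrialMeta(**json.loads(meta_json)) if meta_json else None
    return TrialTensor(values=values, meta=meta)
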