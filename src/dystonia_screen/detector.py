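"""One-class anomaly detection over trial tensors.

The screening logic: train the convolutional autoencoder on healthy pianists'
trial tensors only, measure the mean-squared reconstruction error on a
held-out healthy validation set, and flag any trial whose error strictly
exceeds ``mean + 2 SD`` of the validation errors as abnormal.  Healthy
participants are split 80/20 at the participant level (no participant's
trials appear on both sides), one detector is calibrated per pianistic task,
and sensitivity/specificity are the fractions of patient trials flagged
abnormal and healthy trials passed as normal.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import (
    EmptyGroup,
    TooFewErrors,
    TooFewParticipants,
)
from .nn import AutoencoderConfig, ConvAutoencoder
from .preprocessing import TrialTensor, augment_batch

TRAIN_FRACTION = 0.8
THRESHOLD_SDS = 2.0


@dataclasses.dataclass(frozen=True)
class CalibrationRecord:
    """Validation-error statistics and the derived anomaly threshold.

    ``threshold`` is exactly ``mean_err + 2 * sd_err`` (sample SD, n-1
    denominator).  Seeds for the participant split, weight initialization and
    augmentation are logged so the artifact is reproducible.
    """

    mean_err: float
    sd_err: float
    threshold: float
    n_validation: int
    split_seed: int = 0
    init_seed: int = 0
    augment_seed: int = 0
    train_fraction: float = TRAIN_FRACTION

    def __post_init__(self):
        expected = self.mean_err + THRESHOLD_SDS * self.sd_err
        if not np.isclose(self.threshold, expected, rtol=0, atol=1e-12 * max(1.0, abs(expected))):
            raise ValueError("threshold must equal mean_err + 2*sd_err")


@dataclasses.dataclass
class TrainedModel:
    """A fitted autoencoder plus its training loss history."""

    network: ConvAutoencoder
    loss_history: list[float]

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


@dataclasses.dataclass
class DetectorArtifact:
    """Trained model + calibration; the deployable unit for one task."""

    model: TrainedModel
    calibration: CalibrationRecord
    task_id: int | None = None


# ---------------------------------------------------------------------------
# splitting, training, calibration
# ---------------------------------------------------------------------------

def split_by_participant(
    tensors: list[TrialTensor],
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[list[TrialTensor], list[TrialTensor]]:
    """Split at the participant level: no subject appears in both sets."""
    subjects = sorted({t.meta.subject_id for t in tensors})
    if len(subjects) < 2:
        raise TooFewParticipants(f"need >= 2 participants, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_train = int(round(train_fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train_ids = set(order[:n_train])
    train = [t for t in tensors if t.meta.subject_id in train_ids]
    validation = [t for t in tensors if t.meta.subject_id not in train_ids]
    return train, validation


def _to_array(tensors: list[TrialTensor]) -> np.ndarray:
    # network layout: coordinates as channels over the (landmark, time) grid
    return np.stack([t.values.transpose(1, 0, 2) for t in tensors]).astype(np.float32)


def train_autoencoder(
    train: list[TrialTensor],
    config: AutoencoderConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the autoencoder on training tensors until the MSE converges."""
    if not train:
        raise ValueError("empty training set")
    net = ConvAutoencoder(config=config, seed=seed)
    history = net.fit(_to_array(train), seed=seed)
    return TrainedModel(network=net, loss_history=history)


def reconstruction_error(model: TrainedModel, tensor: TrialTensor) -> float:
    """Mean squared error over all 21*3*128 elements of one tensor."""
    x = tensor.values.transpose(1, 0, 2).astype(np.float32)
    out = model.network.reconstruct(x)
    return float(np.mean((out.astype(np.float64) - x) ** 2))


def reconstruction_errors(model: TrainedModel, tensors: list[TrialTensor]) -> np.ndarray:
    """Vectorized reconstruction error for a list of tensors."""
    if not tensors:
        return np.empty(0)
    x = _to_array(tensors)
    out = model.network.reconstruct(x)
    return np.mean((out.astype(np.float64) - x) ** 2, axis=(1, 2, 3))


def calibrate_threshold(validation_errors, **seeds) -> CalibrationRecord:
    """Set the anomaly threshold at mean + 2 sample SDs of validation errors."""
    errors = np.asarray(list(validation_errors), dtype=float)
    if errors.size < 2:
        raise TooFewErrors(f"need >= 2 validation errors, got {errors.size}")
    mean = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1))
    return CalibrationRecord(
        mean_err=mean, sd_err=sd, threshold=mean + THRESHOLD_SDS * sd,
        n_validation=int(errors.size), **seeds,
    )


def classify(error: float, record: CalibrationRecord) -> str:
    """'abnormal' iff the error strictly exceeds the threshold."""
    return "abnormal" if error > record.threshold else "normal"


# ---------------------------------------------------------------------------
# end-to-end convenience + evaluation
# ---------------------------------------------------------------------------

def fit_task_detector(
    healthy_tensors: list[TrialTensor],
    config: AutoencoderConfig | None = None,
    split_seed: int = 0,
    init_seed: int = 0,
    augment_seed: int = 0,
    n_augment: int = 2,
    task_id: int | None = None,
) -> tuple[DetectorArtifact, list[TrialTensor]]:
    """Train and calibrate a per-task detector from healthy tensors only.

    Rotation/scale augmentation (``n_augment`` copies per training tensor,
    emulating camera-mounting deviations) is part of the training protocol:
    besides robustness to mounting it markedly improves reconstruction of
    *unseen* participants, which tightens the validation-error spread the
    threshold is built from.  Augmented copies are generated from
    training-set participants only, and validation errors are computed on
    unaugmented tensors, so no information leaks from validation
    participants into training.  Returns the artifact and the held-out
    validation tensors.
    """
    train, validation = split_by_participant(healthy_tensors, seed=split_seed)
    if n_augment > 0:
        train = augment_batch(train, n_per_tensor=n_augment, seed=augment_seed)
    model = train_autoencoder(train, config=config, seed=init_seed)
    errors = reconstruction_errors(model, validation)
    record = calibrate_threshold(
        errors, split_seed=split_seed, init_seed=init_seed, augment_seed=augment_seed,
    )
    return DetectorArtifact(model=model, calibration=record, task_id=task_id), validation


@dataclasses.dataclass
class TaskEvaluation:
    """Confusion counts and rates for one task."""

    task_id: int
    tp: int  # patient trials flagged abnormal
    fn: int
    tn: int  # healthy trials passed as normal
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def chance_flag(self) -> bool:
        """True when sensitivity does not beat the 50% chance level."""
        return self.sensitivity <= 0.5


@dataclasses.dataclass
class EvalReport:
    """Per-task sensitivity/specificity table."""

    tasks: dict[int, TaskEvaluation]

    def to_dict(self) -> dict:
        return {
            str(task_id): {
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "tp": ev.tp, "fn": ev.fn, "tn": ev.tn, "fp": ev.fp,
                "chance_flag": ev.chance_flag,
            }
            for task_id, ev in sorted(self.tasks.items())
        }


def evaluate(predictions: list[tuple[int, str, str]]) -> EvalReport:
    """Aggregate (task_id, group, label) classifications into per-task rates.

    ``group`` is 'healthy' or 'md'; ``label`` is 'normal' or 'abnormal'.
    Sensitivity is the proportion of patient trials flagged abnormal,
    specificity the proportion of healthy trials passed as normal.
    """
    by_task: dict[int, dict[str, int]] = {}
    for task_id, group, label in predictions:
        counts = by_task.setdefault(task_id, {"tp": 0, "fn": 0, "tn": 0, "fp": 0})
        if group == "md":
            counts["tp" if label == "abnormal" else "fn"] += 1
        elif group == "healthy":
            counts["tn" if label == "normal" else "fp"] += 1
        else:
            raise ValueError(f"unknown group {group!r}")
    report: dict[int, TaskEvaluation] = {}
    for task_id, c in by_task.items():
        if c["tp"] + c["fn"] == 0 or c["tn"] + c["fp"] == 0:
            raise EmptyGroup(f"task {task_id} needs >= 1 healthy and >= 1 patient trial")
        report[task_id] = TaskEvaluation(task_id=task_id, **c)
    return EvalReport(tasks=report)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_artifact(artifact: DetectorArtifact, directory) -> None:
    """Write weights (npz) plus a diffable calibration.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **artifact.model.network.get_weights())
    payload = {
        "calibration": dataclasses.asdict(artifact.calibration),
        "config": artifact.model.network.config.to_dict(),
        "task_id": artifact.task_id,
        "loss_history": [float(v) for v in artifact.model.loss_history],
    }
    with open(directory / "calibration.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_artifact(directory) -> DetectorArtifact:
    directory = Path(directory)
    with open(directory / "calibration.json", "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    config = AutoencoderConfig.from_dict(payload["config"])
    net = ConvAutoencoder(config=config, seed=0)
    with np.load(directory / "weights.npz") as weights:
        net.set_weights(dict(weights))
    model = TrainedModel(network=net, loss_history=payload["loss_history"])
    record = CalibrationRecord(**payload["calibration"])
    return DetectorArtifact(model=model, calibration=record, task_id=payload["task_id"])
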