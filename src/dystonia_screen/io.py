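"""Readers, writers and validation for the trial file dialects.

Three files make up one recorded trial:

* a long-format landmark CSV (``frame,time_s,landmark_id,x,y,z``) holding the
  21-point hand pose per video frame, as emitted by MediaPipe-style hand
  tracking at a nominal 60 Hz;
* a wide key-trace CSV (``time_ms,k00..k87``) holding the vertical displacement
  of all 88 piano keys in mm on a uniform 1 ms grid, quantized at 0.01 mm;
* a JSON metadata record (subject, group, hand, task, tempo, loudness).

All dialects carry a schema comment line ``#dystonia-screen v1`` and round-trip
losslessly at the stated quantization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .errors import (
    MalformedRow,
    MissingLandmark,
    NegativeDisplacement,
    NonMonotoneTime,
    NonUniformSampling,
    NoTemporalOverlap,
    TaskTempoMismatch,
)
from .landmarks import N_COORDS, N_LANDMARKS

SCHEMA_COMMENT = "#dystonia-screen v1"

N_KEYS = 88
#: 0-based key index of middle C (C4) on the 88-key range A0..C8
KEY_C4 = 39
KEY_SAMPLE_MS = 1
DISPLACEMENT_QUANTUM_MM = 0.01

#: fixed-tempo rule: single-note sequences (tasks 1-6) at 100 bpm,
#: chord-striking sequences (tasks 7-11) at 80 bpm
SINGLE_NOTE_TASKS = frozenset(range(1, 7))
CHORD_TASKS = frozenset(range(7, 12))


def fixed_tempo_for_task(task_id: int) -> float:
    """Nominal fixed tempo in bpm for a task (100 single-note, 80 chord)."""
    return 100.0 if task_id in SINGLE_NOTE_TASKS else 80.0


Hand = Literal["left", "right"]


class TrialMeta(BaseModel):
    """Metadata attached to one recorded trial."""

    subject_id: str
    group: Literal["healthy", "md"]
    hand: Hand
    affected_hand: Literal["left", "right", "none"] = "none"
    task_id: int = Field(ge=1, le=11)
    tempo_bpm: Union[float, Literal["fastest"]]
    loudness: Literal["pp", "ff"] = "ff"

    @field_validator("tempo_bpm")
    @classmethod
    def _positive_tempo(cls, v):
        if v != "fastest" and v <= 0:
            raise ValueError("tempo_bpm must be positive or 'fastest'")
        return v

    @property
    def is_fixed_tempo(self) -> bool:
        return self.tempo_bpm != "fastest"


@dataclasses.dataclass
class LandmarkTrajectory:
    """Per-frame 21-landmark 3-D hand pose.

    ``values`` has shape ``(n_frames, 21, 3)`` with x, y in normalized image
    coordinates ([0, 1] of image width/height) and z a unitless relative
    depth.  ``timestamps`` are seconds, strictly increasing.
    """

    values: np.ndarray
    timestamps: np.ndarray
    fps: float = 60.0
    hand_label: Hand = "right"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_LANDMARKS, N_COORDS):
            raise MissingLandmark(
                f"expected (n, {N_LANDMARKS}, {N_COORDS}) landmark array, "
                f"got {self.values.shape}"
            )
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise MalformedRow("frame count and timestamp count differ")
        if np.any(~np.isfinite(self.values)):
            raise MalformedRow("non-finite landmark coordinate")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise NonMonotoneTime("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def t_start(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])


@dataclasses.dataclass
class KeyTrace:
    """Vertical displacement of the 88 piano keys on a uniform 1 ms grid.

    ``displacement`` has shape ``(n_samples, 88)``, in mm, >= 0, key index 0
    mapping A0 and 87 mapping C8.
    """

    time_ms: np.ndarray
    displacement: np.ndarray

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=np.int64)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 2 or self.displacement.shape[1] != N_KEYS:
            raise MalformedRow(
                f"expected (n, {N_KEYS}) displacement array, got {self.displacement.shape}"
            )
        if self.time_ms.shape[0] != self.displacement.shape[0]:
            raise MalformedRow("time and displacement row counts differ")
        if len(self.time_ms) > 1 and np.any(np.diff(self.time_ms) != KEY_SAMPLE_MS):
            raise NonUniformSampling("key trace must be sampled on a uniform 1 ms grid")
        if np.any(self.displacement < 0):
            raise NegativeDisplacement("key displacement below zero")

    def __len__(self) -> int:
        return self.time_ms.shape[0]

    @property
    def t_start(self) -> float:
        """Start of the trace in seconds."""
        return float(self.time_ms[0]) / 1000.0

    @property
    def t_end(self) -> float:
        return float(self.time_ms[-1]) / 1000.0


@dataclasses.dataclass
class ValidatedTrial:
    """A trajectory/key-trace/metadata triple that passed cross-validation."""

    trajectory: LandmarkTrajectory
    keys: KeyTrace
    meta: TrialMeta


# ---------------------------------------------------------------------------
# landmark CSV (long format)
# ---------------------------------------------------------------------------

def read_landmark_csv(path) -> LandmarkTrajectory:
    """Read a long-format landmark CSV into a validated trajectory.

    Raises :class:`MissingLandmark` if any frame lacks one of ids 0-20,
    :class:`NonMonotoneTime` for non-increasing frame times, and
    :class:`MalformedRow` for rows that do not parse.
    """
    path = Path(path)
    hand_label, fps = _parse_header_comment(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedRow(f"cannot parse {path}: {exc}") from exc
    required = ["frame", "time_s", "landmark_id", "x", "y", "z"]
    if list(df.columns) != required:
        raise MalformedRow(f"expected columns {required}, got {list(df.columns)}")
    for col in required:
        if not np.issubdtype(df[col].dtype, np.number):
            raise MalformedRow(f"non-numeric values in column {col!r}")
    if df[required].isna().any().any():
        raise MalformedRow("missing values in landmark CSV")

    df = df.sort_values(["frame", "landmark_id"], kind="stable")
    frames = df["frame"].to_numpy()
    unique_frames, counts = np.unique(frames, return_counts=True)
    if np.any(counts != N_LANDMARKS):
        bad = unique_frames[counts != N_LANDMARKS][0]
        raise MissingLandmark(f"frame {int(bad)} does not have all {N_LANDMARKS} landmarks")
    ids = df["landmark_id"].to_numpy().reshape(-1, N_LANDMARKS)
    if np.any(ids != np.arange(N_LANDMARKS)):
        bad_row = int(np.argwhere(ids != np.arange(N_LANDMARKS))[0][0])
        raise MissingLandmark(
            f"frame {int(unique_frames[bad_row])} landmark ids are not exactly 0..20"
        )

    values = df[["x", "y", "z"]].to_numpy().reshape(-1, N_LANDMARKS, N_COORDS)
    timestamps = df["time_s"].to_numpy().reshape(-1, N_LANDMARKS)[:, 0]
    return LandmarkTrajectory(values=values, timestamps=timestamps,
                              fps=fps, hand_label=hand_label)


def write_landmark_csv(traj: LandmarkTrajectory, path) -> None:
    """Write a trajectory in the long-format dialect (lossless round-trip)."""
    path = Path(path)
    n = len(traj)
    frame = np.repeat(np.arange(n), N_LANDMARKS)
    time_s = np.repeat(traj.timestamps, N_LANDMARKS)
    lm = np.tile(np.arange(N_LANDMARKS), n)
    flat = traj.values.reshape(-1, N_COORDS)
    df = pd.DataFrame({
        "frame": frame, "time_s": time_s, "landmark_id": lm,
        "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2],
    })
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_COMMENT} hand={traj.hand_label} fps={traj.fps:g}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header_comment(path: Path) -> tuple[Hand, float]:
    hand: Hand = "right"
    fps = 60.0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        for token in first.split()[1:]:
            if token.startswith("hand="):
                value = token[5:]
                if value not in ("left", "right"):
                    raise MalformedRow(f"bad hand label {value!r}")
                hand = value  # type: ignore[assignment]
            elif token.startswith("fps="):
                fps = float(token[4:])
    return hand, fps


# ---------------------------------------------------------------------------
# key-trace CSV (wide format)
# ---------------------------------------------------------------------------

KEY_COLUMNS = [f"k{i:02d}" for i in range(N_KEYS)]


def read_keytrace_csv(path) -> KeyTrace:
    """Read a wide key-trace CSV; verifies the uniform 1 ms grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise MalformedRow(f"cannot parse {path}: {exc}") from exc
    required = ["time_ms"] + KEY_COLUMNS
    if list(df.columns) != required:
        raise MalformedRow("key-trace header must be time_ms,k00..k87")
    if df.isna().any().any():
        raise MalformedRow("missing values in key-trace CSV")
    return KeyTrace(time_ms=df["time_ms"].to_numpy(),
                    displacement=df[KEY_COLUMNS].to_numpy())


def write_keytrace_csv(trace: KeyTrace, path) -> None:
    """Write a key trace at the 0.01 mm quantization (bit-exact round-trip)."""
    df = pd.DataFrame(trace.displacement, columns=KEY_COLUMNS)
    df.insert(0, "time_ms", trace.time_ms)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_COMMENT}\n")
        df.to_csv(fh, index=False, float_format="%.2f")


# ---------------------------------------------------------------------------
# trial metadata JSON
# ---------------------------------------------------------------------------

def read_trial_meta(path) -> TrialMeta:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    payload.pop("schema", None)
    return TrialMeta(**payload)


def write_trial_meta(meta: TrialMeta, path) -> None:
    payload = {"schema": SCHEMA_COMMENT.lstrip("#")}
    payload.update(meta.model_dump())
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# cross-file validation
# ---------------------------------------------------------------------------

def validate_trial(traj: LandmarkTrajectory, keys: KeyTrace, meta: TrialMeta) -> ValidatedTrial:
    """Check that the three files of one trial are mutually consistent.

    Asserts temporal overlap between trajectory and key trace, and — for
    fixed-tempo trials — the 100 bpm (tasks 1-6) / 80 bpm (tasks 7-11) rule.
    """
    if traj.t_end < keys.t_start or keys.t_end < traj.t_start:
        raise NoTemporalOverlap(
            f"trajectory [{traj.t_start:.3f}, {traj.t_end:.3f}] s does not overlap "
            f"key trace [{keys.t_start:.3f}, {keys.t_end:.3f}] s"
        )
    if meta.is_fixed_tempo:
        expected = fixed_tempo_for_task(meta.task_id)
        if float(meta.tempo_bpm) != expected:
            raise TaskTempoMismatch(
                f"task {meta.task_id} fixed tempo must be {expected:g} bpm, "
                f"got {meta.tempo_bpm}"
            )
    return ValidatedTrial(trajectory=traj, keys=keys, meta=meta)
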