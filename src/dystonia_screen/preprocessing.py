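"""Trial windowing, time normalization, tensor assembly and augmentation.

The pipeline turns a raw trial into the fixed-shape sample the anomaly
detector consumes:

1. :func:`detect_trial_window` finds the span from the first keystroke onset
   to the last keystroke offset in the key-displacement trace (hysteresis
   thresholds, defaults 0.5 / 0.3 mm);
2. :func:`extract_segment` keeps the video frames inside that closed window;
3. :func:`time_normalize` resamples each of the 63 landmark-coordinate
   channels by cubic spline onto 128 uniformly spaced samples, yielding a
   21 x 3 x 128 trial tensor;
4. :func:`augment` / :func:`augment_batch` apply in-plane rotation and
   anisotropic scaling about the image center to emulate camera-mounting
   deviations.

Left-hand trajectories are mirrored (x -> 1 - x) before tensorization so a
single model serves both hands; pass ``mirror_left=False`` to disable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    InvalidScale,
    NoKeystrokeDetected,
    SegmentTooShort,
    ShapeMismatch,
)
from .io import KeyTrace, LandmarkTrajectory, TrialMeta
from .landmarks import N_COORDS, N_LANDMARKS

N_TIME_SAMPLES = 128
PRESS_THRESHOLD_MM = 0.5
RELEASE_THRESHOLD_MM = 0.3
MIN_SEGMENT_FRAMES = 4

IMAGE_CENTER = (0.5, 0.5)


@dataclasses.dataclass(frozen=True)
class TrialWindow:
    """Trial span in seconds: first keystroke onset to last keystroke offset."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("window requires t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclasses.dataclass
class TrialTensor:
    """Fixed-shape kinematic sample: 21 landmarks x 3 coordinates x 128 samples."""

    values: np.ndarray
    meta: TrialMeta | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_LANDMARKS, N_COORDS, N_TIME_SAMPLES):
            raise ShapeMismatch(
                f"trial tensor must be {(N_LANDMARKS, N_COORDS, N_TIME_SAMPLES)}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ShapeMismatch("trial tensor contains non-finite values")


@dataclasses.dataclass(frozen=True)
class AugmentParams:
    """In-image-plane rotation (degrees) and anisotropic scaling about the center."""

    rotation_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise InvalidScale("scale factors must be > 0")


def detect_trial_window(
    keys: KeyTrace,
    press_threshold_mm: float = PRESS_THRESHOLD_MM,
    release_threshold_mm: float = RELEASE_THRESHOLD_MM,
) -> TrialWindow:
    """Delimit the trial from the key kinematics.

    ``t_start`` is the first time any key's displacement rises through the
    press threshold; ``t_end`` the last time any key falls through the release
    threshold.  The release threshold must sit below the press threshold
    (hysteresis) so chatter at one level cannot extend the window.
    """
    if not release_threshold_mm < press_threshold_mm:
        raise ValueError("release threshold must be below press threshold")
    envelope = keys.displacement.max(axis=1)
    above_press = envelope >= press_threshold_mm
    if not np.any(above_press):
        raise NoKeystrokeDetected(
            f"no key displacement reaches {press_threshold_mm} mm"
        )
    i_on = int(np.argmax(above_press))
    above_release = envelope >= release_threshold_mm
    i_off = int(len(envelope) - 1 - np.argmax(above_release[::-1]))
    t = keys.time_ms / 1000.0
    return TrialWindow(t_start=float(t[i_on]), t_end=float(t[i_off]))


def extract_segment(traj: LandmarkTrajectory, window: TrialWindow) -> LandmarkTrajectory:
    """Keep frames whose timestamp lies in the closed window [t_start, t_end]."""
    mask = (traj.timestamps >= window.t_start) & (traj.timestamps <= window.t_end)
    n = int(mask.sum())
    if n < MIN_SEGMENT_FRAMES:
        raise SegmentTooShort(
            f"only {n} frames in [{window.t_start:.3f}, {window.t_end:.3f}] s; "
            f"need >= {MIN_SEGMENT_FRAMES}"
        )
    return LandmarkTrajectory(
        values=traj.values[mask],
        timestamps=traj.timestamps[mask],
        fps=traj.fps,
        hand_label=traj.hand_label,
    )


def mirror_x(traj: LandmarkTrajectory) -> LandmarkTrajectory:
    """Reflect the trajectory left-right in the image (x -> 1 - x)."""
    values = traj.values.copy()
    values[:, :, 0] = 1.0 - values[:, :, 0]
    return LandmarkTrajectory(values=values, timestamps=traj.timestamps.copy(),
                              fps=traj.fps, hand_label=traj.hand_label)


def time_normalize(
    traj: LandmarkTrajectory,
    n_samples: int = N_TIME_SAMPLES,
    meta: TrialMeta | None = None,
    mirror_left: bool = True,
) -> TrialTensor:
    """Resample each landmark-coordinate channel to ``n_samples`` points.

    Each of the 63 channels is interpolated independently with a natural cubic
    spline over the frame timestamps and evaluated on ``n_samples`` uniformly
    spaced times spanning [first, last] timestamp inclusive, so endpoint
    values are preserved exactly and an already-uniform 128-frame input is
    reproduced sample-for-sample.
    """
    if len(traj) < MIN_SEGMENT_FRAMES:
        raise SegmentTooShort(f"{len(traj)} frames; need >= {MIN_SEGMENT_FRAMES}")
    if mirror_left and traj.hand_label == "left":
        traj = mirror_x(traj)
    t = traj.timestamps
    grid = np.linspace(t[0], t[-1], n_samples)
    # one spline call over all 63 channels: CubicSpline accepts 2-D ordinates
    flat = traj.values.reshape(len(traj), N_LANDMARKS * N_COORDS)
    spline = CubicSpline(t, flat, bc_type="natural")
    resampled = spline(grid)  # (n_samples, 63)
    values = resampled.T.reshape(N_LANDMARKS, N_COORDS, n_samples)
    if n_samples == N_TIME_SAMPLES:
        return TrialTensor(values=values, meta=meta)
    tensor = TrialTensor.__new__(TrialTensor)  # non-128 sizes for diagnostics
    tensor.values, tensor.meta = values, meta
    return tensor


def augment(tensor: TrialTensor, params: AugmentParams) -> TrialTensor:
    """Rotate then scale the (x, y) channels about the image center (0.5, 0.5).

    The z (relative depth) channel is untouched; rotation with unit scales is
    an in-plane isometry, so inter-landmark image distances are preserved.
    """
    cx, cy = IMAGE_CENTER
    theta = np.deg2rad(params.rotation_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    values = tensor.values.copy()
    x = values[:, 0, :] - cx
    y = values[:, 1, :] - cy
    xr = cos_t * x - sin_t * y
    yr = sin_t * x + cos_t * y
    values[:, 0, :] = cx + params.scale_x * xr
    values[:, 1, :] = cy + params.scale_y * yr
    return TrialTensor(values=values, meta=tensor.meta)


def augment_batch(
    tensors: list[TrialTensor],
    n_per_tensor: int,
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0),
    scale_range: tuple[float, float] = (0.9, 1.1),
    seed: int = 0,
) -> list[TrialTensor]:
    """Emit each input plus ``n_per_tensor`` randomly augmented copies.

    Rotation and the two scale factors are drawn independently and uniformly
    from their ranges; the output order and values are deterministic given the
    seed.
    """
    if n_per_tensor < 0:
        raise ValueError("n_per_tensor must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[TrialTensor] = []
    for tensor in tensors:
        out.append(tensor)
        for _ in range(n_per_tensor):
            params = AugmentParams(
                rotation_deg=float(rng.uniform(*rotation_range_deg)),
                scale_x=float(rng.uniform(*scale_range)),
                scale_y=float(rng.uniform(*scale_range)),
            )
            out.append(augment(tensor, params))
    return out
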