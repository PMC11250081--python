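"""Synthetic trial, cohort and observer generators.

Every downstream module is exercisable without recorded data: this module
emits keystroke-locked hand kinematics with the recording geometry of the
study setup (60 Hz video of a hand over an 88-key keyboard with C4 centred,
1 kHz / 0.01 mm key displacement), biomechanical score cohorts, and
psychophysical observers.

The kinematic template is a schematic articulated hand — a wrist anchor with
five finger chains whose assigned fingertip dips toward the key plane in
synchrony with each key excursion, the whole hand translating along the
keyboard with the note sequence — not a biomechanically exact hand.  The
dystonic perturbation follows the clinical picture of focal hand dystonia in
pianists (sustained flexion of affected fingers toward the keys, reduced
lift, timing irregularity, co-movement of adjacent fingers) and is
continuous in a severity parameter: severity 0 reproduces the healthy trial
exactly.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm as _normal

from .io import (
    KEY_C4,
    KeyTrace,
    LandmarkTrajectory,
    N_KEYS,
    TrialMeta,
    fixed_tempo_for_task,
)
from .landmarks import FINGER_CHAINS, FINGERS, N_COORDS, N_LANDMARKS, WRIST

# ---------------------------------------------------------------------------
# task catalogue
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TaskSpec:
    """One pianistic task: an event sequence of keys with nominal fingering.

    ``events`` is a tuple of (key_indices, fingers) pairs; single-note tasks
    have one key per event, chord tasks several.  ``subdivision`` is events
    per beat at the nominal tempo.  Fingers are 0 (thumb) .. 4 (little), for
    the right hand; the left hand uses mirror-image fingering.
    """

    task_id: int
    name: str
    category: str  # "single" | "chord"
    events: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    subdivision: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def fixed_tempo_bpm(self) -> float:
        return fixed_tempo_for_task(self.task_id)


def _seq(semitones, fingers):
    return tuple(((KEY_C4 + s,), (f,)) for s, f in zip(semitones, fingers))


def _chords(chords, fingers):
    return tuple(
        (tuple(KEY_C4 + s for s in chord), tuple(fingers))
        for chord in chords
    )


# Exemplar note sequences per task category (scale, arpeggio, arpeggio with
# black keys, trill, thirds, repeated chords, octaves); the exact printed
# notes of the study tasks are not published, so these are representative
# sequences of the same categories.
TASKS: dict[int, TaskSpec] = {
    1: TaskSpec(1, "scale", "single", _seq(
        [0, 2, 4, 5, 7, 9, 11, 12, 12, 11, 9, 7, 5, 4, 2, 0],
        [0, 1, 2, 0, 1, 2, 3, 4, 4, 3, 2, 1, 0, 2, 1, 0]), 4),
    2: TaskSpec(2, "scale_black_keys", "single", _seq(
        [4, 6, 8, 9, 11, 13, 15, 16, 16, 15, 13, 11, 9, 8, 6, 4],
        [0, 1, 2, 0, 1, 2, 3, 4, 4, 3, 2, 1, 0, 2, 1, 0]), 4),
    3: TaskSpec(3, "arpeggio", "single", _seq(
        [0, 4, 7, 12, 16, 12, 7, 4, 0, 4, 7, 12, 16, 12, 7, 4],
        [0, 1, 2, 0, 4, 0, 2, 1, 0, 1, 2, 0, 4, 0, 2, 1]), 4),
    4: TaskSpec(4, "arpeggio_black_keys", "single", _seq(
        [6, 10, 13, 18, 22, 18, 13, 10, 6, 10, 13, 18, 22, 18, 13, 10],
        [0, 1, 2, 0, 4, 0, 2, 1, 0, 1, 2, 0, 4, 0, 2, 1]), 4),
    5: TaskSpec(5, "trill", "single", _seq(
        [0, 2] * 8, [1, 2] * 8), 4),
    6: TaskSpec(6, "trill_black_keys", "single", _seq(
        [6, 8] * 8, [1, 2] * 8), 4),
    7: TaskSpec(7, "thirds", "chord", _chords(
        [(0, 4), (2, 5), (4, 7), (5, 9), (7, 11), (5, 9), (4, 7), (2, 5)],
        (1, 3)), 2),
    8: TaskSpec(8, "triad_repeat", "chord", _chords(
        [(0, 4, 7)] * 8, (0, 2, 4)), 2),
    9: TaskSpec(9, "five_note_chord", "chord", _chords(
        [(0, 2, 4, 5, 7)] * 8, (0, 1, 2, 3, 4)), 2),
    10: TaskSpec(10, "broken_octaves", "chord", tuple(
        ((KEY_C4 + s,), (f,)) for s, f in zip([0, 12] * 4, [0, 4] * 4)), 2),
    11: TaskSpec(11, "octaves", "chord", _chords(
        [(0, 12)] * 8, (0, 4)), 2),
}


@dataclasses.dataclass(frozen=True)
class DystoniaPattern:
    """Which fingers express the dystonic perturbation and how strongly.

    ``severity`` in [0, 1] scales the sustained flexion bias toward the key
    plane, the loss of lift of the affected fingertips, the timing jitter of
    their strikes, and the co-movement coupling of adjacent fingers.
    Severity 0 means every perturbation magnitude is zero.
    """

    affected_fingers: tuple[str, ...]
    severity: float = 1.0
    include_wrist: bool = False

    def __post_init__(self):
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        for f in self.affected_fingers:
            if f not in FINGERS:
                raise ValueError(f"unknown finger {f!r}")


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Recording geometry and noise of the simulated setup."""

    fps: float = 60.0
    key_rate_hz: float = 1000.0
    noise_sd: float = 0.003        # normalized image units (~4 px at 1280 width)
    key_depth_mm: float = 10.0
    subject_seed: int = 0          # salt for per-subject templates

    # perturbation magnitudes at severity 1
    flexion_bias: float = 0.030    # sustained fingertip y-offset toward the keys
    lift_loss: float = 0.5         # fractional loss of keystroke dip amplitude
    timing_jitter_s: float = 0.020
    coupling: float = 0.4          # fraction of the dip leaking to neighbours


#: image x per semitone: one octave (~157.5 mm) of the 1620 mm field of view
X_PER_KEY = 0.008
KEY_RISE_S = 0.006
KEY_FALL_S = 0.008

_FINGER_X_OFFSET = {"thumb": -0.040, "index": -0.020, "middle": 0.0,
                    "ring": 0.020, "little": 0.040}
_FINGER_LENGTH = {"thumb": 0.10, "index": 0.19, "middle": 0.21,
                  "ring": 0.19, "little": 0.16}


def key_x(key_index: int) -> float:
    """Normalized image x of a key (C4 centred in the field of view)."""
    return 0.5 + (key_index - KEY_C4) * X_PER_KEY


@dataclasses.dataclass(frozen=True)
class KeystrokeTruth:
    """Ground-truth event timing emitted alongside a generated key trace."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray


# ---------------------------------------------------------------------------
# key traces
# ---------------------------------------------------------------------------

def _event_times(task: TaskSpec, tempo_bpm: float, rng: np.random.Generator,
                 lead_s: float = 0.3):
    ioi = 60.0 / tempo_bpm / task.subdivision
    onsets = lead_s + ioi * np.arange(task.n_events)
    onsets = onsets + rng.normal(0.0, 0.004, size=task.n_events)
    onsets = np.maximum.accumulate(onsets)  # keep event order
    hold = max(0.8 * ioi - KEY_RISE_S - KEY_FALL_S, 0.04)
    return onsets, hold, ioi


def gen_key_trace(task: TaskSpec, tempo_bpm: float | None = None, seed: int = 0,
                  config: GeneratorConfig = GeneratorConfig(),
                  lead_s: float = 0.3) -> tuple[KeyTrace, KeystrokeTruth]:
    """Generate the 88-key displacement trace for one performance.

    One smooth depression/release excursion (~10 mm peak, 6 ms rise, 8 ms
    fall) per note event, at tempo-determined onsets with a few ms of onset
    jitter.  The true onset/offset times are returned alongside, so window
    detection can be validated against ground truth.
    """
    tempo = task.fixed_tempo_bpm if tempo_bpm is None else tempo_bpm
    rng = np.random.default_rng(seed)
    onsets, hold, _ = _event_times(task, tempo, rng, lead_s)
    dur_per_event = KEY_RISE_S + hold + KEY_FALL_S
    offsets = onsets + dur_per_event

    total_s = (offsets[-1] if task.n_events else lead_s) + lead_s
    n = int(np.ceil(total_s * config.key_rate_hz)) + 1
    t = np.arange(n) / config.key_rate_hz
    disp = np.zeros((n, N_KEYS))

    for (keys, _fingers), onset in zip(task.events, onsets):
        depth = config.key_depth_mm * rng.uniform(0.95, 1.0)
        profile = _excursion(t, onset, hold, depth)
        for k in keys:
            disp[:, k] = np.maximum(disp[:, k], profile)

    disp = np.round(disp * 100.0) / 100.0  # sensor quantization, 0.01 mm
    trace = KeyTrace(time_ms=np.arange(n), displacement=disp)
    return trace, KeystrokeTruth(onsets_s=onsets, offsets_s=offsets)


def _excursion(t: np.ndarray, onset: float, hold: float, depth: float) -> np.ndarray:
    """Raised-cosine rise, flat hold, raised-cosine fall."""
    out = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + KEY_RISE_S)
    out[rise] = depth * 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / KEY_RISE_S))
    flat = (t >= onset + KEY_RISE_S) & (t < onset + KEY_RISE_S + hold)
    out[flat] = depth
    fall_start = onset + KEY_RISE_S + hold
    fall = (t >= fall_start) & (t <= fall_start + KEY_FALL_S)
    out[fall] = depth * 0.5 * (1 + np.cos(np.pi * (t[fall] - fall_start) / KEY_FALL_S))
    return out


# ---------------------------------------------------------------------------
# hand kinematics
# ---------------------------------------------------------------------------

def _subject_params(subject_id: str, config: GeneratorConfig) -> dict:
    key = zlib.crc32(subject_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([config.subject_seed, key])
    return {
        "amp_scale": float(np.clip(rng.normal(1.0, 0.12), 0.7, 1.3)),
        "hand_scale": float(np.clip(rng.normal(1.0, 0.08), 0.8, 1.2)),
        "timing_offset": float(rng.normal(0.0, 0.010)),
        "wrist_y": float(rng.normal(0.70, 0.015)),
        "dip_amp": float(np.clip(rng.normal(0.035, 0.005), 0.02, 0.05)),
    }


def _hand_template(params: dict) -> np.ndarray:
    """Static right-hand pose offsets (21, 3) relative to the hand anchor."""
    pose = np.zeros((N_LANDMARKS, N_COORDS))
    scale = params["hand_scale"]
    pose[WRIST] = (0.0, 0.0, 0.0)
    for finger in FINGERS:
        chain = FINGER_CHAINS[finger]
        x_off = _FINGER_X_OFFSET[finger] * scale
        length = _FINGER_LENGTH[finger] * scale
        # proximal->distal fractions of the finger length above the wrist
        for landmark, frac in zip(chain, (0.45, 0.70, 0.88, 1.0)):
            pose[landmark] = (x_off, -frac * length, -0.02 * frac)
    return pose


def _dip_profiles(frame_t, task, onsets, hold, amp, jitter):
    """Per-finger fingertip dip signal on the frame grid (positive = press)."""
    dips = np.zeros((len(FINGERS), len(frame_t)))
    width = KEY_RISE_S + hold + KEY_FALL_S
    for i, ((_keys, fingers), onset) in enumerate(zip(task.events, onsets)):
        t0 = onset + jitter[i]
        inside = (frame_t >= t0) & (frame_t <= t0 + width)
        bump = np.zeros_like(frame_t)
        bump[inside] = 0.5 * (1 - np.cos(2 * np.pi * (frame_t[inside] - t0) / width))
        for f in fingers:
            dips[f] = np.maximum(dips[f], amp * bump)
    return dips


def gen_healthy_trial(
    task: TaskSpec,
    tempo_bpm: float | None = None,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    subject_id: str = "H00",
    hand: str = "right",
    loudness: str = "ff",
) -> tuple[LandmarkTrajectory, KeyTrace, TrialMeta]:
    """One healthy trial: landmark trajectory, key trace and metadata.

    The hand translates along the keyboard with the note sequence; the
    assigned fingertip (with its distal joints) dips toward the key plane in
    synchrony with each key excursion; trajectories are smoothed and Gaussian
    landmark noise of SD ``config.noise_sd`` is added.  Per-subject amplitude,
    hand-size and timing offsets come from a template keyed by
    ``subject_id``, so trials of one subject share a template while the
    trial-level seed drives noise and jitter.
    """
    return _gen_trial(task, tempo_bpm, config, seed, subject_id, hand,
                      loudness, pattern=None)


def gen_dystonic_trial(
    task: TaskSpec,
    tempo_bpm: float | None = None,
    pattern: DystoniaPattern = DystoniaPattern(("index", "middle"), 1.0),
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    subject_id: str = "D00",
    hand: str = "right",
    loudness: str = "ff",
) -> tuple[LandmarkTrajectory, KeyTrace, TrialMeta]:
    """A dystonic trial: the healthy template plus severity-scaled perturbation.

    Affected fingertip/DIP/PIP landmarks are biased toward the key plane,
    their keystroke dips shrink (loss of lift), their strike timing jitters,
    and adjacent fingers co-move.  At severity 0 the output equals
    :func:`gen_healthy_trial` for the same seed exactly.
    """
    return _gen_trial(task, tempo_bpm, config, seed, subject_id, hand,
                      loudness, pattern=pattern)


def _gen_trial(task, tempo_bpm, config, seed, subject_id, hand, loudness, pattern):
    tempo = task.fixed_tempo_bpm if tempo_bpm is None else tempo_bpm
    keys, truth = gen_key_trace(task, tempo, seed=seed, config=config)
    params = _subject_params(subject_id, config)
    trial_rng = np.random.default_rng([seed, 1])
    perturb_rng = np.random.default_rng([seed, 2])

    n_frames = int(np.floor(keys.t_end * config.fps)) + 1
    frame_t = np.arange(n_frames) / config.fps

    # hand anchor follows the struck keys (striking finger lands on its key)
    targets = []
    for (event_keys, fingers), onset in zip(task.events, truth.onsets_s):
        finger_name = FINGERS[fingers[0]]
        targets.append((onset, key_x(event_keys[0]) - _FINGER_X_OFFSET[finger_name]
                        * params["hand_scale"]))
    t_ctrl = np.array([0.0] + [t for t, _ in targets] + [frame_t[-1]])
    x_ctrl = np.array([targets[0][1]] + [x for _, x in targets] + [targets[-1][1]])
    anchor_x = np.interp(frame_t, t_ctrl, x_ctrl)
    anchor_x = gaussian_filter1d(anchor_x, sigma=0.1 * config.fps, mode="nearest")

    jitter = trial_rng.normal(0.0, 0.005, size=task.n_events) + params["timing_offset"]
    dip_amp = params["dip_amp"] * params["amp_scale"]
    hold = max(0.8 * (60.0 / tempo / task.subdivision) - KEY_RISE_S - KEY_FALL_S, 0.04)
    dips = _dip_profiles(frame_t, task, truth.onsets_s, hold, dip_amp, jitter)

    severity = pattern.severity if pattern is not None else 0.0
    if pattern is not None and severity > 0:
        affected = [FINGERS.index(f) for f in pattern.affected_fingers]
        extra_jitter = perturb_rng.normal(
            0.0, config.timing_jitter_s * severity, size=task.n_events)
        dips_dyst = _dip_profiles(frame_t, task, truth.onsets_s, hold,
                                  dip_amp, jitter + extra_jitter)
        for f in affected:
            dips[f] = (1.0 - config.lift_loss * severity) * dips_dyst[f]
        coupling = config.coupling * severity
        base = dips.copy()
        for f in affected:
            for neighbour in (f - 1, f + 1):
                if 0 <= neighbour < len(FINGERS):
                    dips[neighbour] = np.maximum(dips[neighbour],
                                                 coupling * base[f])

    pose = _hand_template(params)
    values = np.empty((n_frames, N_LANDMARKS, N_COORDS))
    values[:] = pose[None, :, :]
    values[:, :, 0] += anchor_x[:, None]
    values[:, :, 1] += params["wrist_y"]

    # keystroke dips: fingertip leads, distal joints follow
    for fi, finger in enumerate(FINGERS):
        chain = FINGER_CHAINS[finger]
        for landmark, weight in zip(chain, (0.05, 0.3, 0.6, 1.0)):
            values[:, landmark, 1] -= weight * dips[fi]
            values[:, landmark, 2] -= 0.3 * weight * dips[fi]
    # slight whole-hand bob with each event
    bob = dips.max(axis=0)
    values[:, :, 1] -= 0.10 * bob[:, None]

    if pattern is not None and severity > 0:
        bias = config.flexion_bias * severity
        for name in pattern.affected_fingers:
            chain = FINGER_CHAINS[name]
            for landmark, weight in zip(chain, (0.0, 0.3, 0.7, 1.0)):
                values[:, landmark, 1] -= weight * bias
        if pattern.include_wrist:
            values[:, WRIST, 1] -= 0.5 * bias

    values += trial_rng.normal(0.0, config.noise_sd, size=values.shape)

    if hand == "left":
        values[:, :, 0] = 1.0 - values[:, :, 0]

    traj = LandmarkTrajectory(values=values, timestamps=frame_t,
                              fps=config.fps, hand_label=hand)
    group = "healthy" if pattern is None or severity == 0 else "md"
    affected_hand = hand if group == "md" else "none"
    meta = TrialMeta(subject_id=subject_id, group=group, hand=hand,
                     affected_hand=affected_hand, task_id=task.task_id,
                     tempo_bpm=tempo, loudness=loudness)
    return traj, keys, meta


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: dystonic-pattern vocabulary mirroring the clinical variety of affected fingers
PATTERN_VOCABULARY: tuple[tuple[str, ...], ...] = (
    ("index", "middle"),
    ("ring", "little"),
    ("middle",),
    ("thumb", "index"),
    ("index",),
    ("ring",),
    ("middle", "ring"),
    ("middle", "ring", "little"),
)


def gen_kinematic_cohort(
    task: TaskSpec,
    n_subjects: int,
    trials_per_subject: int,
    group: str = "healthy",
    severity: float = 0.8,
    pattern: DystoniaPattern | None = None,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> list[tuple[LandmarkTrajectory, KeyTrace, TrialMeta]]:
    """Generate a cohort of trials at the study's sampling structure.

    Healthy cohorts emulate the 20-control structure; dystonic cohorts draw
    each subject's affected-finger pattern from the clinical vocabulary
    (unless one is fixed) at the given severity.
    """
    rng = np.random.default_rng([seed, 3])
    trials = []
    prefix = "H" if group == "healthy" else "D"
    for s in range(n_subjects):
        subject_id = f"{prefix}{s:02d}"
        if group == "healthy":
            subject_pattern = None
        elif pattern is not None:
            subject_pattern = pattern
        else:
            fingers = PATTERN_VOCABULARY[int(rng.integers(len(PATTERN_VOCABULARY)))]
            subject_pattern = DystoniaPattern(fingers, severity)
        for trial in range(trials_per_subject):
            trial_seed = int(np.random.default_rng([seed, s, trial]).integers(2 ** 31))
            if subject_pattern is None:
                trials.append(gen_healthy_trial(
                    task, config=config, seed=trial_seed, subject_id=subject_id))
            else:
                trials.append(gen_dystonic_trial(
                    task, pattern=subject_pattern, config=config,
                    seed=trial_seed, subject_id=subject_id))
    return trials


# ---------------------------------------------------------------------------
# biomechanical cohorts
# ---------------------------------------------------------------------------

#: healthy reference (mean, SD) per function per finger (thumb..little)
BIOMECH_REFERENCE: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "strength":        ((55, 45, 40, 30, 25), (8, 7, 6, 5, 4)),       # N
    "reduction_ratio": ((0.65,) * 5, (0.10,) * 5),
    "independence":    ((0.85, 0.80, 0.70, 0.60, 0.65), (0.08,) * 5),
    "agility":         ((6.0, 6.5, 6.0, 5.5, 5.0), (0.7,) * 5),       # taps/s
    "rom_flex_ext":    ((80, 90, 95, 90, 85), (8,) * 5),              # deg
    "rom_abd_add":     ((50, 25, 20, 25, 40), (5,) * 5),              # deg
}

#: functions degraded on the affected hand of the dystonic cohort, in SD units
DEFAULT_BIOMECH_EFFECT: dict[str, float] = {
    "reduction_ratio": -1.0,
    "independence": -1.5,
}


def gen_biomech_cohort(
    n_healthy: int = 20,
    n_md: int = 16,
    effect: dict[str, float] | None = None,
    seed: int = 0,
    p_affected_right: float = 14 / 16,
):
    """Long-format biomechanical score table for two cohorts.

    Healthy scores are Normal(reference mean, SD) on both hands; dystonic
    subjects receive the per-function SD shift on the affected hand (right
    with the clinical frequency by default).  ``effect=None`` uses the
    default degradation of the two multi-finger-control functions
    (reduction ratio and independence); ``effect={}`` makes the groups
    exchangeable.
    """
    import pandas as pd

    if n_healthy < 2 or n_md < 2:
        raise ValueError("need >= 2 subjects per group")
    effect = DEFAULT_BIOMECH_EFFECT if effect is None else effect
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, prefix in (("healthy", n_healthy, "H"), ("md", n_md, "D")):
        for s in range(n):
            subject = f"{prefix}{s:02d}"
            affected = "right" if rng.random() < p_affected_right else "left"
            for function, (means, sds) in BIOMECH_REFERENCE.items():
                for hand in ("left", "right"):
                    shift = effect.get(function, 0.0) if (
                        group == "md" and hand == affected) else 0.0
                    for finger, mean, sd in zip(FINGERS, means, sds):
                        value = rng.normal(mean + shift * sd, sd)
                        rows.append((subject, group, hand, finger, function, value))
    return pd.DataFrame(rows, columns=[
        "subject", "group", "hand", "finger", "function", "value"])


# ---------------------------------------------------------------------------
# psychophysical observers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimulatedObserver:
    """Observer answering order judgments from a cumulative-Gaussian curve.

    With ``lapse`` 0 the probability of a correct report at
    ``soa = threshold_ms`` is exactly 0.75 (the criterion defining the TOJ
    threshold).
    """

    threshold_ms: float
    slope: float = 3.0
    lapse: float = 0.0

    def p_correct(self, soa_ms: float) -> float:
        x = self.slope * (np.log10(soa_ms) - np.log10(self.threshold_ms))
        return float(0.5 + (0.5 - self.lapse) * _normal.cdf(x))

    def respond(self, soa_ms: float, stimulus_order: str,
                rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(soa_ms))


def gen_observer(threshold_ms: float, slope: float = 3.0,
                 lapse: float = 0.0) -> SimulatedObserver:
    if threshold_ms <= 0:
        raise ValueError("threshold must be > 0")
    return SimulatedObserver(threshold_ms=threshold_ms, slope=slope, lapse=lapse)
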