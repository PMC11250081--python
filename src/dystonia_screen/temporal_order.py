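"""Temporal-order-judgment threshold (TOJT) via a ZEST adaptive staircase.

Two tactile stimuli are delivered to the index and middle fingertips with a
stimulus-onset asynchrony (SOA); the observer reports which finger was
stimulated first.  The probability of a correct order report is modelled as a
cumulative Gaussian in log-SOA with guess rate 0.5 (two-alternative task) and
a small lapse rate::

    P(correct | soa) = 0.5 + (0.5 - lapse) * Phi(slope * (log10 soa - log10 theta))

ZEST maintains a discrete posterior over candidate thresholds ``theta`` on a
log-spaced grid, places each trial at the (log-domain) posterior mean, and
updates the posterior with the Bayes rule after each response — so the SOA
shortens after a correct response and lengthens after an incorrect one.  The
reported TOJT is the SOA at which the posterior-mean psychometric function
crosses 75% correct.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm as _normal

from .errors import DegeneratePrior, OutOfGridSOA

GRID_MIN_MS = 1.0
GRID_MAX_MS = 500.0
GRID_POINTS = 61

DEFAULT_SLOPE = 3.0    # per log10-ms
DEFAULT_LAPSE = 0.02
CRITERION = 0.75       # correct-rate criterion defining the threshold
DEFAULT_TRIALS = 40


def default_grid(n_points: int = GRID_POINTS,
                 lo_ms: float = GRID_MIN_MS, hi_ms: float = GRID_MAX_MS) -> np.ndarray:
    """Log-spaced candidate-threshold grid in ms."""
    return np.logspace(np.log10(lo_ms), np.log10(hi_ms), n_points)


def p_correct(soa_ms, threshold_ms, slope: float = DEFAULT_SLOPE,
              lapse: float = DEFAULT_LAPSE):
    """Psychometric probability of a correct order judgment."""
    x = slope * (np.log10(soa_ms) - np.log10(threshold_ms))
    return 0.5 + (0.5 - lapse) * _normal.cdf(x)


@dataclasses.dataclass
class ZestState:
    """Posterior over candidate thresholds plus the running trial log."""

    grid_ms: np.ndarray
    posterior: np.ndarray
    slope: float = DEFAULT_SLOPE
    lapse: float = DEFAULT_LAPSE
    trial_log: list = dataclasses.field(default_factory=list)

    @property
    def posterior_mean_log10(self) -> float:
        return float(np.sum(self.posterior * np.log10(self.grid_ms)))


def zest_init(grid_ms: np.ndarray | None = None, prior: np.ndarray | None = None,
              slope: float = DEFAULT_SLOPE, lapse: float = DEFAULT_LAPSE) -> ZestState:
    """Normalize the prior over the grid; uniform prior by default."""
    grid = np.asarray(default_grid() if grid_ms is None else grid_ms, dtype=float)
    mass = np.ones_like(grid) if prior is None else np.asarray(prior, dtype=float)
    if mass.shape != grid.shape or np.any(mass < 0):
        raise DegeneratePrior("prior must be nonnegative and match the grid")
    total = mass.sum()
    if total <= 0:
        raise DegeneratePrior("prior has zero total mass")
    return ZestState(grid_ms=grid, posterior=mass / total, slope=slope, lapse=lapse)


def zest_next_soa(state: ZestState) -> float:
    """Next SOA: posterior mean threshold (log domain), snapped to the grid."""
    target = state.posterior_mean_log10
    idx = int(np.argmin(np.abs(np.log10(state.grid_ms) - target)))
    return float(state.grid_ms[idx])


def zest_update(state: ZestState, soa_ms: float, correct: bool,
                stimulus_order: str = "index_first") -> ZestState:
    """Bayes update of the posterior with one trial's response.

    The likelihood of a correct (or incorrect) response at ``soa_ms`` is
    evaluated at every candidate threshold; the posterior is multiplied and
    renormalized, and the trial is appended to the log.
    """
    lo, hi = state.grid_ms[0], state.grid_ms[-1]
    if not (lo <= soa_ms <= hi):
        raise OutOfGridSOA(f"SOA {soa_ms} ms outside grid [{lo:g}, {hi:g}] ms")
    p = p_correct(soa_ms, state.grid_ms, state.slope, state.lapse)
    likelihood = p if correct else 1.0 - p
    posterior = state.posterior * likelihood
    total = posterior.sum()
    if total <= 0:  # pragma: no cover - cannot happen with lapse > 0
        raise DegeneratePrior("posterior collapsed to zero mass")
    new = ZestState(grid_ms=state.grid_ms, posterior=posterior / total,
                    slope=state.slope, lapse=state.lapse,
                    trial_log=list(state.trial_log))
    new.trial_log.append({
        "trial": len(state.trial_log) + 1,
        "soa_ms": float(soa_ms),
        "first_stimulus": stimulus_order,
        "correct": bool(correct),
    })
    return new


@dataclasses.dataclass(frozen=True)
class TOJResult:
    """Estimated temporal-order threshold at the 75%-correct criterion."""

    threshold_ms: float
    n_trials: int
    final_posterior_mean_ms: float


def threshold_from_state(state: ZestState, criterion: float = CRITERION) -> TOJResult:
    """SOA where the posterior-mean psychometric curve crosses the criterion.

    With the cumulative-Gaussian family the crossing has the closed form
    ``log10 soa = mu + Phi^-1((criterion - 0.5) / (0.5 - lapse)) / slope``
    where ``mu`` is the posterior mean of log10 threshold.  The result is
    clipped to the grid bounds.
    """
    mu = state.posterior_mean_log10
    q = (criterion - 0.5) / (0.5 - state.lapse)
    if not 0 < q < 1:
        raise ValueError("criterion unreachable under the lapse rate")
    log_soa = mu + float(_normal.ppf(q)) / state.slope
    threshold = float(np.clip(10 ** log_soa, state.grid_ms[0], state.grid_ms[-1]))
    return TOJResult(threshold_ms=threshold, n_trials=len(state.trial_log),
                     final_posterior_mean_ms=float(10 ** mu))


def run_session(observer, n_trials: int = DEFAULT_TRIALS, seed: int = 0,
                state: ZestState | None = None) -> tuple[TOJResult, ZestState]:
    """Run a full adaptive session against a (simulated) observer.

    The stimulus order (index-first vs middle-first) alternates randomly per
    trial; the SOA follows the ZEST placement rule.  ``observer`` must expose
    ``respond(soa_ms, stimulus_order, rng) -> bool`` (True = correct order
    report).  Deterministic for a given seed and observer.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    if state is None:
        state = zest_init()
    for _ in range(n_trials):
        soa = zest_next_soa(state)
        order = "index_first" if rng.random() < 0.5 else "middle_first"
        correct = observer.respond(soa, order, rng)
        state = zest_update(state, soa, correct, stimulus_order=order)
    return threshold_from_state(state), state


def replay_log(trials, slope: float = DEFAULT_SLOPE,
               lapse: float = DEFAULT_LAPSE) -> tuple[TOJResult, ZestState]:
    """Re-estimate the threshold from a recorded session log.

    ``trials`` is an iterable of (soa_ms, correct) pairs, e.g. parsed from a
    session CSV of a hardware run.
    """
    state = zest_init(slope=slope, lapse=lapse)
    for soa_ms, correct in trials:
        state = zest_update(state, float(soa_ms), bool(correct))
    return threshold_from_state(state), state
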