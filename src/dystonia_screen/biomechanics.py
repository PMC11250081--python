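"""Per-finger biomechanical function scores and hand-asymmetry statistics.

Six finger functions are scored per hand: maximum strength (N), the
force-reduction ratio under simultaneous all-finger exertion, the
independence (individuation) index from a 20%-MVC designated-finger hold,
tapping agility (taps/s over 5 s), and the two range-of-motion directions
(flexion/extension and abduction/adduction, degrees, supplied externally).

Scores are standardized per function per finger against a healthy reference
cohort pooled over hands, and the left-right asymmetry of a function is the
Euclidean norm of the difference between the five-finger z-score vectors::

    Assym = || z_L - z_R ||,   z_h = (z_h,thumb, ..., z_h,little)

Group comparisons (healthy vs musician's-dystonia cohorts) use the
Mann-Whitney U test with midranks (exact permutation null for pooled
n <= 12) and Benjamini-Hochberg step-up correction across the function
family tested in one invocation.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal, rankdata

from .errors import (
    EmptyGroup,
    LengthMismatch,
    OutOfRangeP,
    ZeroDesignatedForce,
    ZeroMaxForce,
    ZeroReferenceSD,
)
from .landmarks import FINGERS

FUNCTIONS = (
    "strength",
    "reduction_ratio",
    "independence",
    "agility",
    "rom_flex_ext",
    "rom_abd_add",
)

#: pooled sample size at or below which the Mann-Whitney null is enumerated exactly
EXACT_MWU_MAX_N = 12

PROFILE_COLUMNS = ["subject", "group", "hand", "finger", "function", "value"]


# ---------------------------------------------------------------------------
# per-finger scores
# ---------------------------------------------------------------------------

def force_reduction_ratio(simultaneous_force: float, max_force: float) -> float:
    """Force during simultaneous all-finger exertion over maximum strength."""
    if max_force <= 0:
        raise ZeroMaxForce("maximum finger strength must be > 0")
    if simultaneous_force < 0:
        raise ValueError("forces must be >= 0")
    return simultaneous_force / max_force


def independence_index(designated_force: float, other_forces_sum: float) -> float:
    """Individuation score: 1 - (enslaved force / designated force), floored at 0.

    1.0 means the designated finger pressed alone; 0 means the other fingers
    together produced at least as much force as the instructed one.
    """
    if designated_force <= 0:
        raise ZeroDesignatedForce("designated finger force must be > 0")
    if other_forces_sum < 0:
        raise ValueError("forces must be >= 0")
    return max(0.0, 1.0 - other_forces_sum / designated_force)


def sustained_hold_mean(t: np.ndarray, force: np.ndarray,
                        duration_s: float = 5.0, trim_s: float = 1.0) -> float:
    """Mean force over the central window of a sustained hold.

    The first and last ``trim_s`` seconds of the 5 s hold are discarded as
    on/off transients; the summary force is the mean over the remaining
    central 3 s.
    """
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    mask = (t >= trim_s) & (t <= duration_s - trim_s)
    if not np.any(mask):
        raise ValueError("no samples in the central window")
    return float(np.mean(force[mask]))


def agility_rate(tap_times, trial_duration_s: float = 5.0) -> float:
    """Taps per second over the fixed-duration fastest-tapping trial."""
    taps = np.asarray(list(tap_times), dtype=float)
    if taps.size and (taps.min() < 0 or taps.max() > trial_duration_s):
        raise ValueError("tap times must lie within the trial")
    return taps.size / trial_duration_s


# ---------------------------------------------------------------------------
# z-score profiles and asymmetry
# ---------------------------------------------------------------------------

def fit_reference(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-(function, finger) mean and sample SD, pooled over hands.

    ``profiles`` is the long-format score table (columns
    subject,group,hand,finger,function,value); normally only the healthy
    cohort is passed.  Pooling hands keeps left and right on one scale, which
    the left-right difference requires.
    """
    grouped = profiles.groupby(["function", "finger"])["value"]
    ref = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    if (ref["sd"] <= 0).any() or ref["sd"].isna().any():
        bad = ref.loc[(ref["sd"] <= 0) | ref["sd"].isna()].iloc[0]
        raise ZeroReferenceSD(f"degenerate reference SD for {bad['function']}/{bad['finger']}")
    return ref


def zscore_profile(profiles: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Standardize each score against the reference (adds a ``z`` column)."""
    merged = profiles.merge(reference, on=["function", "finger"], how="left", validate="m:1")
    if merged["mean"].isna().any():
        missing = merged.loc[merged["mean"].isna(), ["function", "finger"]].iloc[0]
        raise ZeroReferenceSD(
            f"no reference for {missing['function']}/{missing['finger']}"
        )
    merged["z"] = (merged["value"] - merged["mean"]) / merged["sd"]
    return merged.drop(columns=["mean", "sd"])


def asymmetry(z_left, z_right) -> float:
    """Euclidean norm of the left-right difference of five-finger z-vectors."""
    z_left = np.asarray(z_left, dtype=float)
    z_right = np.asarray(z_right, dtype=float)
    if z_left.shape != z_right.shape or z_left.ndim != 1:
        raise LengthMismatch(f"vectors {z_left.shape} vs {z_right.shape}")
    return float(np.linalg.norm(z_left - z_right))


def asymmetry_table(zscored: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-function Assym from a z-scored long table."""
    wide = zscored.pivot_table(
        index=["subject", "group", "function"],
        columns=["hand", "finger"], values="z", aggfunc="first",
    )
    rows = []
    for (subject, group, function), row in wide.iterrows():
        z_l = np.array([row[("left", f)] for f in FINGERS])
        z_r = np.array([row[("right", f)] for f in FINGERS])
        if np.isnan(z_l).any() or np.isnan(z_r).any():
            raise LengthMismatch(
                f"{subject}/{function}: missing finger scores for one hand"
            )
        rows.append({"subject": subject, "group": group, "function": function,
                     "assym": asymmetry(z_l, z_r)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric group comparison
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with an exact small-sample null.

    Returns ``(U, p)`` where U is the statistic of ``group_a``.  For pooled
    n <= 12 the two-sided p is computed by enumerating every assignment of
    the pooled midranks to the groups and counting assignments whose U lies
    at least as far from the null mean ``n_a n_b / 2`` as the observed U.
    Larger samples use the normal approximation with tie correction (no
    continuity correction: at these sample sizes the uncorrected two-sided
    region coincides with the exact test's).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroup("both groups need >= 1 observation")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= EXACT_MWU_MAX_N:
        dist_obs = abs(u_obs - mu) - 1e-12  # tolerate float midranks
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            r_sum = ranks[list(combo)].sum()
            u = r_sum - n_a * (n_a + 1) / 2.0
            total += 1
            if abs(u - mu) >= dist_obs:
                hits += 1
        assert total == math.comb(n_a + n_b, n_a)
        return u_obs, hits / total

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = abs(u_obs - mu) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(_normal.sf(z)))
    return u_obs, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise OutOfRangeP("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclasses.dataclass
class AsymmetryComparison:
    """Group comparison of hand asymmetry across a family of functions."""

    per_subject: pd.DataFrame   # subject, group, function, assym
    per_function: pd.DataFrame  # function, u, p_raw, p_adj, significant


def compare_groups(
    profiles: pd.DataFrame,
    functions=FUNCTIONS,
    alpha: float = 0.05,
    reference: pd.DataFrame | None = None,
) -> AsymmetryComparison:
    """Full asymmetry pipeline: reference fit, z-scores, Assym, MWU + BH.

    ``profiles`` holds both cohorts in long format.  The z-score reference is
    fitted on the healthy rows unless supplied.  The BH family is the set of
    functions tested in this invocation.
    """
    df = profiles.loc[profiles["function"].isin(functions)].copy()
    for group in ("healthy", "md"):
        if df.loc[df["group"] == group, "subject"].nunique() < 2:
            raise EmptyGroup(f"need >= 2 subjects in group {group!r}")
    if reference is None:
        reference = fit_reference(df.loc[df["group"] == "healthy"])
    zscored = zscore_profile(df, reference)
    assym = asymmetry_table(zscored)

    rows = []
    for function in functions:
        sub = assym.loc[assym["function"] == function]
        healthy = sub.loc[sub["group"] == "healthy", "assym"].to_numpy()
        md = sub.loc[sub["group"] == "md", "assym"].to_numpy()
        u, p = mann_whitney_u(healthy, md)
        rows.append({"function": function, "u": u, "p_raw": p})
    per_function = pd.DataFrame(rows)
    per_function["p_adj"] = bh_adjust(per_function["p_raw"])
    per_function["significant"] = per_function["p_adj"] < alpha
    return AsymmetryComparison(per_subject=assym, per_function=per_function)
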