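"""Finger-function scores, the asymmetry norm, and the nonparametric stats.

The Mann-Whitney implementation is checked against a definitional brute-force
oracle (U from pairwise comparisons, p by enumerating group assignments) and
against scipy's asymptotic test; BH adjustment against statsmodels.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu
from statsmodels.stats.multitest import multipletests

import dystonia_screen as ds
from dystonia_screen.errors import (
    EmptyGroup,
    LengthMismatch,
    OutOfRangeP,
    ZeroDesignatedForce,
    ZeroMaxForce,
    ZeroReferenceSD,
)


# --- independent oracle -------------------------------------------------------

def _pairwise_u(a, b):
    """Definitional U of group a: #{a_i > b_j} + half-ties."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def _brute_force_mwu(a, b):
    """Exact two-sided p by enumerating every group assignment of the pool."""
    pooled = list(a) + list(b)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    u_obs = _pairwise_u(a, b)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = _pairwise_u([pooled[i] for i in combo], rest)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    assert total == math.comb(len(pooled), n_a)
    return u_obs, hits / total


# --- per-finger scores --------------------------------------------------------

class TestFingerScores:
    @pytest.mark.parametrize("sim,maxf,expected", [(6, 10, 0.6), (10, 10, 1.0)])
    def test_force_reduction_ratio(self, sim, maxf, expected):
        assert ds.force_reduction_ratio(sim, maxf) == pytest.approx(expected)

    def test_zero_max_force_raises(self):
        with pytest.raises(ZeroMaxForce):
            ds.force_reduction_ratio(5.0, 0.0)

    @pytest.mark.parametrize("designated,others,expected",
                             [(10, 0, 1.0), (10, 2, 0.8), (10, 15, 0.0)])
    def test_independence_index(self, designated, others, expected):
        assert ds.independence_index(designated, others) == pytest.approx(expected)

    def test_zero_designated_force_raises(self):
        with pytest.raises(ZeroDesignatedForce):
            ds.independence_index(0.0, 1.0)

    def test_sustained_hold_uses_central_3s(self):
        t = np.linspace(0, 5, 5001)
        force = np.where((t < 1) | (t > 4), 100.0, 2.0)  # transients outside
        assert ds.sustained_hold_mean(t, force) == pytest.approx(2.0, abs=0.2)

    @pytest.mark.parametrize("taps,expected", [
        (np.arange(30) * (5 / 30), 6.0),
        ([], 0.0),
        (np.arange(0.1, 5.01, 0.1), 10.0),
    ])
    def test_agility_rate(self, taps, expected):
        assert ds.agility_rate(taps) == pytest.approx(expected)


# --- z-scores and asymmetry ---------------------------------------------------

class TestZScores:
    def test_reference_mean_and_sd_map_to_0_and_1(self):
        ref = pd.DataFrame({"function": ["strength"] * 2,
                            "finger": ["thumb", "index"],
                            "mean": [50.0, 40.0], "sd": [5.0, 4.0]})
        profiles = pd.DataFrame({
            "subject": ["s"] * 2, "group": ["healthy"] * 2,
            "hand": ["left"] * 2, "finger": ["thumb", "index"],
            "function": ["strength"] * 2, "value": [50.0, 44.0]})
        z = ds.zscore_profile(profiles, ref)["z"].to_numpy()
        np.testing.assert_allclose(z, [0.0, 1.0])

    def test_self_standardization(self):
        cohort = ds.gen_biomech_cohort(n_healthy=60, n_md=2, effect={}, seed=4)
        healthy = cohort[cohort["group"] == "healthy"]
        ref = ds.fit_reference(healthy)
        z = ds.zscore_profile(healthy, ref)
        stats = z.groupby(["function", "finger"])["z"].agg(["mean", "std"])
        np.testing.assert_allclose(stats["mean"], 0.0, atol=1e-9)
        np.testing.assert_allclose(stats["std"], 1.0, atol=1e-9)

    def test_degenerate_reference_sd_raises(self):
        df = pd.DataFrame({
            "subject": ["a", "b"], "group": ["healthy"] * 2,
            "hand": ["left"] * 2, "finger": ["thumb"] * 2,
            "function": ["strength"] * 2, "value": [5.0, 5.0]})
        with pytest.raises(ZeroReferenceSD):
            ds.fit_reference(df)


class TestAsymmetry:
    @pytest.mark.parametrize("diff,expected", [
        (np.zeros(5), 0.0),
        (np.array([1, 0, 0, 0, 0.0]), 1.0),
        (np.ones(5), np.sqrt(5)),
    ])
    def test_closed_forms(self, diff, expected):
        z_r = np.array([0.3, -1.0, 0.2, 0.0, 2.0])
        assert ds.asymmetry(z_r + diff, z_r) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(LengthMismatch):
            ds.asymmetry(np.zeros(5), np.zeros(4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=5, max_size=5),
           st.lists(st.floats(-3, 3), min_size=5, max_size=5),
           st.permutations(range(5)))
    def test_hand_swap_and_finger_permutation_invariance(self, zl, zr, perm):
        zl, zr = np.array(zl), np.array(zr)
        a = ds.asymmetry(zl, zr)
        assert ds.asymmetry(zr, zl) == pytest.approx(a)
        assert ds.asymmetry(zl[list(perm)], zr[list(perm)]) == pytest.approx(a)


# --- Mann-Whitney U and BH ----------------------------------------------------

class TestMannWhitney:
    @pytest.mark.parametrize("a,b,u_expected,p_expected", [
        ([1, 2, 3], [4, 5, 6], 0.0, 0.1),
        ([1, 1, 1], [1, 1, 1], 4.5, 1.0),
        ([1], [2], 0.0, 1.0),
    ])
    def test_worked_examples(self, a, b, u_expected, p_expected):
        u, p = ds.mann_whitney_u(a, b)
        assert u == pytest.approx(u_expected)
        assert p == pytest.approx(p_expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_exact_mode_matches_brute_force_oracle(self, data):
        n_a = data.draw(st.integers(1, 4))
        n_b = data.draw(st.integers(1, 8 - n_a))
        values = st.integers(0, 4)  # small support forces ties
        a = data.draw(st.lists(values, min_size=n_a, max_size=n_a))
        b = data.draw(st.lists(values, min_size=n_b, max_size=n_b))
        u, p = ds.mann_whitney_u(a, b)
        u_ref, p_ref = _brute_force_mwu(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(0.7, 1, size=16)
        u, p = ds.mann_whitney_u(a, b)
        ref = scipy_mwu(a, b, alternative="two-sided", method="asymptotic",
                        use_continuity=False)
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroup):
            ds.mann_whitney_u([], [1.0])


class TestBHAdjust:
    @pytest.mark.parametrize("p_in,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.04], [0.04]),
        ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
    ])
    def test_worked_step_up_examples(self, p_in, expected):
        np.testing.assert_allclose(ds.bh_adjust(p_in), expected)

    def test_out_of_range_raises(self):
        with pytest.raises(OutOfRangeP):
            ds.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_statsmodels_and_dominates_raw(self, p_values):
        ours = ds.bh_adjust(p_values)
        ref = multipletests(p_values, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        assert np.all(ours >= np.asarray(p_values) - 1e-15)
        assert np.all(ours <= 1.0)


# --- group comparison ---------------------------------------------------------

class TestCompareGroups:
    def test_effect_direction_detected(self):
        df = ds.gen_biomech_cohort(effect={"independence": -1.5}, seed=3)
        result = ds.compare_groups(df)
        table = result.per_function.set_index("function")
        # the shifted function should carry the smallest p of the family
        assert table["p_raw"].idxmin() == "independence"
        md = result.per_subject.query("group=='md' and function=='independence'")
        hl = result.per_subject.query("group=='healthy' and function=='independence'")
        assert md["assym"].mean() > hl["assym"].mean()

    def test_groups_of_size_one_raise(self):
        df = ds.gen_biomech_cohort(n_healthy=2, n_md=2, effect={}, seed=0)
        df = df[df["subject"] != "D01"]
        with pytest.raises(EmptyGroup):
            ds.compare_groups(df)
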