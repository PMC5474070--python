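"""Tests of window tallies, cue vectors and the social choice rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ewalearn as ew
from ewalearn.core import CUE_NAMES
from ewalearn.cues import WindowIndex, in_window


@pytest.fixture
def roster():
    return pd.DataFrame(
        {
            "age_years": [4.0, 8.0, 8.0, 20.0],
            "matriline": ["m1", "m1", "m2", "m2"],
            "alpha": [False, False, False, True],
        },
        index=pd.Index(["a", "b", "c", "alpha_male"], name="id"),
    )


TECHS = ew.TechniqueSet(("t1", "t2", "t3"))


def bout(day, seq, actor, technique, success=True, duration=50.0, audience=()):
    return ew.BoutRecord(day=day, seq=seq, actor=actor, technique=technique,
                         success=success, duration_s=duration,
                         audience=frozenset(audience))


class TestBoutRecord:
    def test_actor_cannot_watch_itself(self):
        with pytest.raises(ValueError):
            bout(1, 1, "a", "t1", audience=("a", "b"))

    def test_day_must_be_positive(self):
        with pytest.raises(ValueError):
            bout(0, 1, "a", "t1")

    def test_success_needs_duration(self):
        with pytest.raises(ValueError):
            bout(1, 1, "a", "t1", success=True, duration=0.0)


class TestCueVector:
    def test_same_age_cohort_cue_is_one(self, roster):
        k = ew.cue_vector("b", "c", (True, 50.0), roster)
        assert k[CUE_NAMES.index("coho")] == 1.0

    def test_age_gap_four_years(self, roster):
        k = ew.cue_vector("a", "b", (True, 50.0), roster)
        assert k[CUE_NAMES.index("coho")] == pytest.approx(0.2)

    def test_alpha_rank_cue(self, roster):
        assert ew.cue_vector("alpha_male", "a", (True, 50.0), roster)[1] == 1.0
        assert ew.cue_vector("b", "a", (True, 50.0), roster)[1] == 0.0

    def test_kin_cue_shared_matriline(self, roster):
        assert ew.cue_vector("a", "b", (True, 50.0), roster)[2] == 1.0
        assert ew.cue_vector("a", "c", (True, 50.0), roster)[2] == 0.0

    def test_payoff_cue_and_age_bias(self, roster):
        k = ew.cue_vector("b", "a", (False, 30.0), roster)
        assert k[0] == 0.0
        ages = roster["age_years"].to_numpy()
        expected = (8.0 - ages.mean()) / ages.std()
        assert k[4] == pytest.approx(expected)

    def test_unknown_individual_rejected(self, roster):
        with pytest.raises(ValueError):
            ew.cue_vector("zzz", "a", (True, 50.0), roster)


class TestTallyWindow:
    def test_empty_history(self, roster):
        s = ew.tally_window([], "a", 10, 14, techniques=TECHS, roster=roster)
        assert not np.any(s.N)
        assert not np.any(s.kappa)

    def test_old_bout_falls_out_of_window(self, roster):
        h = [bout(1, 1, "b", "t1", audience=("a",))]
        s = ew.tally_window(h, "a", 16, 14, techniques=TECHS, roster=roster)
        assert not np.any(s.N)

    def test_fourteen_day_old_included_fifteen_excluded(self, roster):
        h = [bout(1, 1, "b", "t1", audience=("a",))]
        s14 = ew.tally_window(h, "a", 15, 14, techniques=TECHS, roster=roster)
        s15 = ew.tally_window(h, "a", 16, 14, techniques=TECHS, roster=roster)
        assert s14.N[0] == 1 and s15.N[0] == 0

    def test_same_day_sequence_semantics(self, roster):
        h = [bout(5, 1, "b", "t1", audience=("a",)),
             bout(5, 3, "b", "t1", audience=("a",))]
        s = ew.tally_window(h, "a", 5, 14, techniques=TECHS, roster=roster, now_seq=2)
        assert s.N[0] == 1  # earlier same-day bout in, later one out

    def test_requires_audience_membership(self, roster):
        h = [bout(3, 1, "b", "t1", audience=("c",))]
        s = ew.tally_window(h, "a", 4, 14, techniques=TECHS, roster=roster)
        assert not np.any(s.N)

    def test_mean_payoff_cue_over_mixed_outcomes(self, roster):
        d = math.exp(5.0)  # payoff cue exactly 0.2
        h = [bout(3, 1, "b", "t1", success=True, duration=d, audience=("a",)),
             bout(3, 2, "b", "t1", success=False, duration=d, audience=("a",))]
        s = ew.tally_window(h, "a", 4, 14, techniques=TECHS, roster=roster)
        assert s.N[0] == 2
        assert s.kappa[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_unknown_observer(self, roster):
        with pytest.raises(KeyError):
            ew.tally_window([], "zzz", 5, 14, techniques=TECHS, roster=roster)


@st.composite
def histories(draw):
    n = draw(st.integers(min_value=0, max_value=25))
    bouts = []
    day, seq = 1, 1
    for _ in range(n):
        if draw(st.booleans()):
            day += draw(st.integers(min_value=1, max_value=8))
            seq = 1
        actor = draw(st.sampled_from(["a", "b", "c", "alpha_male"]))
        audience = draw(st.sets(
            st.sampled_from([x for x in ["a", "b", "c", "alpha_male"] if x != actor])))
        bouts.append(bout(day, seq, actor,
                          draw(st.sampled_from(TECHS.names)),
                          success=draw(st.booleans()),
                          duration=draw(st.floats(min_value=5, max_value=500)),
                          audience=audience))
        seq += 1
    return bouts


class TestWindowProperties:
    @given(histories(), st.integers(min_value=1, max_value=40),
           st.integers(min_value=1, max_value=28))
    def test_containment_matches_predicate(self, history, now_day, window):
        roster = pd.DataFrame(
            {"age_years": [4.0, 8.0, 8.0, 20.0],
             "matriline": ["m1", "m1", "m2", "m2"],
             "alpha": [False, False, False, True]},
            index=pd.Index(["a", "b", "c", "alpha_male"], name="id"))
        s = ew.tally_window(history, "a", now_day, window,
                            techniques=TECHS, roster=roster, now_seq=3)
        expected = sum(1 for b in history if in_window(b, "a", now_day, window, 3))
        assert int(s.N.sum()) == expected

    @given(histories(), st.integers(min_value=1, max_value=40))
    def test_incremental_index_matches_reference_tally(self, history, now_day):
        """The O(window) incremental index agrees with the reference tally."""
        roster = pd.DataFrame(
            {"age_years": [4.0, 8.0, 8.0, 20.0],
             "matriline": ["m1", "m1", "m2", "m2"],
             "alpha": [False, False, False, True]},
            index=pd.Index(["a", "b", "c", "alpha_male"], name="id"))
        widx = WindowIndex(TECHS, roster, 14)
        for b in history:
            widx.append(b)
        got = widx.query("b", now_day, 2)
        ref = ew.tally_window(history, "b", now_day, 14,
                              techniques=TECHS, roster=roster, now_seq=2)
        assert np.array_equal(got.N, ref.N)
        assert got.kappa == pytest.approx(ref.kappa, abs=1e-12)


class TestSocialChoice:
    def kappa0(self):
        return np.zeros((3, len(CUE_NAMES)))

    def test_frequency_proportional_when_unbiased(self):
        s = ew.CueWindowSummary(N=np.array([3, 1, 0]), kappa=self.kappa0(), window_days=14)
        p = ew.social_choice_probs(s, 1.0, np.zeros(5))
        assert p == pytest.approx([0.75, 0.25, 0.0], abs=1e-12)

    def test_anticonformity_overweights_rare_option(self):
        s = ew.CueWindowSummary(N=np.array([9, 1, 0]), kappa=self.kappa0(), window_days=14)
        p = ew.social_choice_probs(s, 0.38, np.zeros(5))
        assert p[1] == pytest.approx(1.0 / (9**0.38 + 1.0), abs=1e-12)
        assert p[1] > 0.1

    def test_empty_window_has_no_social_term(self):
        s = ew.CueWindowSummary(N=np.zeros(3, dtype=int), kappa=self.kappa0(), window_days=14)
        assert ew.social_choice_probs(s, 1.0, np.zeros(5)) is None

    def test_scaling_invariance_at_f_one(self):
        k = self.kappa0()
        a = ew.social_choice_probs(
            ew.CueWindowSummary(N=np.array([6, 3, 1]), kappa=k, window_days=14), 1.0, np.zeros(5))
        b = ew.social_choice_probs(
            ew.CueWindowSummary(N=np.array([60, 30, 10]), kappa=k, window_days=14), 1.0, np.zeros(5))
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("f,side", [(0.38, "below"), (1.0, "equal"), (3.0, "above")])
    def test_conformity_signature(self, f, side):
        N = np.array([8, 2])
        s = ew.CueWindowSummary(N=N, kappa=np.zeros((2, 5)), window_days=14)
        p = ew.social_choice_probs(s, f, np.zeros(5))
        raw = N[0] / N.sum()
        assert p[0] > p[1]  # majority still preferred for any f > 0
        if side == "below":
            assert p[0] < raw
        elif side == "above":
            assert p[0] > raw
        else:
            assert p[0] == pytest.approx(raw, abs=1e-12)

    def test_increasing_in_count(self):
        for f in (0.38, 1.0, 3.0):
            probs = []
            for n1 in (1, 3, 5, 9):
                s = ew.CueWindowSummary(N=np.array([n1, 5]),
                                        kappa=np.zeros((2, 5)), window_days=14)
                probs.append(ew.social_choice_probs(s, f, np.zeros(5))[0])
            assert np.all(np.diff(probs) > 0)

    def test_zero_beta_makes_cue_irrelevant(self):
        rng = np.random.default_rng(3)
        kappa = rng.normal(size=(3, 5))
        beta = np.array([0.7, 0.0, -0.4, 0.2, 0.9])
        N = np.array([4, 2, 1])
        base = ew.social_choice_probs(
            ew.CueWindowSummary(N=N, kappa=kappa, window_days=14), 1.3, beta)
        shuffled = kappa.copy()
        shuffled[:, 1] = rng.permutation(shuffled[:, 1])  # cue with beta = 0
        other = ew.social_choice_probs(
            ew.CueWindowSummary(N=N, kappa=shuffled, window_days=14), 1.3, beta)
        assert base == pytest.approx(other, abs=1e-12)


class TestPreferenceCurve:
    def test_unbiased_curve_is_diagonal(self):
        grid = np.arange(1, 10) / 10.0
        curve = ew.preference_curve(grid, 10, 1.0, np.zeros(5), 0.5)
        assert curve == pytest.approx(grid, abs=1e-12)

    def test_payoff_bias_at_even_frequency(self):
        curve = ew.preference_curve(np.array([0.5]), 10, 1.0,
                                    np.array([1.02, 0, 0, 0, 0]), 0.5)
        expected = math.exp(0.51) / (math.exp(0.51) + 1.0)
        assert curve[0] == pytest.approx(expected, abs=1e-12)

    def test_anticonformity_dips_below_diagonal_near_one(self):
        curve = ew.preference_curve(np.array([0.9]), 10, 0.38,
                                    np.array([1.02, 0, 0, 0, 0]), 0.5)
        # common high-pay-off option is under-copied relative to its frequency
        assert curve[0] < 0.9

    def test_non_integer_grid_rejected(self):
        with pytest.raises(ValueError):
            ew.preference_curve(np.array([0.55]), 10, 1.0, np.zeros(5), 0.5)
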