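"""Log-rank statistic against independent oracles; prognostic screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mpem_interactome.io import ValidationError
from mpem_interactome.survival import (
    SurvivalCohort,
    km_restricted_mean,
    logrank,
    prognostic_screen,
)
from mpem_interactome.synthetic import generate_survival_cohort


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([1, 2, 3, 1, 2, 3.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([1, 1, 1, 0, 0, 0], bool)
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_toy_cohort_frozen_values_and_permutation_rank(self):
        """Fully separated groups: chi2 = 5.0517, asymptotic p = 0.0246;
        the exact permutation p over all 20 label assignments is 2/20."""
        times = np.array([1, 2, 3, 4, 5, 6.0])
        events = np.ones(6, int)
        group = np.array([1, 1, 1, 0, 0, 0], bool)
        chi2, p = logrank(times, events, group)
        assert chi2 == pytest.approx(5.0516605, rel=1e-6)
        assert p == pytest.approx(0.0246023, rel=1e-5)
        stats_all = [
            logrank(times, events, np.isin(np.arange(6), comb))[0]
            for comb in itertools.combinations(range(6), 3)
        ]
        perm_p = np.mean([s >= chi2 - 1e-12 for s in stats_all])
        assert perm_p == pytest.approx(2 / 20)

    def test_matches_lifelines_on_enumerated_small_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            times = np.round(rng.exponential(10, n), 2) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            n1 = int(rng.integers(1, n))
            group = np.zeros(n, bool)
            group[rng.choice(n, n1, replace=False)] = True
            if group.all() or not group.any():
                continue
            chi2, p = logrank(times, events, group)
            ref = logrank_test(times[group], times[~group], events[group], events[~group])
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_swap_invariance(self):
        times = np.array([2, 5, 3, 8, 1, 9.0])
        events = np.array([1, 0, 1, 1, 1, 0])
        group = np.array([1, 0, 1, 0, 1, 0], bool)
        assert logrank(times, events, group) == pytest.approx(logrank(times, events, ~group))

    def test_time_scaling_invariance(self):
        times = np.array([2, 5, 3, 8, 1, 9.0])
        events = np.array([1, 0, 1, 1, 1, 0])
        group = np.array([1, 0, 1, 0, 1, 0], bool)
        chi2_a, _ = logrank(times, events, group)
        chi2_b, _ = logrank(times * 7.3, events, group)
        assert chi2_a == pytest.approx(chi2_b)

    def test_all_censored_returns_p_one(self):
        chi2, p = logrank([1, 2, 3, 4.0], [0, 0, 0, 0], [1, 1, 0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank([1, 2.0], [1, 1], [1, 1])

    def test_asymptotic_matches_sampled_permutations_at_moderate_n(self):
        """At n = 40 the chi-square approximation agrees with the
        permutation distribution within Monte-Carlo error."""
        rng = np.random.default_rng(21)
        n = 40
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        group = np.zeros(n, bool)
        group[:20] = True
        chi2, p = logrank(times, events, group)
        perm = []
        for _ in range(2000):
            g = rng.permutation(group)
            perm.append(logrank(times, events, g)[0])
        perm_p = np.mean(np.asarray(perm) >= chi2 - 1e-12)
        mc_err = 3 * np.sqrt(max(p * (1 - p), 0.01) / 2000)
        assert abs(perm_p - p) < 0.04 + mc_err


class TestPrognosticScreen:
    def _cohort(self, seed=3, n=200, hr=3.0):
        return generate_survival_cohort(n, ["GX", "GN"], planted_hr={"GX": hr}, seed=seed)

    def test_planted_hazard_gene_flagged_unfavourable(self):
        flagged = 0
        for seed in range(1, 21):
            cohort = self._cohort(seed=seed)
            calls = {c.gene: c for c in prognostic_screen(cohort)}
            call = calls["GX"]
            flagged += call.direction == "unfavourable" and call.p < 0.001
        assert flagged >= 18

    def test_direction_consistent_with_protective_gene(self):
        hits = 0
        for seed in range(1, 11):
            cohort = generate_survival_cohort(300, ["GP"], planted_hr={"GP": 1 / 4}, seed=seed)
            (call,) = prognostic_screen(cohort)
            if call.direction != "none":
                hits += call.direction == "favourable"
        assert hits >= 8

    def test_constant_expression_gene_gets_no_direction(self):
        cohort = self._cohort()
        cohort.expression["CONST"] = 1.0
        calls = {c.gene: c for c in prognostic_screen(cohort)}
        assert calls["CONST"].direction == "none"
        assert calls["CONST"].p is None

    def test_tiny_cohort_rejected(self):
        df = pd.DataFrame({"G": [1.0, 2.0, 3.0]})
        cohort = SurvivalCohort(time=[1, 2, 3.0], event=[1, 1, 1], expression=df)
        with pytest.raises(ValidationError):
            prognostic_screen(cohort)


def test_km_restricted_mean_step_function():
    # events at 1 and 3 out of {1, 3}, survival 1 -> 0.5 -> 0
    rm = km_restricted_mean(np.array([1.0, 3.0]), np.array([1, 1]), tau=3.0)
    assert rm == pytest.approx(1.0 * 1 + 0.5 * 2)
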