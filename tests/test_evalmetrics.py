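"""Evaluation statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from adscca import (SurvivalData, bonferroni, cohens_d, concordance_index,
                    cox_univariate, dichotomize_median, evaluate_risks,
                    km_curve, logrank_test, wilcoxon_signed_rank)
from adscca.errors import AdsccaError, InvalidConfigError
from adscca.survhead import cox_partial_log_likelihood


def surv(times, events):
    return SurvivalData([f"s{i}" for i in range(len(times))],
                        np.asarray(times, float), np.asarray(events, int))


def cindex_bruteforce(risks, times, events):
    """Independent O(n²) Harrell pair count, written from the definition."""
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if i == j or times[i] >= times[j] or events[i] != 1:
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_reverse_ranking(self):
        s = surv([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([4, 3, 2, 1], s) == 1.0

    def test_all_tied_risks(self):
        s = surv([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([2, 2, 2, 2], s) == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_with_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        times = rng.exponential(10, size=n).round(1) + 0.1  # some ties, > 0
        events = (rng.random(n) > 0.3).astype(int)
        risks = rng.normal(size=n).round(1)
        s = surv(times, events)
        assert concordance_index(risks, s) == pytest.approx(
            cindex_bruteforce(risks, times, events), abs=1e-12)

    def test_matches_lifelines(self, random_survival):
        from lifelines.utils import concordance_index as ll_ci
        s, lp = random_survival
        ours = concordance_index(lp, s)
        theirs = ll_ci(s.time, -lp, s.event)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_negation_identity(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=15)  # continuous: no ties
        risks = rng.normal(size=15)
        s = surv(times, np.ones(15))
        assert concordance_index(risks, s) + concordance_index(-risks, s) \
            == pytest.approx(1.0)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(AdsccaError):
            concordance_index([1, 2], surv([5, 5], [0, 0]))


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = km_curve(surv([1, 2, 3], [0, 0, 0]))
        assert km.time.size == 0
        assert km.survival_at(10) == 1.0

    def test_single_event(self):
        km = km_curve(surv([5], [1]))
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5) == 0.0

    def test_hand_product_limit(self):
        """n=4: events at 1 and 2, censored at 1.5, survivor to 3.
        S(1) = 3/4; at t=2 risk set {2, 3} → S(2) = 3/4 · 1/2 = 3/8."""
        km = km_curve(surv([1, 1.5, 2, 3], [1, 0, 1, 0]))
        assert km.survival_at(1) == pytest.approx(0.75)
        assert km.survival_at(2) == pytest.approx(0.375)
        assert km.at_risk.tolist() == [4, 2]

    def test_curve_monotone_from_random_data(self, random_survival):
        s, _ = random_survival
        km = km_curve(s)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival[0] <= 1.0


class TestDichotomize:
    def test_even_split(self):
        labels = dichotomize_median(np.array([1.0, 2.0, 3.0, 4.0]))
        assert labels == ["low", "low", "high", "high"]

    def test_median_element_goes_low(self):
        labels = dichotomize_median(np.array([1.0, 2.0, 3.0]))
        assert labels == ["low", "low", "high"]

    def test_all_identical_warns(self):
        with pytest.warns(UserWarning):
            labels = dichotomize_median(np.array([2.0, 2.0]))
        assert labels == ["low", "low"]


def logrank_oracle(ta, ea, tb, eb):
    """Hand O−E/V table over pooled distinct event times."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(np.concatenate([ta[ea == 1], tb[eb == 1]]))):
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n, d = na + nb, da + db
        if n < 2:
            continue
        o_minus_e += da - d * na / n
        var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        s = surv([1, 2, 3], [1, 1, 0])
        stat, p = logrank_test(s, s)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_table(self):
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        stat, _ = logrank_test(surv(ta, ea), surv(tb, eb))
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb),
                                     rel=1e-10)

    def test_clear_separation_significant(self):
        a = surv(np.arange(1, 11), np.ones(10))
        b = surv(np.arange(20, 30), np.ones(10))
        _, p = logrank_test(a, b)
        assert p < 0.05

    def test_label_swap_invariance(self, random_survival):
        s, lp = random_survival
        half = len(s) // 2
        g1 = s.subset(s.sample_ids[:half])
        g2 = s.subset(s.sample_ids[half:])
        assert logrank_test(g1, g2)[1] == pytest.approx(
            logrank_test(g2, g1)[1])

    def test_no_events_warns(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test(surv([1, 2], [0, 0]), surv([3], [0]))
        assert (stat, p) == (0.0, 1.0)


class TestCoxPartialLikelihood:
    def test_two_subjects_equal_risks(self):
        s = surv([1.0, 2.0], [1, 0])
        assert cox_partial_log_likelihood(np.zeros(2), s) \
            == pytest.approx(-np.log(2))

    def test_all_censored_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert cox_partial_log_likelihood(np.ones(3),
                                              surv([1, 2, 3], [0, 0, 0])) == 0.0

    def test_hand_enumeration_with_tie(self):
        """3 subjects, times (2, 2, 5), events (1, 1, 1), risks (a, b, c):
        Breslow risk sets: both t=2 events see all three; t=5 sees itself."""
        r = np.array([0.3, -0.2, 0.9])
        s = surv([2.0, 2.0, 5.0], [1, 1, 1])
        denom_all = np.log(np.exp(r).sum())
        expected = ((r[0] - denom_all) + (r[1] - denom_all)
                    + (r[2] - np.log(np.exp(r[2])))) / 3
        assert cox_partial_log_likelihood(r, s) == pytest.approx(
            expected, abs=1e-10)

    def test_shift_invariance(self, random_survival):
        s, lp = random_survival
        a = cox_partial_log_likelihood(lp, s)
        b = cox_partial_log_likelihood(lp + 7.3, s)
        assert a == pytest.approx(b, abs=1e-8)


class TestCoxUnivariate:
    def test_null_covariate_near_one(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            times = rng.exponential(10, size=200)
            events = (rng.random(200) > 0.3).astype(int)
            x = rng.normal(size=200)
            fit = cox_univariate(x, surv(times, events))
            if 0.7 <= fit.hr <= 1.4 and fit.p > 0.01:
                hits += 1
        assert hits >= 9

    def test_constant_covariate_flagged(self):
        with pytest.warns(UserWarning):
            fit = cox_univariate(np.zeros(6), surv([1, 2, 3, 4, 5, 6],
                                                   [1, 1, 1, 0, 0, 1]))
        assert fit.beta == 0.0 and fit.hr == 1.0 and fit.flagged

    def test_matches_grid_search(self):
        """Binary covariate, n=6: Newton beta vs brute-force grid."""
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        s = surv([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 0, 1, 1, 1])

        def pl(beta):
            tot = 0.0
            for i in np.flatnonzero(s.event == 1):
                rs = s.time >= s.time[i]
                tot += beta * x[i] - np.log(np.exp(beta * x[rs]).sum())
            return tot

        grid = np.linspace(-5, 5, 200001)
        beta_grid = grid[np.argmax([pl(b) for b in grid[::100]]) * 100]
        # refine around the coarse optimum
        fine = np.linspace(beta_grid - 0.1, beta_grid + 0.1, 20001)
        beta_star = fine[np.argmax([pl(b) for b in fine])]
        fit = cox_univariate(x, s)
        assert fit.beta == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines(self, random_survival):
        import pandas as pd
        from lifelines import CoxPHFitter
        s, lp = random_survival
        fit = cox_univariate(lp, s)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"x": lp, "T": s.time, "E": s.event}),
                "T", "E")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)

    def test_separation_flagged(self):
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        s = surv([1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1])
        with pytest.warns(UserWarning):
            fit = cox_univariate(x, s)
        assert fit.flagged and fit.ci_high == np.inf

    def test_direction_agrees_with_logrank(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            lp = rng.normal(size=60)
            from adscca import generate_survival
            s = generate_survival(lp, 1.0, 0.2, seed=int(rng.integers(1e6)))
            ind = (lp > np.median(lp)).astype(float)
            fit = cox_univariate(ind, s)
            high = [sid for sid, g in zip(s.sample_ids, ind) if g == 1]
            low = [sid for sid, g in zip(s.sample_ids, ind) if g == 0]
            km_hi = km_curve(s.subset(high))
            km_lo = km_curve(s.subset(low))
            t_med = np.median(s.time)
            if fit.beta > 0:   # high group worse → lower survival
                assert km_hi.survival_at(t_med) <= km_lo.survival_at(t_med)


def wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = [ranks[list(signs)].sum() for signs in
          (np.array(bits, bool) for bits in
           itertools.product([0, 1], repeat=n))]
    ws = np.array(ws)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return min(1.0, p)


class TestWilcoxon:
    def test_five_positive_differences(self):
        p = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_matches_full_enumeration_n10(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        b = a + rng.normal(0.4, 1.0, size=10)
        # distinct |diffs| by construction (continuous)
        p = wilcoxon_signed_rank(b, a)
        assert p == pytest.approx(wilcoxon_enumeration(b - a), abs=1e-10)


class TestBonferroniCohen:
    def test_bonferroni_values(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.5, 4) == 1.0
        with pytest.raises(InvalidConfigError):
            bonferroni(0.5, 0)

    def test_cohens_d_degenerate_flagged(self):
        with pytest.warns(UserWarning):
            assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_cohens_d_value(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([0.0, 0.0, 0.0])
        d = (a - b).mean() / (a - b).std(ddof=1)
        assert cohens_d(a, b) == pytest.approx(d)


def test_evaluate_risks_bundle(random_survival):
    s, lp = random_survival
    rep = evaluate_risks(lp, s)
    assert 0.0 <= rep.c_index <= 1.0
    assert rep.hr > 0 and rep.hr_ci_low <= rep.hr <= rep.hr_ci_high
    assert len(rep.groups) == len(s)
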