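"""Oracle- and property-based tests for the evaluation statistics."""

import numpy as np
import pytest
from scipy import stats

from cirrdx import evalstats as ev
from cirrdx.errors import DegenerateInputError, DomainError


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with ties worth 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        c = ev.ScoredCohort([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        _, auc, _ = ev.roc_auc(c)
        assert auc == 1.0

    def test_constant_scores_half(self):
        c = ev.ScoredCohort([0.5] * 10, [0, 1] * 5)
        _, auc, _ = ev.roc_auc(c)
        assert auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = np.round(rng.normal(labels, 1.2), 1)  # rounded -> ties occur
        auc = ev.mann_whitney_auc(scores, labels)
        assert abs(auc - brute_force_auc(scores, labels)) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            ev.roc_auc(ev.ScoredCohort([0.1, 0.2], [1, 1]))

    def test_ci_contains_point(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.0)
        _, auc, (lo, hi) = ev.roc_auc(ev.ScoredCohort(scores, labels))
        assert lo <= auc <= hi


class TestYouden:
    def test_forced_convention(self):
        c = ev.ScoredCohort([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert ev.youden_cutoff(c) == 0.8

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = np.round(rng.normal(labels, 1.0), 1)
        t = ev.youden_cutoff(ev.ScoredCohort(scores, labels))
        n1, n0 = labels.sum(), (1 - labels).sum()

        def j_at(th):
            calls = scores >= th
            return (calls & (labels == 1)).sum() / n1 + (
                (~calls & (labels == 0)).sum() / n0) - 1

        best = max(j_at(th) for th in np.unique(scores))
        assert abs(j_at(t) - best) < 1e-12
        # tie-break: no higher threshold attains the same J
        higher = [th for th in np.unique(scores) if th > t]
        assert all(j_at(th) < best - 1e-12 for th in higher)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.normal(labels, 1.0)
        c1 = ev.ScoredCohort(scores, labels)
        c2 = ev.ScoredCohort(np.exp(scores), labels)
        t1, t2 = ev.youden_cutoff(c1), ev.youden_cutoff(c2)
        assert np.isclose(np.exp(t1), t2)


class TestConfusion:
    def test_degenerate_cutoffs(self):
        c = ev.ScoredCohort([0.1, 0.5, 0.9], [0, 1, 1])
        hi = ev.confusion_at(c, 2.0)
        assert hi.tp == 0 and hi.fp == 0
        lo = ev.confusion_at(c, -1.0)
        assert lo.fn == 0 and lo.tn == 0

    def test_partition(self):
        rng = np.random.default_rng(1)
        c = ev.ScoredCohort(rng.random(33), rng.integers(0, 2, 33))
        cm = ev.confusion_at(c, 0.4)
        assert cm.total == 33


class TestMetrics:
    def test_published_external_combined(self):
        ms = ev.metrics_with_ci(ev.ConfusionMatrix(tp=62, fp=11, fn=12, tn=30))
        assert ms.as_percent() == {"sensitivity": 84, "specificity": 73,
                                   "ppv": 85, "npv": 71, "accuracy": 80}

    def test_published_internal1_combined(self):
        ms = ev.metrics_with_ci(ev.ConfusionMatrix(tp=60, fp=5, fn=7, tn=22))
        pct = ms.as_percent()
        assert pct["sensitivity"] == 90 and pct["accuracy"] == 87

    def test_perfect_classifier(self):
        ms = ev.metrics_with_ci(ev.ConfusionMatrix(tp=8, fp=0, fn=0, tn=0))
        pct = ms.as_percent()
        assert pct["sensitivity"] == 100 and pct["ppv"] == 100 and pct["accuracy"] == 100
        assert "specificity" in ms.undefined and "npv" in ms.undefined

    def test_ci_brackets_point(self):
        ms = ev.metrics_with_ci(ev.ConfusionMatrix(tp=30, fp=10, fn=5, tn=40))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lo, hi = ms.ci[name]
            assert lo <= getattr(ms, name) <= hi

    def test_clopper_pearson_against_scipy(self):
        lo, hi = ev._clopper_pearson(62, 74)
        res = stats.binomtest(62, 74).proportion_ci(method="exact")
        assert np.isclose(lo, res.low) and np.isclose(hi, res.high)

    def test_percent_rounding_half_up(self):
        assert ev.percent_display(0.975) == 98
        assert ev.percent_display(0.845) == 85  # 84.5 rounds up
        assert ev.percent_display(0.844999) == 84


def delong_variance_oracle(sa, sb, labels):
    """Direct structural-components enumeration of var(AUC_a - AUC_b)."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    m, n = len(pos), len(neg)

    def components(s):
        v10 = np.array([np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                                 for j in neg]) for i in pos])
        v01 = np.array([np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                                 for i in pos]) for j in neg])
        return v10, 1.0 - v01  # v01 as P(neg outranks pos)

    v10a, v01a = components(sa)
    v10b, v01b = components(sb)

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

    return (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m + (
        cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        s = rng.normal(size=30)
        res = ev.delong_test(s, s, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_variance_matches_enumeration_oracle(self, scored_fixture):
        a, b, labels = scored_fixture
        a, b, labels = a[:40], b[:40], labels[:40]
        res = ev.delong_test(a, b, labels)
        oracle = delong_variance_oracle(a, b, labels)
        assert abs(res.extra["var"] - oracle) < 1e-10

    def test_p_in_unit_interval(self, scored_fixture):
        a, b, labels = scored_fixture
        res = ev.delong_test(a, b, labels)
        assert 0.0 <= res.p_value <= 1.0

    def test_unpaired_identical_strata(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        s = rng.normal(labels, 1.0)
        c = ev.ScoredCohort(s, labels)
        res = ev.unpaired_delong_test(c, c)
        assert res.p_value == 1.0


class TestMcNemar:
    def test_worked_exact_value(self):
        # b=5, c=1 -> 2 * P(X <= 1 | n=6, p=1/2) = 0.21875
        labels = np.ones(20, dtype=int)
        calls_a = np.ones(20, dtype=int)
        calls_b = np.ones(20, dtype=int)
        calls_a[:1] = 0   # A wrong, B correct: c=1
        calls_b[1:6] = 0  # A correct, B wrong: b=5
        res = ev.mcnemar_test(calls_a, calls_b, labels, "sensitivity")
        assert res.method == "mcnemar_exact"
        assert res.p_value == pytest.approx(0.21875, abs=1e-12)

    def test_symmetric_discordance_p_one(self):
        labels = np.ones(10, dtype=int)
        a = np.array([1, 1, 1, 0, 0, 1, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 1, 1, 1, 1, 1, 1])
        res = ev.mcnemar_test(a, b, labels, "sensitivity")
        assert res.p_value == 1.0

    def test_swap_invariance(self, scored_fixture):
        a, b, labels = scored_fixture
        ca, cb = (a > 0.4).astype(int), (b > 0.4).astype(int)
        for metric in ("sensitivity", "specificity", "accuracy"):
            p1 = ev.mcnemar_test(ca, cb, labels, metric).p_value
            p2 = ev.mcnemar_test(cb, ca, labels, metric).p_value
            assert p1 == p2

    def test_no_discordance(self):
        labels = np.array([0, 1, 0, 1])
        calls = np.array([0, 1, 1, 1])
        assert ev.mcnemar_test(calls, calls, labels, "accuracy").p_value == 1.0

    def test_asymptotic_matches_scipy_chi2(self):
        labels = np.ones(200, dtype=int)
        a = np.ones(200, dtype=int)
        b = np.ones(200, dtype=int)
        a[:10] = 0
        b[10:40] = 0  # b=30, c=10 -> asymptotic branch
        res = ev.mcnemar_test(a, b, labels, "sensitivity")
        assert res.method == "mcnemar_chi2"
        expected = (abs(30 - 10) - 1) ** 2 / 40
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(expected, 1)))


class TestKosinski:
    def test_identical_calls_p_one(self, scored_fixture):
        a, _, labels = scored_fixture
        calls = (a > 0.4).astype(int)
        for which in ("ppv", "npv"):
            res = ev.kosinski_test(calls, calls, labels, which)
            assert res.p_value == 1.0

    def test_order_invariance(self, scored_fixture):
        a, b, labels = scored_fixture
        ca, cb = (a > 0.4).astype(int), (b > 0.4).astype(int)
        perm = np.random.default_rng(0).permutation(len(labels))
        r1 = ev.kosinski_test(ca, cb, labels, "ppv")
        r2 = ev.kosinski_test(ca[perm], cb[perm], labels[perm], "ppv")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_no_positive_calls_flagged(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.raises(DegenerateInputError):
            ev.kosinski_test(np.zeros(4, int), np.array([1, 1, 0, 0]), labels, "ppv")

    def test_agrees_with_permutation_oracle(self, scored_fixture):
        a, b, labels = scored_fixture
        ca, cb = (a > 0.55).astype(int), (b > 0.2).astype(int)
        res = ev.kosinski_test(ca, cb, labels, "ppv")
        rng = np.random.default_rng(99)
        n_reps = 20_000
        stats_obs = res.statistic
        count = 0
        swaps = rng.random((n_reps, len(labels))) < 0.5
        for s in swaps:
            pa = np.where(s, cb, ca)
            pb = np.where(s, ca, cb)
            r = ev.kosinski_test(pa, pb, labels, "ppv")
            if r.statistic >= stats_obs - 1e-12:
                count += 1
        p_perm = count / n_reps
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_reps)
        assert abs(res.p_value - p_perm) < max(0.05, 4 * mc_se)


class TestCalibration:
    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(11)
        p = rng.beta(2, 2, 5000)
        y = (rng.random(5000) < p).astype(int)
        rows = ev.calibration_bins(ev.ScoredCohort(p, y), 10)
        gap = max(abs(r["mean_predicted"] - r["observed_rate"]) for r in rows)
        assert gap < 0.05

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        c = ev.ScoredCohort(rng.random(47), rng.integers(0, 2, 47))
        sizes = [r["n"] for r in ev.calibration_bins(c, 10)]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 47

    def test_too_few_cases_reduces_bins(self):
        c = ev.ScoredCohort([0.2, 0.4, 0.9], [0, 0, 1])
        with pytest.warns(UserWarning):
            rows = ev.calibration_bins(c, 10)
        assert len(rows) == 3


class TestNetBenefit:
    def test_worked_arithmetic(self):
        # external-testing counts at pt=0.2: 62/115 - (11/115)*0.25
        scores = np.concatenate([np.full(62, 0.9), np.full(11, 0.9),
                                 np.full(12, 0.1), np.full(30, 0.1)])
        labels = np.concatenate([np.ones(62), np.zeros(11), np.ones(12), np.zeros(30)])
        rows = ev.net_benefit(ev.ScoredCohort(scores, labels.astype(int)), [0.2])
        assert rows[0]["nb_model"] == pytest.approx(62 / 115 - (11 / 115) * 0.25)
        assert rows[0]["nb_none"] == 0.0

    def test_dominates_treat_all_with_fewer_fp_at_equal_tp(self):
        # model keeps every true positive but rejects half the negatives:
        # NB_model >= NB_all at every threshold
        labels = np.array([1] * 40 + [0] * 60)
        scores = np.concatenate([np.ones(40), np.ones(30), np.zeros(30)])
        rows = ev.net_benefit(ev.ScoredCohort(scores, labels), np.linspace(0.05, 0.9, 12))
        for r in rows:
            assert r["nb_model"] >= r["nb_all"] - 1e-12

    def test_model_bounded_by_prevalence(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 100)
        c = ev.ScoredCohort(rng.random(100), labels)
        for r in ev.net_benefit(c, np.linspace(0.05, 0.95, 10)):
            assert r["nb_model"] <= labels.mean() + 1e-12


class TestSubgroups:
    def test_identical_strata_p_one(self):
        rng = np.random.default_rng(8)
        labels = np.tile(rng.integers(0, 2, 30), 2)
        labels[:2] = [0, 1]
        labels[30:32] = [0, 1]
        scores = np.tile(rng.normal(size=30), 2)
        strata = np.repeat(["a", "b"], 30)
        out = ev.subgroup_auc(ev.ScoredCohort(scores, labels), strata)
        assert out["comparisons"][("a", "b")].p_value == 1.0

    def test_single_class_stratum_excluded(self):
        labels = np.array([1, 1, 1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.4])
        strata = np.array(["x", "x", "x", "y", "y", "y"])
        with pytest.warns(UserWarning):
            out = ev.subgroup_auc(ev.ScoredCohort(scores, labels), strata)
        assert out["excluded"] == ["x"] and "y" in out["strata"]

    @pytest.mark.slow
    def test_power_for_separated_aucs(self):
        rejections = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            labels = np.concatenate([rng.integers(0, 2, 200), rng.integers(0, 2, 200)])
            labels[:2] = [0, 1]
            labels[200:202] = [0, 1]
            # stratum A: AUC ~ 0.9 (d=1.81), stratum B: AUC ~ 0.7 (d=0.74)
            s1 = rng.normal(labels[:200] * 1.81, 1.0)
            s2 = rng.normal(labels[200:] * 0.74, 1.0)
            strata = np.repeat(["a", "b"], 200)
            out = ev.subgroup_auc(
                ev.ScoredCohort(np.concatenate([s1, s2]), labels), strata)
            if out["comparisons"][("a", "b")].p_value < 0.05:
                rejections += 1
        assert rejections > 80


class TestReferenceCounts:
    def test_fixture_totals(self):
        ref = ev.load_reference_confusions()
        totals = {"internal_test_1": 94, "internal_test_2": 266, "external_test": 115}
        for ds, models in ref.items():
            for cm in models.values():
                assert cm.total == totals[ds]

    def test_all_90_published_cells(self):
        printed = {
            "internal_test_1": {
                "combined": (90, 81, 92, 76, 87), "cnn": (87, 74, 89, 69, 83),
                "fib4": (69, 67, 84, 46, 68), "apri": (72, 63, 83, 47, 69),
                "reader1": (82, 67, 86, 60, 78), "reader2": (72, 85, 92, 55, 76)},
            "internal_test_2": {
                "combined": (87, 71, 86, 72, 82), "cnn": (81, 79, 89, 67, 80),
                "fib4": (64, 64, 79, 46, 64), "apri": (59, 62, 76, 42, 60),
                "reader1": (74, 73, 85, 58, 74), "reader2": (71, 91, 94, 60, 77)},
            "external_test": {
                "combined": (84, 73, 85, 71, 80), "cnn": (77, 68, 81, 62, 74),
                "fib4": (62, 66, 77, 49, 63), "apri": (65, 54, 72, 46, 61),
                "reader1": (73, 73, 83, 60, 73), "reader2": (70, 71, 81, 57, 70)},
        }
        ref = ev.load_reference_confusions()
        for ds, models in printed.items():
            for model, expected in models.items():
                pct = ev.metrics_with_ci(ref[ds][model]).as_percent()
                got = tuple(pct[k] for k in
                            ("sensitivity", "specificity", "ppv", "npv", "accuracy"))
                assert got == expected, (ds, model)


def test_invalid_inputs():
    with pytest.raises(DomainError):
        ev.ScoredCohort([0.1, 0.2], [0, 2])
    with pytest.raises(DomainError):
        ev.ConfusionMatrix(tp=-1, fp=0, fn=0, tn=5)
    with pytest.raises(DomainError):
        ev.confusion_at(ev.ScoredCohort([0.5, 0.1], [1, 0]), np.inf)
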