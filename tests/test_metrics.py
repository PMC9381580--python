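import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcrsig.metrics import (
    auc,
    km_estimate,
    logrank_test,
    median_split,
    precision_recall_curve,
    roc_curve,
    sensitivity_at_zero_fpr,
    spearman_rho,
)


def brute_force_metrics(scores, labels):
    """Exhaustive threshold sweep: reference for AUC and zero-FPR sensitivity."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best_sens = 0.0
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for thr in np.unique(scores):
        tpr = (scores[pos] > thr).sum() / n_pos
        fpr = (scores[~pos] > thr).sum() / n_neg
        pts.add((fpr, tpr))
        if fpr == 0:
            best_sens = max(best_sens, tpr)
    # AUC by explicit pair counting
    wins = half = 0
    for sp in scores[pos]:
        for sn in scores[~pos]:
            if sp > sn:
                wins += 1
            elif sp == sn:
                half += 1
    return (wins + 0.5 * half) / (n_pos * n_neg), best_sens


class TestSensitivityAtZeroFPR:
    def test_hand_example(self):
        s = [0.9, 0.8, 0.3, 0.5, 0.2]
        y = [1, 1, 1, 0, 0]
        assert sensitivity_at_zero_fpr(s, y) == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        assert sensitivity_at_zero_fpr([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_top_sample_negative(self):
        assert sensitivity_at_zero_fpr([1, 2, 3], [1, 1, 0]) == 0.0

    def test_tie_with_best_negative_does_not_count(self):
        # deployment rule: a positive tied with the best negative is not called
        assert sensitivity_at_zero_fpr([0.5, 0.9], [0, 1]) == 1.0
        assert sensitivity_at_zero_fpr([0.5, 0.5], [0, 1]) == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            sensitivity_at_zero_fpr([1, 2], [1, 1])


class TestAUC:
    def test_hand_example(self):
        assert auc([0.9, 0.8, 0.3, 0.5, 0.2], [1, 1, 1, 0, 0]) == pytest.approx(5 / 6)

    def test_perfect(self):
        assert auc([2, 1], [1, 0]) == 1.0

    def test_tie_counts_half(self):
        assert auc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(4, 20)
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.all() or not labels.any():
                continue
            bf_auc, bf_sens = brute_force_metrics(scores, labels)
            assert auc(scores, labels) == pytest.approx(bf_auc, abs=0)
            assert sensitivity_at_zero_fpr(scores, labels) == pytest.approx(bf_sens, abs=0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    scores = rng.normal(size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.all() or not labels.any():
        labels[0], labels[1] = 0, 1
    transformed = np.exp(3 * scores) + 1
    assert auc(scores, labels) == pytest.approx(auc(transformed, labels), abs=1e-12)
    assert sensitivity_at_zero_fpr(scores, labels) == sensitivity_at_zero_fpr(
        transformed, labels
    )


class TestCurves:
    def test_minimal_roc(self):
        pts = roc_curve([0.9, 0.1], [1, 0])
        assert pts == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]

    def test_trapezoid_integral_equals_auc(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            pts = np.asarray(roc_curve(scores, labels))
            integral = np.trapezoid(pts[:, 1], pts[:, 0])
            assert integral == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_precision_at_clean_top(self):
        # threshold admitting 2 positives, 0 negatives -> precision 1
        pts = precision_recall_curve([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 1])
        recall, precision = pts[1]
        assert (recall, precision) == (pytest.approx(2 / 3), 1.0)


class TestSpearman:
    def test_identity_and_reverse(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_hand_example(self):
        rho, _ = spearman_rho([1, 2, 3], [1, 3, 2])
        assert rho == pytest.approx(0.5)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestSurvival:
    def test_km_hand_example(self):
        # n=4, deaths at t=1 and t=2: S(2) = (3/4)(2/3) = 0.5
        times, surv = km_estimate([1, 2, 3, 4], [1, 1, 0, 0])
        np.testing.assert_allclose(times, [1, 2])
        np.testing.assert_allclose(surv, [0.75, 0.5])

    def test_logrank_identical_groups(self):
        res = logrank_test(["a", "a", "b", "b"], [1, 2, 1, 2], [1, 1, 1, 1])
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_logrank_hand_example(self):
        # A events at 1,2; B at 3,4; O-E = 7/6, V = 17/36 -> chi2 = 49/17
        res = logrank_test(["A", "A", "B", "B"], [1, 2, 3, 4], [1, 1, 1, 1])
        assert res.chi_square == pytest.approx(49 / 17, rel=1e-12)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(13)
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        g = rng.integers(0, 2, size=60)
        if e.sum() == 0:
            e[0] = 1
        ours = logrank_test(g, t, e)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_km_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(14)
        t = rng.exponential(5, size=50)
        e = rng.integers(0, 2, size=50)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        times, surv = km_estimate(t, e)
        for et, s in zip(times, surv):
            assert kmf.predict(et) == pytest.approx(s, rel=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1, 2], [1, 1])


class TestMedianSplit:
    def test_even_split(self):
        g = median_split([1, 2, 3, 4])
        assert list(g) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        g = median_split([1, 1, 1, 2])
        assert list(g) == ["low", "low", "low", "high"]

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            g = median_split([5, 5, 5])
        assert (g == "low").all()
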