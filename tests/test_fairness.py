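import numpy as np
import pytest
from sklearn.metrics import f1_score

from convoscreen.fairness import (
    GroupRates,
    apply_thresholds,
    audit,
    demographic_parity_ratio,
    equalized_odds_ratio,
    fit_eo_thresholds,
    group_rates,
    policy_expected_rates,
    subgroup_f1_tradeoff,
)


def brute_rates(y, p, g):
    out = {}
    for grp in set(g):
        idx = [i for i, x in enumerate(g) if x == grp]
        sel = sum(p[i] for i in idx) / len(idx)
        pos = [i for i in idx if y[i] == 1]
        neg = [i for i in idx if y[i] == 0]
        tpr = sum(p[i] for i in pos) / len(pos) if pos else float("nan")
        fpr = sum(p[i] for i in neg) / len(neg) if neg else float("nan")
        out[str(grp)] = (sel, tpr, fpr)
    return out


class TestGroupRates:
    def test_hand_count(self):
        r = group_rates([1, 1, 0, 0], [1, 0, 1, 0], ["g"] * 4)
        assert r.selection_rate["g"] == 0.5
        assert r.tpr["g"] == 0.5
        assert r.fpr["g"] == 0.5

    def test_perfect_predictions(self):
        r = group_rates([1, 0, 1, 0], [1, 0, 1, 0], ["a", "a", "b", "b"])
        assert all(v == 1.0 for v in r.tpr.values())
        assert all(v == 0.0 for v in r.fpr.values())

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = 50
            y = rng.integers(0, 2, n).tolist()
            p = rng.integers(0, 2, n).tolist()
            g = rng.choice(["a", "b", "c"], n).tolist()
            r = group_rates(y, p, g)
            for grp, (sel, tpr, fpr) in brute_rates(y, p, g).items():
                assert r.selection_rate[grp] == pytest.approx(sel)
                if np.isfinite(tpr):
                    assert r.tpr[grp] == pytest.approx(tpr)
                if np.isfinite(fpr):
                    assert r.fpr[grp] == pytest.approx(fpr)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            group_rates([1, 0], [1], ["a", "b"])


def _rates(sr=None, tpr=None, fpr=None):
    groups = [f"g{i}" for i in range(len(sr or tpr))]
    zeros = {g: 0.5 for g in groups}
    return GroupRates(
        selection_rate=dict(zip(groups, sr)) if sr else zeros,
        tpr=dict(zip(groups, tpr)) if tpr else zeros,
        fpr=dict(zip(groups, fpr)) if fpr else zeros,
        support={g: 10 for g in groups},
    )


class TestRatios:
    def test_dpr_examples(self):
        assert demographic_parity_ratio(_rates(sr=[0.8, 0.4])) == 0.5
        assert demographic_parity_ratio(_rates(sr=[0.3, 0.6, 0.9])) == pytest.approx(1 / 3)
        assert demographic_parity_ratio(_rates(sr=[0.7, 0.7])) == 1.0
        assert demographic_parity_ratio(_rates(sr=[0.0, 0.0])) == 1.0  # no selections
        assert demographic_parity_ratio(_rates(sr=[0.0, 0.4])) == 0.0

    def test_eor_examples(self):
        r = _rates(tpr=[1.0, 0.5], fpr=[0.4, 0.2])
        assert equalized_odds_ratio(r) == 0.5
        assert equalized_odds_ratio(_rates(tpr=[0.8, 0.8], fpr=[0.1, 0.1])) == 1.0
        assert equalized_odds_ratio(_rates(tpr=[0.0, 0.6], fpr=[0.1, 0.1])) == 0.0
        # both degenerate (0/0) on FPR -> that ratio is 1
        assert equalized_odds_ratio(_rates(tpr=[0.5, 0.25], fpr=[0.0, 0.0])) == 0.5

    def test_four_fifths_flag(self):
        y = [1, 0] * 10 + [1, 0] * 10
        pred = list(y)
        rep = audit(y, pred, ["a"] * 20 + ["b"] * 20, attribute="sex")
        assert rep.dpr == rep.eor == 1.0
        assert not rep.four_fifths_flag
        # group a: TPR 0.8, FPR 0.2; group b: TPR 0.6, FPR 0.4
        y = [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10
        pred = ([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
                + [1] * 6 + [0] * 4 + [1] * 4 + [0] * 6)
        g = ["a"] * 20 + ["b"] * 20
        rep2 = audit(y, pred, g, attribute="sex")
        assert rep2.eor == pytest.approx(0.5)  # min(0.6/0.8, 0.2/0.4)
        assert rep2.four_fifths_flag

    def test_undefined_groups_excluded_then_error(self):
        r = _rates(tpr=[float("nan"), 0.5, 0.25], fpr=[0.1, 0.1, 0.2])
        assert equalized_odds_ratio(r) == 0.5
        with pytest.raises(ValueError):
            equalized_odds_ratio(_rates(tpr=[float("nan"), 0.5],
                                        fpr=[0.1, 0.1]))


class TestEqualizedOddsFit:
    def _biased(self, rng, n=600, shift=0.8):
        g = np.where(rng.random(n) < 0.5, "A", "B")
        y = rng.integers(0, 2, n)
        s = rng.normal(y * 1.4 + (g == "A") * shift, 1.0)
        return s, y, g

    def test_identical_groups_identical_rules(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.normal(y * 1.0, 1.0)
        g = np.array((["A"] * 100) + (["B"] * 100))
        s = np.concatenate([s[:100], s[:100]])
        y = np.concatenate([y[:100], y[:100]])
        pol = fit_eo_thresholds(s, y, g)
        assert pol.group_rules["A"] == pol.group_rules["B"]

    def test_expected_rates_hit_target_on_fitting_set(self, rng):
        s, y, g = self._biased(rng)
        pol = fit_eo_thresholds(s, y, g)
        r = policy_expected_rates(pol, s, y, g)
        tprs, fprs = list(r.tpr.values()), list(r.fpr.values())
        assert max(tprs) - min(tprs) < 0.05
        assert max(fprs) - min(fprs) < 0.05

    def test_perfect_scores_choose_ideal_operating_point(self):
        y = np.array([0, 0, 1, 1] * 10)
        s = y.astype(float)
        g = np.array(["A", "B"] * 20)
        pol = fit_eo_thresholds(s, y, g)
        assert pol.target_fpr == pytest.approx(0.0)
        assert pol.target_tpr == pytest.approx(1.0)

    def test_degenerate_group_error_names_group(self):
        with pytest.raises(ValueError, match="B"):
            fit_eo_thresholds([0.1, 0.9, 0.2, 0.8],
                              [0, 1, 1, 1], ["A", "A", "B", "B"])

    def test_apply_deterministic_when_unrandomized(self):
        from convoscreen.fairness import ThresholdPolicy
        pol = ThresholdPolicy(0.1, 0.8, {
            "A": dict(t_lo=0.3, t_hi=0.3, alpha=1.0, beta=1.0, coin_p=0.1)
        })
        s = np.array([0.1, 0.3, 0.5])
        p1 = apply_thresholds(pol, s, ["A"] * 3, seed=0)
        assert np.array_equal(p1, [0, 1, 1])

    def test_apply_same_seed_reproducible(self, rng):
        s, y, g = self._biased(rng)
        pol = fit_eo_thresholds(s, y, g)
        a = apply_thresholds(pol, s, g, seed=11)
        b = apply_thresholds(pol, s, g, seed=11)
        assert np.array_equal(a, b)

    def test_held_out_rates_approach_target(self, rng):
        s, y, g = self._biased(rng, n=6000)
        pol = fit_eo_thresholds(s, y, g)
        s2, y2, g2 = self._biased(rng, n=20_000)
        pred = apply_thresholds(pol, s2, g2, seed=5)
        r = group_rates(y2, pred, g2)
        for grp in r.groups:
            assert r.tpr[grp] == pytest.approx(pol.target_tpr, abs=0.05)
            assert r.fpr[grp] == pytest.approx(pol.target_fpr, abs=0.05)


class TestSubgroupF1:
    def test_mean_of_subgroup_f1(self, rng):
        y = rng.integers(0, 2, 80)
        pred = rng.integers(0, 2, 80)
        g = np.array(["a"] * 40 + ["b"] * 40)
        before, after = subgroup_f1_tradeoff(y, pred, pred, g)
        expected = np.mean([
            f1_score(y[:40], pred[:40], zero_division=0),
            f1_score(y[40:], pred[40:], zero_division=0),
        ])
        assert before == pytest.approx(expected)
        assert after == before  # identical predictions -> zero delta

    def test_degenerate_subgroup_scores_zero(self):
        y = [0, 0, 1, 1]
        pred = [0, 0, 1, 1]
        g = ["empty", "empty", "full", "full"]
        before, _ = subgroup_f1_tradeoff(y, pred, pred, g)
        assert before == pytest.approx((0.0 + 1.0) / 2)
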