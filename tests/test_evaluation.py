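"""Evaluation statistics against brute-force and analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kegfr import evaluation as ev


def brute_force_auc(scores, labels):
    """Pairwise probability that an event outranks a non-event (½ ties)."""
    x = scores[labels]
    y = scores[~labels]
    wins = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    return wins / (x.size * y.size)


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 10.0, 20.0])
        labels = np.array([True, True, False, False])
        roc = ev.empirical_auc(scores, labels, "lower_predicts_event")
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = ev.empirical_auc([3.0] * 6, [True, False] * 3)
        assert roc.auc == 0.5

    def test_small_enumeration_case(self):
        # events score {1, 3}, non-events {2, 4}: the only winning pair
        # is (3, 2), so 1 of 4 pairs → AUC 0.25 by direct enumeration
        roc = ev.empirical_auc([1, 2, 3, 4], [True, False, True, False])
        assert roc.auc == 0.25

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(6, 100)
            scores = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties
                scores = np.round(scores, 1)
            labels = rng.random(n) < 0.4
            if labels.all() or (~labels).all():
                continue
            roc = ev.empirical_auc(scores, labels)
            assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        base = ev.empirical_auc(scores, labels).auc
        assert ev.empirical_auc(3 * scores + 7, labels).auc == pytest.approx(base)
        assert ev.empirical_auc(np.exp(scores), labels).auc == pytest.approx(base)

    def test_curve_endpoints(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        roc = ev.empirical_auc(scores, labels)
        assert roc.curve[0] == (0.0, 0.0)
        assert roc.curve[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.empirical_auc([1.0, 2.0], [True, True])


class TestDeLong:
    def test_identical_predictors(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        out = ev.delong_variance_and_test(scores, scores.copy(), labels)
        assert out["auc_difference"] == 0.0
        assert out["p_value"] == 1.0

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(size=50) + 0.8 * (rng.random(50) < 0.4)
        labels = rng.random(50) < 0.4
        out = ev.delong_variance_and_test(scores, rng.normal(size=50), labels)
        lo, hi = out["ci_a"]
        assert lo <= out["auc_a"] <= hi

    def test_se_agrees_with_bootstrap(self, rng):
        """DeLong SE of a single AUC vs a seeded bootstrap SE."""
        n = 80
        labels = rng.random(n) < 0.4
        scores = rng.normal(size=n) + 1.0 * labels
        out = ev.delong_variance_and_test(scores, rng.normal(size=n), labels)
        se_delong = (out["ci_a"][1] - out["ci_a"][0]) / (2 * 1.959963984540054)
        boots = []
        brng = np.random.default_rng(7)
        for _ in range(2000):
            idx = brng.integers(0, n, n)
            if labels[idx].all() or (~labels[idx]).all():
                continue
            boots.append(ev._mann_whitney_auc(scores[idx], labels[idx]))
        se_boot = np.std(boots, ddof=1)
        assert se_delong == pytest.approx(se_boot, rel=0.15)

    def test_null_rejection_rate_near_nominal(self):
        """Type-I error of the paired test under independent noise
        predictors stays near 5% (moderate-replicate check)."""
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(20, bool), np.zeros(30, bool)]
        n_rep, rej = 400, 0
        for _ in range(n_rep):
            a, b = rng.normal(size=50), rng.normal(size=50)
            if ev.delong_variance_and_test(a, b, labels)["p_value"] < 0.05:
                rej += 1
        assert 0.02 <= rej / n_rep <= 0.09

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.delong_variance_and_test([1, 2], [1, 2, 3], [True, False])


def exhaustive_youden(scores, labels, direction):
    s = scores if direction == "higher_predicts_event" else -scores
    best_j, best = -np.inf, None
    u = np.unique(s)
    for thr in np.r_[u[0] - 1, (u[:-1] + u[1:]) / 2, u[-1] + 1]:
        pos = s >= thr
        sens = (pos & labels).sum() / labels.sum()
        spec = (~pos & ~labels).sum() / (~labels).sum()
        if sens + spec - 1 > best_j + 1e-12:
            best_j, best = sens + spec - 1, (sens, spec)
    return best_j, best


class TestYouden:
    def test_perfect_separation_midpoint(self):
        scores = np.array([1.0, 2.0, 5.0, 6.0])
        labels = np.array([False, False, True, True])
        cutoff, sens, spec = ev.youden_optimal_cutoff(scores, labels)
        assert sens == spec == 1.0
        assert cutoff == pytest.approx(3.5)

    def test_all_identical_scores(self):
        _, sens, spec = ev.youden_optimal_cutoff([2.0] * 8, [True, False] * 4)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.45
            if labels.all() or (~labels).all():
                continue
            direction = "lower_predicts_event" if rng.random() < 0.5 else "higher_predicts_event"
            cutoff, sens, spec = ev.youden_optimal_cutoff(scores, labels, direction)
            best_j, _ = exhaustive_youden(scores, labels, direction)
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_direction_mirror(self):
        scores = np.array([5.0, 10.0, 1.0, 2.0])
        labels = np.array([False, False, True, True])
        cutoff, sens, spec = ev.youden_optimal_cutoff(
            scores, labels, "lower_predicts_event"
        )
        assert sens == spec == 1.0
        assert cutoff == pytest.approx(3.5)


class TestCutoffTable:
    def test_perfect_separation_all_ones(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([False, False, True, True])
        table = ev.cutoff_table(scores, labels)
        row = table[table.operating_point == "youden"].iloc[0]
        assert row.sensitivity == row.specificity == row.ppv == row.npv == 1.0

    def test_ppv_npv_bayes_arithmetic(self):
        """Fabricated 2×2: sens 0.9, spec 0.5, prevalence 22/56."""
        prev = 22 / 56
        sens, spec = 0.9, 0.5
        ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        npv = spec * (1 - prev) / ((1 - sens) * prev + spec * (1 - prev))
        # construct data realizing exactly these rates: 20 events (18 pos),
        # 34 non-events (17 pos)
        scores = np.r_[np.ones(18), np.zeros(2), np.ones(17), np.zeros(17)]
        labels = np.r_[np.ones(20, bool), np.zeros(34, bool)]
        table = ev.cutoff_table(scores, labels, prevalence=prev)
        row = table[table.operating_point == "sens90"].iloc[0]
        assert row.sensitivity == pytest.approx(0.9)
        assert row.specificity == pytest.approx(0.5)
        assert row.ppv == pytest.approx(ppv)
        assert row.npv == pytest.approx(npv)

    def test_balanced_case(self):
        # sens = spec = 0.8 at prevalence 0.5 → PPV = NPV = 0.8
        scores = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        table = ev.cutoff_table(scores, labels)
        row = table[table.operating_point == "youden"].iloc[0]
        assert row.ppv == pytest.approx(0.8)
        assert row.npv == pytest.approx(0.8)

    def test_three_rows(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        table = ev.cutoff_table(scores, labels)
        assert list(table.operating_point) == ["sens90", "youden", "spec90"]


class TestAugmentedModel:
    def _cohort(self, rng, n=200, signal=1.5):
        labels = rng.random(n) < 0.4
        base_risk = ev._expit(-0.4 + 1.0 * labels + rng.normal(0, 1, n))
        biomarker = signal * labels + rng.normal(0, 1, n)
        return base_risk, biomarker, labels

    def test_zero_variance_biomarker_changes_nothing(self, rng):
        base_risk, _, labels = self._cohort(rng)
        p_base, p_new = ev.fit_augmented_model(base_risk, np.full(200, 3.0), labels)
        assert np.allclose(p_base, p_new, atol=1e-5)

    def test_collinear_biomarker_changes_nothing(self, rng):
        base_risk, _, labels = self._cohort(rng)
        p_base, p_new = ev.fit_augmented_model(base_risk, ev._logit(base_risk), labels)
        assert np.allclose(p_base, p_new, atol=1e-5)

    def test_informative_biomarker_raises_auc(self, rng):
        base_risk, biomarker, labels = self._cohort(rng)
        p_base, p_new = ev.fit_augmented_model(base_risk, biomarker, labels)
        auc_base = ev.empirical_auc(p_base, labels).auc
        auc_new = ev.empirical_auc(p_new, labels).auc
        assert auc_new > auc_base

    def test_matches_statsmodels_fit(self, rng):
        """Our likelihood optimiser agrees with the statsmodels MLE."""
        import statsmodels.api as sm

        base_risk, biomarker, labels = self._cohort(rng, n=150)
        p_base, p_new = ev.fit_augmented_model(base_risk, biomarker, labels)
        X = sm.add_constant(np.column_stack([ev._logit(base_risk), biomarker]))
        ref = sm.Logit(labels.astype(float), X).fit(disp=0).predict(X)
        assert np.allclose(p_new, ref, atol=1e-5)

    def test_separated_data_handled_with_ridge(self):
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        base_risk = np.full(20, 0.4)
        biomarker = np.r_[np.ones(10), np.zeros(10)]
        p_base, p_new = ev.fit_augmented_model(base_risk, biomarker, labels)
        assert np.isfinite(p_new).all()
        assert (p_new[labels] > p_new[~labels]).all()

    def test_base_risk_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ev.fit_augmented_model([0.2, 1.0], [1.0, 2.0], [True, False])

    def test_offset_mode_keeps_base_risk_fixed(self, rng):
        base_risk, biomarker, labels = self._cohort(rng)
        p_base, p_new = ev.fit_augmented_model(
            base_risk, biomarker, labels, base_mode="offset"
        )
        assert np.allclose(p_base, base_risk)
        assert not np.allclose(p_new, p_base)


class TestIdi:
    def test_identical_probabilities_give_zero(self):
        p = np.array([0.2, 0.5, 0.7, 0.3])
        labels = np.array([True, False, True, False])
        out = ev.idi(p, p.copy(), labels, n_bootstrap=0)
        assert out.idi_events == 0.0
        assert out.idi_nonevents == 0.0

    def test_direct_mean_arithmetic(self):
        # events: base {0.2, 0.4} → new {0.3, 0.6}; non-event: 0.3 → 0.1
        p_base = np.array([0.2, 0.4, 0.3])
        p_new = np.array([0.3, 0.6, 0.1])
        labels = np.array([True, True, False])
        out = ev.idi(p_base, p_new, labels, n_bootstrap=0)
        assert out.idi_events == pytest.approx(0.15)
        assert out.idi_nonevents == pytest.approx(0.2)

    def test_discrimination_slope_identity(self, rng):
        """IDI-events + IDI-nonevents equals the difference in
        discrimination slopes between the two models."""
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.random(n) < 0.5
            if labels.all() or (~labels).all():
                continue
            p_base, p_new = rng.random(n), rng.random(n)
            out = ev.idi(p_base, p_new, labels, n_bootstrap=0)
            slope = lambda p: p[labels].mean() - p[~labels].mean()
            assert out.idi_events + out.idi_nonevents == pytest.approx(
                slope(p_new) - slope(p_base), abs=1e-12
            )

    def test_bootstrap_ci_brackets_estimate_under_signal(self, rng):
        labels = rng.random(120) < 0.4
        base_risk = ev._expit(rng.normal(0, 1, 120) + labels)
        biomarker = 1.5 * labels + rng.normal(0, 1, 120)
        p_base, p_new = ev.fit_augmented_model(base_risk, biomarker, labels)
        out = ev.idi(p_base, p_new, labels, n_bootstrap=200, seed=3,
                     refit_inputs=(base_risk, biomarker))
        lo, hi = out.idi_events_ci
        assert lo < out.idi_events < hi

    def test_bootstrap_requires_seed(self):
        p = np.array([0.2, 0.8, 0.4, 0.6])
        labels = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="seed"):
            ev.idi(p, p, labels, n_bootstrap=10)

    def test_pencina_ci(self, rng):
        labels = rng.random(80) < 0.5
        p_base, p_new = rng.random(80), rng.random(80)
        out = ev.idi(p_base, p_new, labels, ci_method="pencina")
        lo, hi = out.idi_events_ci
        assert lo < out.idi_events < hi


class TestRiskAssessmentCurves:
    def test_degenerate_all_zero(self):
        out = ev.risk_assessment_curves([0.0, 0.0], [True, False], n_grid=11)
        assert out["sensitivity"][0] == 1.0
        assert (out["sensitivity"][1:] == 0.0).all()

    def test_perfect_model_steps(self):
        labels = np.array([True, False, True, False])
        p = labels.astype(float)
        out = ev.risk_assessment_curves(p, labels, n_grid=101)
        assert (out["sensitivity"] == 1.0).all()  # events stay 1 through r=1
        assert out["one_minus_specificity"][0] == 1.0
        assert (out["one_minus_specificity"][1:] == 0.0).all()

    def test_matches_direct_counting(self, rng):
        p = rng.random(10)
        labels = rng.random(10) < 0.5
        if labels.all() or (~labels).all():
            labels[0] = ~labels[0]
        out = ev.risk_assessment_curves(p, labels, n_grid=21)
        for i, r in enumerate(out["risk"]):
            assert out["sensitivity"][i] == pytest.approx(
                np.mean(p[labels] >= r)
            )
            assert out["one_minus_specificity"][i] == pytest.approx(
                np.mean(p[~labels] >= r)
            )

    def test_curves_non_increasing(self, rng):
        p = rng.random(50)
        labels = rng.random(50) < 0.4
        out = ev.risk_assessment_curves(p, labels)
        assert (np.diff(out["sensitivity"]) <= 1e-12).all()
        assert (np.diff(out["one_minus_specificity"]) <= 1e-12).all()


class TestBlandAltman:
    def test_identical_methods(self):
        out = ev.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.bias == out.loa_low == out.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        out = ev.bland_altman(x, x + 5.0)
        assert out.bias == pytest.approx(-5.0)
        assert out.loa_low == pytest.approx(-5.0)
        assert out.loa_high == pytest.approx(-5.0)

    def test_hand_arithmetic(self):
        # differences {-2, 0, 2}: bias 0, sample SD 2
        out = ev.bland_altman([-2.0, 0.0, 2.0], [0.0, 0.0, 0.0])
        assert out.bias == pytest.approx(0.0)
        assert out.loa_low == pytest.approx(-3.92)
        assert out.loa_high == pytest.approx(3.92)
        assert out.pairs_used == 3

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ev.bland_altman([1.0], [2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = ev.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = ev.spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_case(self):
        # ranks {1,2,3,4} vs {2,1,4,3}: Σd² = 4 → rho = 1 − 24/60 = 0.6
        rho, _ = ev.spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ev.spearman_correlation([1, 1, 1], [1, 2, 3])


class TestCensoring:
    def _dataset(self, n=56, n_early=4):
        """Cohort table mirroring the study flow: ``n_early`` DGF
        subjects dialysed between 4 h and 8 h."""
        rows = []
        for i in range(n):
            dgf = i < 22
            dial = 6.0 if (dgf and i < n_early) else (30.0 if dgf else np.nan)
            for t in (4.0, 8.0, 12.0):
                rows.append(
                    {"subject_id": f"S{i}", "timepoint_h": t,
                     "dialysis_time_h": dial, "dgf": dgf}
                )
        return pd.DataFrame(rows)

    def test_study_flow_counts(self):
        data = self._dataset()
        for t, expected in [(4.0, 56), (8.0, 52), (12.0, 52)]:
            censored = ev.censor_after_dialysis(data, t)
            at_t = censored[censored.timepoint_h == t]
            assert len(at_t) == expected

    def test_earlier_timepoints_keep_dgf_label(self):
        data = self._dataset()
        censored = ev.censor_after_dialysis(data, 8.0)
        at_4 = censored[censored.timepoint_h == 4.0]
        assert len(at_4) == 56
        assert at_4.dgf.sum() == 22

    def test_no_dialysis_is_noop(self):
        data = self._dataset(n_early=0)
        data["dialysis_time_h"] = np.nan
        censored = ev.censor_after_dialysis(data, 8.0)
        pd.testing.assert_frame_equal(censored, data)

    def test_idempotent(self):
        data = self._dataset()
        once = ev.censor_after_dialysis(data, 8.0)
        twice = ev.censor_after_dialysis(once, 8.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_dialysed_early_gives_empty_set(self):
        data = self._dataset()
        data["dialysis_time_h"] = 2.0
        censored = ev.censor_after_dialysis(data, 4.0)
        assert censored.empty
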