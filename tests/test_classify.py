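"""ROC, Youden threshold, cross-validation and predictive values."""

import numpy as np
import pytest

import lge_zmap as lz


def _mann_whitney_auc(features, labels):
    """Brute-force pairwise concordance oracle: P(f_pos > f_neg) + ties/2."""
    f = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = f[y == 1], f[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = lz.roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_all_tied_features_give_half(self):
        roc = lz.roc_curve([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_on_random_instances(self, rng):
        # >= 100 random small instances, with ties made likely by rounding
        for trial in range(120):
            n = int(rng.integers(4, 13))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            f = np.round(rng.normal(size=n), 1)
            roc = lz.roc_curve(f, y)
            assert roc.auc == pytest.approx(_mann_whitney_auc(f, y), abs=1e-12)
            assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lz.roc_curve([1.0, 2.0], [1, 1])


class TestYoudenThreshold:
    def test_perfect_separation_picks_observed_value(self):
        roc = lz.roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        thr, sens, spec = lz.youden_threshold(roc)
        assert thr == pytest.approx(0.8)  # tie -> higher (more specific)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for trial in range(120):
            n = int(rng.integers(4, 16))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            f = np.round(rng.normal(size=n), 1)
            roc = lz.roc_curve(f, y)
            thr, sens, spec = lz.youden_threshold(roc)
            # oracle: scan every candidate threshold
            best_j, best_thr = -np.inf, None
            for t in np.unique(f):
                pos = f >= t
                j = (pos & (y == 1)).sum() / (y == 1).sum() - (
                    pos & (y == 0)
                ).sum() / (y == 0).sum()
                if j > best_j or (j == best_j and t > best_thr):
                    best_j, best_thr = j, t
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
            assert thr == pytest.approx(best_thr)

    def test_anticorrelated_features_flagged(self, caplog):
        roc = lz.roc_curve([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        with caplog.at_level("WARNING", logger="lge_zmap"):
            thr, sens, spec = lz.youden_threshold(roc)
        assert sens + spec - 1 <= 0
        assert any("orientation" in r.message for r in caplog.records)


class TestCvEvaluate:
    def test_perfectly_separable_cohort(self):
        f = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        rep = lz.cv_evaluate(f, y, k=5, seed=1)
        assert rep.fold_aucs == [1.0] * 5
        assert rep.sd_auc == 0.0
        assert rep.mean_sensitivity == 1.0 and rep.mean_specificity == 1.0

    def test_determinism_under_seed(self, rng):
        f = rng.normal(size=22)
        y = np.r_[np.zeros(13, int), np.ones(9, int)]
        r1 = lz.cv_evaluate(f, y, k=5, seed=7)
        r2 = lz.cv_evaluate(f, y, k=5, seed=7)
        assert r1.as_dict() == r2.as_dict()

    def test_permuted_labels_near_chance(self):
        # null calibration: label permutation destroys any association
        rng = np.random.default_rng(3)
        aucs = []
        for s in range(60):
            f = rng.normal(size=22)
            y = np.r_[np.zeros(13, int), np.ones(9, int)]
            rng.shuffle(y)
            aucs.append(lz.cv_evaluate(f, y, k=5, seed=s).mean_auc)
        assert 0.4 < float(np.mean(aucs)) < 0.6

    def test_leave_one_out_degenerate_runs(self, rng):
        f = rng.normal(size=10)
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        rep = lz.cv_evaluate(f, y, k=10, seed=0)
        assert np.isfinite(rep.mean_auc)
        assert np.isfinite(rep.threshold)

    def test_class_smaller_than_k_rejected(self):
        f = np.arange(8.0)
        y = np.r_[np.zeros(6, int), np.ones(2, int)]
        with pytest.raises(lz.StratificationError):
            lz.cv_evaluate(f, y, k=4, seed=0)

    def test_mean_roc_grid(self, rng):
        f = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:5] = 1
        y[5:10] = 0
        rep = lz.cv_evaluate(f, y, k=5, seed=2)
        assert len(rep.mean_roc_fpr) == 101
        assert rep.mean_roc_tpr[0] >= 0 and rep.mean_roc_tpr[-1] == pytest.approx(1.0)

    def test_threshold_modes(self, rng):
        f = rng.normal(size=22)
        y = np.r_[np.zeros(13, int), np.ones(9, int)]
        full = lz.cv_evaluate(f, y, k=5, seed=7, threshold_mode="full")
        per = lz.cv_evaluate(f, y, k=5, seed=7, threshold_mode="per-fold")
        assert full.threshold == lz.youden_threshold(lz.roc_curve(f, y))[0]
        assert per.threshold == pytest.approx(float(np.mean(per.fold_thresholds)))


class TestPredictiveValues:
    def test_bayes_formulas(self):
        pv = lz.predictive_values(0.64, 0.74, 9 / 22)
        se, sp, p = 0.64, 0.74, 9 / 22
        assert pv.ppv == pytest.approx(se * p / (se * p + (1 - sp) * (1 - p)))
        assert pv.npv == pytest.approx(sp * (1 - p) / (sp * (1 - p) + (1 - se) * p))

    def test_perfect_test(self):
        pv = lz.predictive_values(1.0, 1.0, 0.3)
        assert pv.ppv == 1.0 and pv.npv == 1.0

    def test_counting_oracle_on_simulated_population(self, rng):
        # simulate a million-patient population and count the confusion matrix
        se, sp, p = 0.8, 0.9, 0.25
        n = 1_000_000
        disease = rng.random(n) < p
        test_pos = np.where(disease, rng.random(n) < se, rng.random(n) > sp)
        ppv_emp = disease[test_pos].mean()
        npv_emp = (~disease[~test_pos]).mean()
        pv = lz.predictive_values(se, sp, p)
        assert pv.ppv == pytest.approx(ppv_emp, abs=1e-3)
        assert pv.npv == pytest.approx(npv_emp, abs=1e-3)

    def test_monotone_in_prevalence(self):
        grid = np.linspace(0.05, 0.95, 19)
        ppvs = [lz.predictive_values(0.7, 0.8, p).ppv for p in grid]
        npvs = [lz.predictive_values(0.7, 0.8, p).npv for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(ppvs, ppvs[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(npvs, npvs[1:]))

    def test_undefined_denominator(self):
        with pytest.raises(lz.UndefinedValueError):
            lz.predictive_values(0.0, 1.0, 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lz.predictive_values(1.2, 0.5, 0.5)
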