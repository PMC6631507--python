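"""Harness contracts: Wilcoxon oracle, confusion matrices, grid semantics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sp_stats

from armband_bench.evaluation_stats import (
    EvalConfig, StatsConfig, compare_profiles, confusion_matrix,
    generate_study, last_cycle_experiment, report, run_comparison,
    wilcoxon_signed_rank,
)
from armband_bench.synthetic_semg import VariabilityConfig


def _enumerated_p(d):
    """Independent exact two-tailed p by brute-force sign enumeration:
    p = min(1, 2 * P(W+ <= min(W+, W-))) over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = sp_stats.rankdata(np.abs(d))
    n = d.size
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = sum(
        1 for signs in itertools.product([1, -1], repeat=n)
        if sum(r for r, s in zip(ranks, signs) if s > 0) <= w_obs + 1e-12)
    return min(1.0, 2.0 * count / 2.0**n)


class TestWilcoxon:
    def test_all_positive_n6(self):
        a = np.arange(1, 7, dtype=float)
        res = wilcoxon_signed_rank(a + np.array([1, 2, 3, 4, 5, 6]), a)
        assert res.pvalue == pytest.approx(2 / 64)

    def test_identical_samples_degenerate(self):
        a = np.ones(8)
        res = wilcoxon_signed_rank(a, a)
        assert res.degenerate and res.pvalue == 1.0

    def test_exact_matches_enumeration_small_n(self, rng):
        for n in (5, 7, 9, 12):
            for _ in range(5):
                d = rng.normal(0.2, 1.0, n)
                res = wilcoxon_signed_rank(d, np.zeros_like(d), method="exact")
                assert res.pvalue == pytest.approx(_enumerated_p(d), abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            a = rng.normal(0.3, 1.0, n)
            b = rng.normal(0.0, 1.0, n)
            ours = wilcoxon_signed_rank(a, b)
            ref = sp_stats.wilcoxon(a, b, mode="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
            assert ours.statistic == pytest.approx(ref.statistic)

    def test_exact_and_approx_branches_agree(self, rng):
        deltas = []
        for _ in range(100):
            a = rng.normal(0.2, 1.0, 22)
            b = rng.normal(0.0, 1.0, 22)
            exact = wilcoxon_signed_rank(a, b, method="exact").pvalue
            approx = wilcoxon_signed_rank(a, b, method="approx").pvalue
            deltas.append(abs(exact - approx))
        assert max(deltas) < 0.01

    def test_tie_handling_uses_approximation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.5, 0.5, 0.5, 1.0, 1.5, 2.0])  # tied |d|
        res = wilcoxon_signed_rank(a, b)
        ref = sp_stats.wilcoxon(a, b, mode="approx", correction=True)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=0.02)
        with pytest.raises(ValueError, match="tied"):
            wilcoxon_signed_rank(a, b, method="exact")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(3), np.ones(4))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(11), 3)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.diag(np.full(11, 3)))

    def test_totals_conserved(self, rng):
        t = rng.integers(0, 11, 500)
        p = rng.integers(0, 11, 500)
        cm = confusion_matrix(t, p)
        assert cm.sum() == 500
        assert np.array_equal(cm.sum(axis=1), np.bincount(t, minlength=11))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 11], [0, 1])


class TestStatsConfig:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=1.5)


class TestComparisonGrid:
    def test_oracle_and_random_reference_classifiers(self, small_study):
        cfg = EvalConfig(train_cycle_counts=(1,), n_runs_deep=1, seed=0)
        res = run_comparison(small_study, profiles=("3dc",),
                             classifiers=("oracle", "random"), config=cfg,
                             participants=[0])
        assert res.mean_accuracy("3dc", "oracle", 1) == 1.0
        acc_rand = res.mean_accuracy("3dc", "random", 1)
        n_windows = res.total_confusion("3dc", "random", 1).sum()
        sigma = np.sqrt((1 / 11) * (10 / 11) / n_windows)
        assert abs(acc_rand - 1 / 11) < 3 * sigma

    def test_lda_grid_is_deterministic(self, small_study):
        cfg = EvalConfig(train_cycle_counts=(1, 2), seed=3)
        r1 = run_comparison(small_study, classifiers=("lda",), config=cfg,
                            participants=[0, 1])
        r2 = run_comparison(small_study, classifiers=("lda",), config=cfg,
                            participants=[0, 1])
        assert r1.accuracy == r2.accuracy

    def test_confusion_row_sums_match_test_windows(self, small_study):
        cfg = EvalConfig(train_cycle_counts=(1,), seed=0)
        res = run_comparison(small_study, profiles=("myo",),
                             classifiers=("lda",), config=cfg, participants=[0])
        cm = res.total_confusion("myo", "lda", 1)
        # 4 test cycles x 20 windows per 5 s gesture
        assert np.all(cm.sum(axis=1) == 80)

    def test_unknown_names_rejected(self, small_study):
        with pytest.raises(KeyError):
            run_comparison(small_study, profiles=("gforce",))
        with pytest.raises(ValueError):
            run_comparison(small_study, classifiers=("svm",))

    def test_last_cycle_uses_one_cycle_of_data(self, small_study):
        cfg = EvalConfig(seed=0)
        res = last_cycle_experiment(small_study, ("lda",), cfg, profiles=("3dc",))
        assert res.meta["train_cycle_sets"] == {1: [3]}
        # same training-set size as the k=1 case: accuracies comparable scale
        assert 0.0 <= res.mean_accuracy("3dc", "lda", 1) <= 1.0

    def test_last_cycle_deterministic(self, small_study):
        cfg = EvalConfig(seed=0)
        a = last_cycle_experiment(small_study, ("lda",), cfg, profiles=("myo",))
        b = last_cycle_experiment(small_study, ("lda",), cfg, profiles=("myo",))
        assert a.accuracy == b.accuracy

    def test_cycles_exchangeable_without_drift(self):
        # with zero inter-cycle/session variability, first- and last-cycle
        # training are statistically equivalent
        still = VariabilityConfig(amp_jitter_sigma=0.0, cycle_rotation_sigma_deg=0.0,
                                  session_rotation_deg=0.0, session_gain_sigma=0.0)
        study = generate_study(n_participants=2, seed=5, variability=still)
        cfg = EvalConfig(seed=0)
        first = run_comparison(study, profiles=("3dc",), classifiers=("lda",),
                               config=cfg, train_cycle_sets={1: (0,)})
        last = run_comparison(study, profiles=("3dc",), classifiers=("lda",),
                              config=cfg, train_cycle_sets={1: (3,)})
        diff = abs(first.mean_accuracy("3dc", "lda", 1)
                   - last.mean_accuracy("3dc", "lda", 1))
        assert diff < 0.05


class TestDeepPipelineIntegration:
    def test_deep_classifiers_run_through_the_grid(self, small_study):
        # end-to-end check of both deep modalities on the narrowband profile
        # (small windows), at a few epochs
        from armband_bench.deep_models import TrainingConfig
        cfg = EvalConfig(train_cycle_counts=(1,), n_runs_deep=1, seed=0,
                         training=TrainingConfig(max_epochs=2))
        res = run_comparison(small_study, profiles=("myo",),
                             classifiers=("raw", "spectrogram"), config=cfg,
                             participants=[0])
        for clf in ("raw", "spectrogram"):
            acc = res.mean_accuracy("myo", clf, 1)
            assert 0.0 <= acc <= 1.0
            assert res.total_confusion("myo", clf, 1).sum() == 880


class TestReport:
    def test_report_outputs(self, small_study, tmp_path):
        import pandas as pd
        cfg = EvalConfig(train_cycle_counts=(1, 2), seed=0)
        res = run_comparison(small_study, classifiers=("lda",), config=cfg)
        written = report(res, tmp_path)
        summary = pd.read_csv(written["summary"])
        assert len(summary) == 2 * 1 * 2  # profiles x classifiers x k
        # sd computed across participants, not runs
        pp = res.per_participant("3dc", "lda", 1)
        row = summary[(summary.profile == "3dc") & (summary.n_train_cycles == 1)]
        assert row.sd_across_participants.iloc[0] == pytest.approx(np.std(pp, ddof=1))
        assert written["accuracy_lda"].exists()
        assert written["confusion_3dc_lda"].exists()

    def test_p_annotation_only_when_significant(self, tmp_path):
        import pandas as pd
        from armband_bench.evaluation_stats import ExperimentResult
        res = ExperimentResult()
        rng = np.random.default_rng(0)
        for pid in range(8):
            base = rng.uniform(0.5, 0.9)
            noise = rng.normal(0, 1e-3)
            res.accuracy[("3dc", "lda", 1, pid, 0)] = base + noise
            res.accuracy[("myo", "lda", 1, pid, 0)] = base - noise  # mixed signs
            res.accuracy[("3dc", "lda", 2, pid, 0)] = base + 0.10   # all positive
            res.accuracy[("myo", "lda", 2, pid, 0)] = base
            for key in list(res.accuracy):
                res.confusion.setdefault(key, np.eye(11, dtype=int))
        written = report(res, tmp_path)
        comp = pd.read_csv(written["comparison"], keep_default_na=False)
        k2 = comp[comp.n_train_cycles == 2].iloc[0]
        assert k2.p_value < 0.05 and k2.annotation.startswith("p=")
        k1 = comp[comp.n_train_cycles == 1].iloc[0]
        if k1.p_value >= 0.05:
            assert k1.annotation == ""
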