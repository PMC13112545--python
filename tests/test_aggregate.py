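"""RR-interval aggregation: counting, conservation, ranking, coloring."""

import numpy as np
import pytest

from ecgxai.aggregate import aggregate_importance, interval_color_values, rank_intervals
from ecgxai.beats import RPeakSet
from ecgxai.records import Rhythm
from ecgxai.xai import ImportanceVector


def _imp(values):
    return ImportanceVector(np.asarray(values, dtype=float), Rhythm.AFIB, "lime")


class TestAggregation:
    def test_unit_importance_counts_samples(self):
        values = np.ones(900)
        rpeaks = RPeakSet(indices=np.array([0, 300, 600]), fs=300.0)
        report = aggregate_importance(_imp(values), rpeaks)
        assert [s.raw_score for s in report.scores] == [300.0, 300.0]
        assert report.head_residual == 0.0
        assert report.tail_residual == 300.0

    def test_small_arithmetic_example(self):
        # fs low enough that peaks two samples apart respect refractoriness
        rpeaks = RPeakSet(indices=np.array([0, 2]), fs=10.0)
        report = aggregate_importance(_imp([1.0, -2.0, 3.0, 4.0]), rpeaks)
        assert report.scores[0].raw_score == -1.0
        assert report.tail_residual == 7.0
        assert report.conservation_check

    @pytest.mark.parametrize("trial", range(10))
    def test_conservation_on_random_inputs(self, trial):
        """Interval sums + residuals recover the total importance."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2000, 9000))
        values = rng.normal(size=n)
        idx = np.unique(rng.integers(0, n, size=20))
        idx = idx[np.r_[True, np.diff(idx) >= 60]]
        if idx.size < 2:
            idx = np.array([0, n - 1])
        report = aggregate_importance(_imp(values), RPeakSet(indices=idx, fs=300.0))
        total = sum(s.raw_score for s in report.scores)
        total += report.head_residual + report.tail_residual
        assert report.conservation_check
        assert total == pytest.approx(values.sum(), rel=1e-9, abs=1e-9)

    def test_misaligned_vector_rejected(self):
        rpeaks = RPeakSet(indices=np.array([0, 300]), fs=300.0)
        with pytest.raises(ValueError, match="aligned"):
            aggregate_importance(_imp(np.ones(500)), rpeaks, n_samples=600)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="beat detection"):
            aggregate_importance(_imp(np.ones(500)), RPeakSet(indices=np.array([5]), fs=300.0))

    def test_mean_statistic_divides_by_length(self):
        values = np.ones(900)
        rpeaks = RPeakSet(indices=np.array([0, 300, 900 - 1]), fs=300.0)
        report = aggregate_importance(_imp(values), rpeaks, statistic="mean")
        assert report.scores[0].raw_score == pytest.approx(1.0)
        assert report.scores[1].raw_score == pytest.approx(1.0)


class TestRanking:
    def _report(self, scores):
        n = 300 * (len(scores) + 1)
        values = np.zeros(n)
        idx = np.arange(0, n, 300)
        for i, s in enumerate(scores):
            values[i * 300] = s
        return aggregate_importance(_imp(values), RPeakSet(indices=idx, fs=300.0))

    def test_tie_broken_by_earlier_interval(self):
        report = self._report([5.0, 1.0, 5.0])
        top2 = rank_intervals(report, 2)
        assert [s.interval.start for s in top2] == [0, 600]

    def test_single_interval(self):
        report = self._report([2.0])
        assert rank_intervals(report, 1)[0].raw_score == 2.0

    def test_oversized_k_warns_and_returns_all(self):
        report = self._report([1.0, 2.0])
        with pytest.warns(UserWarning):
            assert len(rank_intervals(report, 10)) == 2

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=15).tolist()
        report = self._report(scores)
        ranked = rank_intervals(report, 15)
        oracle = sorted(
            report.scores, key=lambda s: (-s.raw_score, s.interval.start)
        )
        assert [s.interval.start for s in ranked] == [s.interval.start for s in oracle]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(12)
        report = self._report(rng.normal(size=12).tolist())
        assert sorted(s.rank for s in report.scores) == list(range(1, 13))


class TestMethodAgreement:
    def test_lime_and_shap_interval_scores_corroborate(self, timing_contrast_model):
        """On the P-wave-contrast study model the two attribution routes
        rank RR intervals consistently (mean Spearman >= 0 over a panel
        of AFib records)."""
        from dataclasses import replace

        from scipy.stats import spearmanr

        from ecgxai.beats import detect_rpeaks
        from ecgxai.preprocessing import preprocess
        from ecgxai.synth import synth_record
        from ecgxai.xai import lime_explain, shap_explain

        model, afib_base = timing_contrast_model
        rhos = []
        for i in range(6):
            record, _ = synth_record(replace(afib_base, seed=7000 + i), f"agree{i}")
            record = preprocess(record)
            rpeaks = detect_rpeaks(record)
            lime_scores = aggregate_importance(
                lime_explain(model, record, n_perturb=400, seed=i),
                rpeaks, n_samples=record.n_samples,
            )
            shap_scores = aggregate_importance(
                shap_explain(model, record, n_coalitions=600, seed=i),
                rpeaks, n_samples=record.n_samples,
            )
            rhos.append(
                spearmanr(
                    [s.raw_score for s in lime_scores.scores],
                    [s.raw_score for s in shap_scores.scores],
                ).statistic
            )
        assert np.mean(rhos) >= 0.0


class TestColoring:
    def test_zero_importance_is_neutral(self):
        values = np.zeros(900)
        report = aggregate_importance(
            _imp(values), RPeakSet(indices=np.array([0, 300, 600]), fs=300.0)
        )
        assert interval_color_values(report) == [0.0, 0.0]

    def test_strongest_interval_saturates(self):
        values = np.zeros(900)
        values[350] = 2.0
        values[50] = -1.0
        report = aggregate_importance(
            _imp(values), RPeakSet(indices=np.array([0, 300, 600]), fs=300.0)
        )
        colors = interval_color_values(report)
        assert max(colors) == 1.0

    def test_sign_follows_raw_score(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=1500)
        report = aggregate_importance(
            _imp(values), RPeakSet(indices=np.arange(0, 1500, 300), fs=300.0)
        )
        for s, c in zip(report.scores, interval_color_values(report)):
            assert np.sign(c) == np.sign(s.raw_score)
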