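"""Phase orchestration, bootstrap, trajectories, peaks, recurrence."""

import numpy as np
import pytest

import serumrna as sr
from serumrna.trajectory import WindowSummary
from serumrna.windows import WindowSpec


def _summary(center, n_de_by_class, label=None, width=17.0):
    start = max(0.0, center - width / 2)
    w = WindowSpec(start, start + width, label=label or f"w{center}")
    total = sum(n_de_by_class.values())
    ids = [f"{cls}_{i}" for cls, n in n_de_by_class.items() for i in range(n)]
    return WindowSummary(
        window=w, n_de=total, n_de_by_class=dict(n_de_by_class),
        de_rna_ids=ids, direction={i: 1 for i in ids}, n_tested=100,
    )


class TestRunPhase:
    def test_phase1_single_summary(self, cfg, small_cohort):
        samples, counts, _ = small_cohort
        summaries = sr.run_phase(samples, counts, 1, cfg, seed=0)
        assert len(summaries) == 1
        assert summaries[0].n_cases == sum(s.group == "case" for s in samples)
        assert summaries[0].n_controls == sum(s.group == "control" for s in samples)

    def test_phase2_has_seven_windows(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        summaries = sr.run_phase(samples, counts, 2, cfg, seed=1)
        assert len(summaries) == 7
        filled = [s for s in summaries if not s.skipped]
        assert all((s.n_cases, s.n_controls) == (27, 135) for s in filled)
        assert len(filled) == 7

    def test_phase4_has_42_windows(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        summaries = sr.run_phase(samples, counts, 4, cfg, seed=2)
        assert len(summaries) == 42

    def test_null_cohort_yields_near_zero_signal(self, cfg, full_null_cohort):
        """On a null cohort the per-window DE counts are FDR noise only."""
        samples, counts, _ = full_null_cohort
        summaries = sr.run_phase(samples, counts, 2, cfg, seed=3)
        n_de = [s.n_de for s in summaries if not s.skipped]
        n_tested = max(s.n_tested for s in summaries)
        assert np.median(n_de) == 0
        assert sum(n_de) <= 0.01 * n_tested * len(n_de)

    def test_phase3_requires_stage(self, cfg, small_cohort):
        samples, counts, _ = small_cohort
        with pytest.raises(ValueError, match="stage_filter"):
            sr.run_phase(samples, counts, 3, cfg, seed=0)

    def test_phase3_runs_stage_specific_quota(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        summaries = sr.run_phase(samples, counts, 3, cfg, stage_filter="advanced", seed=4)
        filled = [s for s in summaries if not s.skipped]
        assert filled and all((s.n_cases, s.n_controls) == (18, 90) for s in filled)

    def test_infeasible_window_skipped_not_fatal(self, cfg, small_cohort):
        samples, counts, _ = small_cohort  # far too few cases for quota 27
        summaries = sr.run_phase(samples, counts, 2, cfg, seed=5)
        assert len(summaries) == 7
        assert any(s.skipped for s in summaries)

    def test_pipeline_determinism(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        a = sr.run_phase(samples, counts, 2, cfg, seed=6)
        b = sr.run_phase(samples, counts, 2, cfg, seed=6)
        assert [s.n_de for s in a] == [s.n_de for s in b]
        assert [s.de_rna_ids for s in a] == [s.de_rna_ids for s in b]


class TestTrajectory:
    def test_single_window_tabulation(self):
        traj = sr.build_trajectory([_summary(30, {"piRNA": 2, "tRF": 1})])
        assert traj.total.tolist() == [3]
        assert traj.per_class["piRNA"].tolist() == [2]
        assert traj.per_class["tRF"].tolist() == [1]

    def test_class_counts_sum_to_total(self):
        summaries = [_summary(c, {"miRNA": c % 3, "mRNA": (c // 10) % 2}) for c in (20, 40, 60)]
        traj = sr.build_trajectory(summaries)
        stacked = np.sum([traj.per_class[c] for c in traj.per_class], axis=0)
        assert np.array_equal(stacked, traj.total)

    def test_effect_weighted_signal(self):
        s = _summary(30, {"piRNA": 2})
        s.weighted = 4.2
        traj = sr.build_trajectory([s], signal="effect")
        assert traj.total.tolist() == [4.2]
        with pytest.raises(ValueError, match="signal"):
            sr.build_trajectory([s], signal="density")

    def test_window_resampling_aggregates_mean_signal(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        cfg_small = sr.StudyConfig(sliding_step_months=17.0)  # few windows, fast
        summaries = sr.run_phase(samples, counts, 4, cfg_small, seed=7, n_resample=2)
        for s in summaries:
            if not s.skipped:
                assert len(s.n_de_values) == 2
                assert s.n_de_mean == pytest.approx(np.mean(s.n_de_values))

    def test_order_invariance(self):
        summaries = [_summary(c, {"miRNA": i}) for i, c in enumerate((20, 40, 60))]
        a = sr.build_trajectory(summaries)
        b = sr.build_trajectory(summaries[::-1])
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.total, b.total)


class TestDetectPeaks:
    def test_flat_zero_series(self):
        traj = sr.build_trajectory([_summary(c, {}) for c in (20, 40, 60, 80)])
        assert sr.detect_peaks(traj, min_height=1) == []

    def test_two_bumps_respect_separation(self):
        counts = {20: 1, 30: 8, 40: 2, 50: 1, 60: 3, 70: 9, 80: 2}
        summaries = [_summary(c, {"miRNA": n}) for c, n in counts.items()]
        traj = sr.build_trajectory(summaries)
        assert sr.detect_peaks(traj, min_height=2, min_separation_months=20) == [30, 70]
        # tight separation keeps only the higher bump
        assert sr.detect_peaks(traj, min_height=2, min_separation_months=50) == [70]

    def test_short_series_rejected(self):
        traj = sr.build_trajectory([_summary(20, {"miRNA": 1}), _summary(40, {"miRNA": 2})])
        with pytest.raises(ValueError, match=">= 3"):
            sr.detect_peaks(traj)


class TestRecurrentRNAs:
    def test_multi_window_rna_reported_with_signs(self):
        a = _summary(20, {}, label="w1")
        a.de_rna_ids, a.direction, a.n_de = ["x", "y"], {"x": 1, "y": -1}, 2
        b = _summary(50, {}, label="w4")
        b.de_rna_ids, b.direction, b.n_de = ["x"], {"x": -1}, 1
        rec = sr.recurrent_rnas([a, b], min_windows=2)
        assert rec == [("x", ["w1", "w4"], [1, -1])]
        assert len(sr.recurrent_rnas([a, b], min_windows=1)) == 2

    def test_null_cohort_has_no_recurrent_rnas(self, cfg, full_null_cohort):
        samples, counts, _ = full_null_cohort
        summaries = sr.run_phase(samples, counts, 2, cfg, seed=8)
        assert len(sr.recurrent_rnas(summaries, min_windows=2)) == 0


class TestBootstrap:
    def test_single_iteration_has_no_sd(self, full_null_cohort):
        samples, counts, _ = full_null_cohort
        cfg1 = sr.StudyConfig(n_bootstrap=1)
        summary = sr.bootstrap_phase3(samples, counts, "advanced", cfg1, seed=0)
        w = summary.windows[0]
        assert w.n_iter == 1
        assert np.isnan(w.sd)
        assert w.mean == w.n_de_values[0]

    def test_two_year_window_variant_has_five_windows(self, full_null_cohort):
        samples, counts, _ = full_null_cohort
        cfg1 = sr.StudyConfig(n_bootstrap=1)
        summary = sr.bootstrap_phase3(
            samples, counts, "advanced", cfg1, seed=2, window_months=24.0
        )
        assert len(summary.windows) == 5
        assert summary.windows[0].window.end_months == pytest.approx(24.0)

    def test_signal_window_separates_from_null_windows(self, cfg):
        """A strong injected bump makes its window's minimum bootstrap signal
        exceed every other window's maximum."""
        cfg_b = sr.StudyConfig(n_bootstrap=5)
        base_samples, base_counts, _ = sr.generate_cohort(sr.StudyConfig(), n_rnas=150, seed=31)
        profiles = sr.make_signal_profiles(
            base_counts.rna_ids, 0.30, 2.0, 60.0, 6.0, seed=3
        )
        samples, counts, _ = sr.generate_cohort(
            sr.StudyConfig(), n_rnas=150, signal_spec=profiles, seed=31
        )
        summary = sr.bootstrap_phase3(samples, counts, "advanced", cfg_b, seed=1)
        # 60 months falls in fixed window 3 ([51.4, 68.6))
        target = summary.windows[3]
        others = [w for i, w in enumerate(summary.windows) if i != 3]
        assert target.min > max(w.max for w in others)
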