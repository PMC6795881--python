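"""Block summaries, day averages, persistence regression, pre/post windows."""

import numpy as np
import pandas as pd
import pytest

from megaim.behavioral_metrics import (
    day_summaries,
    day_summary,
    group_table,
    persistence_regression,
    pre_post_display,
    summarize_block,
    summarize_blocks,
)
from megaim.optimal_aim import optimal_aim_gaussian
from megaim.task_model import TrialRecord, trials_to_frame


def block_frame(endpoints, timeouts=None, block=1, pid="P01", group="display"):
    n = len(endpoints)
    timeouts = timeouts or [False] * n
    return trials_to_frame([
        TrialRecord(pid, group, 1 if block <= 7 else 2, block, t + 1,
                    None if timeouts[t] else float(endpoints[t]), timeouts[t])
        for t in range(n)
    ])


class TestSummarizeBlock:
    def test_risk_neutral_by_construction(self, gf):
        # symmetric endpoints have a known SD; recentre them on the optimum
        # for that SD so that E_obs == E_opt and rs == 0
        base = np.array([-2.0, -1.0, 1.0, 2.0] * 5)
        e_opt, _ = optimal_aim_gaussian(float(np.std(base, ddof=1)), gf)
        summary = summarize_block(block_frame(base + e_opt), gf)
        assert summary.rs_cm == pytest.approx(0.0, abs=1e-9)
        assert summary.abs_rs_cm == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_risk_offset(self, gf):
        rng = np.random.default_rng(0)
        e_opt, _ = optimal_aim_gaussian(2.0, gf)
        endpoints = rng.normal(e_opt + 1.0, 2.0, size=50)
        summary = summarize_block(block_frame(endpoints), gf)
        assert summary.rs_cm == pytest.approx(1.0, abs=3 * 2.0 / np.sqrt(50))

    def test_positive_rs_is_risk_seeking_side(self, gf):
        rng = np.random.default_rng(1)
        e_opt, _ = optimal_aim_gaussian(2.0, gf)
        endpoints = rng.normal(e_opt + 1.5, 2.0, size=50)
        summary = summarize_block(block_frame(endpoints), gf)
        assert summary.e_obs_cm > summary.e_opt_cm
        assert summary.rs_cm > 0

    def test_trial_order_invariance(self, gf):
        rng = np.random.default_rng(2)
        endpoints = rng.normal(26.0, 2.0, size=50)
        a = summarize_block(block_frame(endpoints), gf)
        b = summarize_block(block_frame(endpoints[::-1]), gf)
        assert a == b

    def test_timeouts_excluded_and_counted(self, gf):
        rng = np.random.default_rng(3)
        endpoints = rng.normal(26.0, 2.0, size=50)
        timeouts = [i % 10 == 0 for i in range(50)]
        df = block_frame([None if t else e for e, t in zip(endpoints, timeouts)],
                         timeouts)
        summary = summarize_block(df, gf)
        assert summary.n_valid == 45
        assert summary.n_timeout == 5
        assert summary.n_valid + summary.n_timeout == 50

    def test_overshoots_included_by_default_excluded_on_request(self, gf):
        endpoints = [25.0, 26.0, 27.0, 31.0]
        with_over = summarize_block(block_frame(endpoints), gf)
        without = summarize_block(block_frame(endpoints), gf, include_overshoots=False)
        assert with_over.miss_rate == pytest.approx(0.25)
        assert without.sd_cm < with_over.sd_cm

    def test_too_few_valid_trials_flagged_invalid(self, gf, caplog):
        df = block_frame([26.0, None, None], [False, True, True])
        with caplog.at_level("WARNING"):
            assert summarize_block(df, gf) is None
        assert "flagged invalid" in caplog.text

    def test_zero_variance_flagged_invalid(self, gf):
        assert summarize_block(block_frame([26.0] * 10), gf) is None


class TestDaySummary:
    @staticmethod
    def summaries_frame(rs_by_block, pid="P01", group="display"):
        rows = []
        for block, rs in rs_by_block.items():
            rows.append({
                "participant_id": pid, "group": group,
                "day": 1 if block <= 7 else 2, "block": block,
                "n_valid": 50, "n_timeout": 0, "e_obs_cm": 26.0 + rs,
                "sd_cm": 2.0, "e_opt_cm": 26.0, "eg_max_points": 80.0,
                "rs_cm": rs, "abs_rs_cm": abs(rs), "miss_rate": 0.0,
            })
        return pd.DataFrame(rows)

    def test_constant_rs_passes_through(self):
        s = self.summaries_frame({b: 0.3 for b in range(1, 8)})
        out = day_summary(s, day=1)
        assert out.mean_rs_cm == pytest.approx(0.3)
        assert out.included_blocks == tuple(range(2, 8))

    def test_sign_cancellation_vs_absolute(self):
        s = self.summaries_frame({9: 0.5, 10: -0.5})
        out = day_summary(s, day=2, included_blocks=(9, 10))
        assert out.mean_rs_cm == pytest.approx(0.0)
        assert out.mean_abs_rs_cm == pytest.approx(0.5)

    def test_missing_blocks_reported(self):
        s = self.summaries_frame({b: 0.1 for b in (2, 3, 4)})
        with pytest.raises(ValueError, match=r"\[5, 6, 7\]"):
            day_summary(s, day=1)

    def test_recovers_constant_offset_over_six_blocks(self, gf):
        rng = np.random.default_rng(4)
        e_opt, _ = optimal_aim_gaussian(2.0, gf)
        frames = [block_frame(rng.normal(e_opt + 0.4, 2.0, size=50), block=b)
                  for b in range(8, 15)]
        summaries = summarize_blocks(pd.concat(frames, ignore_index=True), gf)
        out = day_summary(summaries, day=2)
        assert out.mean_rs_cm == pytest.approx(0.4, abs=3 * 2.0 / np.sqrt(300))


class TestPersistenceRegression:
    def test_identity_line(self):
        x = np.array([-0.5, -0.2, 0.1, 0.4, 0.8])
        fit = persistence_regression(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_known_slope_within_ci(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-0.8, 0.8, size=10)
        y = 0.7 * x + rng.normal(0, 0.05, size=10)
        fit = persistence_regression(x, y)
        assert fit.slope_ci_low <= 0.7 <= fit.slope_ci_high
        assert fit.n == 10

    def test_outlier_sensitivity_smoke(self):
        rng = np.random.default_rng(6)
        x = np.append(rng.uniform(-0.5, 0.5, size=9), 3.0)
        y = 0.7 * x + rng.normal(0, 0.05, size=10)
        full = persistence_regression(x, y)
        trimmed = persistence_regression(x[:-1], y[:-1])
        assert np.isfinite(full.slope) and np.isfinite(trimmed.slope)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            persistence_regression([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            persistence_regression([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])


class TestPrePostDisplay:
    @staticmethod
    def day2_trials(rng, gf, pre_offset, post_offset, sd=2.0, pid="P01"):
        """Blocks 8-14 whose first 10 trials carry post_offset and last 10
        pre_offset relative to the optimum (middle trials at pre_offset)."""
        e_opt, _ = optimal_aim_gaussian(sd, gf)
        frames = []
        for block in range(8, 15):
            offsets = np.full(50, pre_offset)
            offsets[:10] = post_offset
            endpoints = rng.normal(e_opt + offsets, sd)
            frames.append(block_frame(endpoints, block=block, pid=pid))
        return pd.concat(frames, ignore_index=True)

    def test_six_transitions_reported(self, gf):
        rng = np.random.default_rng(7)
        out = pre_post_display(self.day2_trials(rng, gf, 0.5, 0.5), gf)
        assert list(out["pre_block"]) == [8, 9, 10, 11, 12, 13]
        assert list(out["post_block"]) == [9, 10, 11, 12, 13, 14]

    def test_jump_to_optimum_reduces_post_abs_rs(self, gf):
        rng = np.random.default_rng(8)
        pre, post = [], []
        for p in range(40):
            out = pre_post_display(
                self.day2_trials(rng, gf, pre_offset=2.5, post_offset=0.0,
                                 pid=f"P{p:02d}"), gf)
            pre.append(out["pre_abs_rs_cm"].mean())
            post.append(out["post_abs_rs_cm"].mean())
        assert np.mean(post) < np.mean(pre)

    def test_sparse_window_skips_transition(self, gf, caplog):
        rng = np.random.default_rng(9)
        trials = self.day2_trials(rng, gf, 0.5, 0.5)
        # knock out most of block 9's first window
        mask = (trials["block"] == 9) & (trials["trial"] <= 8)
        trials.loc[mask, "timeout"] = True
        trials.loc[mask, ["endpoint_cm", "points"]] = np.nan
        with caplog.at_level("WARNING"):
            out = pre_post_display(trials, gf)
        assert 9 not in set(out["post_block"])
        assert "skipped" in caplog.text


class TestGroupTable:
    def test_cloned_participants_have_zero_sem(self, gf):
        rng = np.random.default_rng(10)
        endpoints = rng.normal(26.0, 2.0, size=50)
        frames = [block_frame(endpoints, block=1, pid=f"P{i}") for i in range(4)]
        summaries = summarize_blocks(pd.concat(frames, ignore_index=True), gf)
        table = group_table(summaries)
        assert table["sem_rs_cm"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_cohort_layout(self, cohort_summaries):
        table = group_table(cohort_summaries)
        assert len(table) == 2 * 14
        assert set(table["group"]) == {"display", "no_display"}
        assert set(table["n"]) == {10, 11}

    def test_group_means_recover_generative_offsets(self, gf):
        rng = np.random.default_rng(11)
        e_opt, _ = optimal_aim_gaussian(2.0, gf)
        frames = []
        for group, offset, n in (("display", 0.5, 8), ("no_display", -0.4, 8)):
            for i in range(n):
                frames.append(block_frame(
                    rng.normal(e_opt + offset, 2.0, size=50),
                    block=1, pid=f"{group}{i}", group=group))
        table = group_table(summarize_blocks(pd.concat(frames, ignore_index=True), gf))
        for group, offset in (("display", 0.5), ("no_display", -0.4)):
            row = table[table["group"] == group].iloc[0]
            assert row["mean_rs_cm"] == pytest.approx(
                offset, abs=max(3 * row["sem_rs_cm"], 0.3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_table(pd.DataFrame())


def test_day_summaries_cover_cohort(cohort_summaries):
    days = day_summaries(cohort_summaries)
    assert len(days) == 21 * 2
    assert set(days["day"]) == {1, 2}
    assert (days["mean_abs_rs_cm"] >= 0).all()
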