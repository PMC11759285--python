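import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import sfi_timing as st
from sfi_timing.transitions import (
    TransitionModel,
    adaptation_latency,
    blockwise_means,
    build_transition_records,
    classify_transition,
    normalized_adaptation_curves,
    post_transition_correlations,
)

DUR = [12.0, 24.0, 36.0, 48.0, 60.0]


def table_from_blocks(blocks, subject="s", day=1, value=None):
    """Synthetic start-time table: blocks = [(fi, [values...]), ...].

    All four metric columns get the same values, so analyses of any
    metric can be cross-checked against the constructed truth.
    """
    rows = []
    for b, (fi, vals) in enumerate(blocks, start=1):
        for j, v in enumerate(vals, start=1):
            rows.append({
                "subject_id": subject, "day": day, "block_index": b,
                "trial_index_in_block": j, "fi_duration": fi,
                "first_press": v, "first_burst": v,
                "rate_increase": v, "change_point": v,
            })
    return pd.DataFrame(rows)


class TestBlockwiseMeans:
    def test_pairwise_deletion_and_all_missing(self):
        tab = table_from_blocks([(24.0, [10.0, 20.0, math.nan]),
                                 (48.0, [math.nan, math.nan])])
        bm = blockwise_means(tab)
        assert bm.loc[bm.block_index == 1, "first_press"].iloc[0] == pytest.approx(15.0)
        assert math.isnan(bm.loc[bm.block_index == 2, "first_press"].iloc[0])

    def test_constant_block(self):
        tab = table_from_blocks([(24.0, [7.0, 7.0, 7.0])])
        bm = blockwise_means(tab)
        assert bm["first_burst"].iloc[0] == pytest.approx(7.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            blockwise_means(table_from_blocks([]))


class TestClassifyTransition:
    @pytest.mark.parametrize("prev,nxt,direction,magnitude", [
        (36.0, 48.0, "increase", "small"),
        (60.0, 24.0, "decrease", "large"),
        (60.0, 12.0, "decrease", "large"),
        (12.0, 36.0, "increase", "intermediate"),
        (24.0, 12.0, "decrease", "small"),
    ])
    def test_direction_and_magnitude(self, prev, nxt, direction, magnitude):
        assert classify_transition(prev, nxt, DUR) == (direction, magnitude)

    def test_unknown_fi_rejected(self):
        with pytest.raises(ValueError):
            classify_transition(10.0, 24.0, DUR)

    def test_equal_fis_rejected(self):
        with pytest.raises(ValueError):
            classify_transition(24.0, 24.0, DUR)


class TestBuildRecords:
    def five_block_table(self):
        blocks = [(fi, [10.0 + fi / 10] * 4) for fi in (24.0, 12.0, 48.0, 36.0, 60.0)]
        return table_from_blocks(blocks)

    def test_record_count_bounded_by_boundaries(self):
        recs = build_transition_records(self.five_block_table(), "first_press")
        assert len(recs) == 4

    def test_shortest_duration_excluded_for_rate_metrics(self):
        tab = self.five_block_table()
        fp = build_transition_records(tab, "first_press")
        fb = build_transition_records(tab, "first_burst")
        fp_pairs = {(r.prev_fi, r.next_fi) for r in fp}
        fb_pairs = {(r.prev_fi, r.next_fi) for r in fb}
        assert (24.0, 12.0) in fp_pairs and (12.0, 48.0) in fp_pairs
        assert all(12.0 not in pair for pair in fb_pairs)
        assert fb_pairs == {(48.0, 36.0), (36.0, 60.0)}

    def test_missing_prev_block_mean_drops_record(self):
        blocks = [(24.0, [math.nan] * 3), (48.0, [20.0] * 3)]
        recs = build_transition_records(table_from_blocks(blocks), "first_press")
        assert recs == []

    def test_post_values_follow_trial_order_and_pad(self):
        blocks = [(24.0, [12.0, 12.0]), (48.0, [12.0, 24.0, 24.0])]
        recs = build_transition_records(
            table_from_blocks(blocks), "first_press", n_post_trials=5)
        (r,) = recs
        assert r.post_trial_values[:3] == pytest.approx([12.0, 24.0, 24.0])
        assert np.isnan(r.post_trial_values[3:]).all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            build_transition_records(self.five_block_table(), "not_a_metric")


class TestNormalization:
    def test_previous_block_mean_normalizes_to_100(self):
        blocks = [(24.0, [10.0, 14.0]), (48.0, [12.0, 12.0, 12.0])]
        recs = build_transition_records(table_from_blocks(blocks), "first_press")
        # post values equal to the previous-block mean (12.0) -> 100 %
        curves = normalized_adaptation_curves(recs)
        c = curves["increase"]
        assert c["mean_pct"].iloc[:3].tolist() == pytest.approx([100.0] * 3)

    def test_one_shot_closed_form_jump(self):
        # ideal one-shot agent: trial 1 still at the old target, then an
        # exact jump to the new target (new/prev * 100 %)
        blocks = [(24.0, [12.0] * 4), (48.0, [12.0] + [24.0] * 3)]
        recs = build_transition_records(table_from_blocks(blocks), "first_press")
        c = normalized_adaptation_curves(recs)["increase"]
        assert c["mean_pct"].iloc[0] == pytest.approx(100.0)
        assert c["mean_pct"].iloc[1:4].tolist() == pytest.approx([200.0] * 3)

    def test_gradual_delta_rule_monotone_approach(self):
        prev_fi, next_fi, alpha = 24.0, 48.0, 0.2
        est, vals = prev_fi, []
        for _ in range(8):
            vals.append(0.5 * est)
            est = est + alpha * (next_fi - est)
        blocks = [(prev_fi, [12.0] * 4), (next_fi, vals)]
        recs = build_transition_records(
            table_from_blocks(blocks), "first_press", n_post_trials=8)
        c = normalized_adaptation_curves(recs)["increase"]
        m = c["mean_pct"].to_numpy()
        assert np.all(np.diff(m) > 0)
        assert m[0] == pytest.approx(100.0)
        assert m[-1] < 200.0  # approaches but never exceeds the target


class TestCorrelations:
    def test_perfect_linear_scaling(self):
        blocks = [(12.0, [6.0] * 3), (24.0, [12.0] * 3), (36.0, [18.0] * 3),
                  (48.0, [24.0] * 3), (60.0, [30.0] * 3)]
        tab = table_from_blocks(blocks)
        out = post_transition_correlations(tab, "first_press", trial_index=2)
        assert out["r"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_fi_gives_missing(self):
        blocks = [(24.0, [6.0] * 3), (24.0, [8.0] * 3), (24.0, [7.0] * 3)]
        out = post_transition_correlations(
            table_from_blocks(blocks), "first_press", trial_index=1)
        assert math.isnan(out["r"])

    def test_block_one_excluded(self):
        blocks = [(12.0, [100.0] * 3), (24.0, [12.0] * 3), (36.0, [18.0] * 3),
                  (48.0, [24.0] * 3), (60.0, [30.0] * 3)]
        out = post_transition_correlations(
            table_from_blocks(blocks), "first_press", trial_index=1)
        assert out["n"] == 4  # block 1's aberrant value never enters
        assert out["r"] == pytest.approx(1.0)

    def test_fewer_than_three_pairs_missing(self):
        blocks = [(12.0, [6.0]), (24.0, [12.0]), (36.0, [18.0])]
        out = post_transition_correlations(
            table_from_blocks(blocks), "first_press", trial_index=2)
        assert math.isnan(out["r"]) and out["n"] < 3


class TestAdaptationLatency:
    def test_flat_curves_never_deviate(self):
        blocks = [(24.0, [12.0] * 4), (48.0, [12.0] * 4)]
        recs = build_transition_records(table_from_blocks(blocks), "first_press")
        lat, table = adaptation_latency(recs)
        assert lat is None
        assert (table["p_holm"] >= 0.05).all()

    def test_one_shot_cohort_adapts_on_trial_two(self, one_shot_table):
        res = TransitionModel(one_shot_table).fit()
        assert res.earliest_adaptation("increase") == 2
        assert res.earliest_adaptation("decrease") == 2

    def test_latency_non_increasing_in_learning_rate(self):
        latencies = []
        for alpha in (1.0, 0.5, 0.2, 0.05):
            params = dataclasses.replace(
                st.PRESETS["rat_fast"], learning_rate=alpha)
            cohort = st.simulate_cohort(
                st.Protocol(), params, n_subjects=10, master_seed=8)
            res = TransitionModel(st.estimate_all(cohort)).fit()
            lat = res.earliest_adaptation("increase")
            latencies.append(math.inf if lat is None else lat)
        assert latencies == sorted(latencies)
        assert latencies[0] == 2
        assert latencies[-1] > 2

    def test_large_jumps_exceed_small_jumps_on_trial_two(self, one_shot_table):
        recs = build_transition_records(one_shot_table, "first_press")
        jump = {}
        for mag in ("small", "large"):
            sel = [r for r in recs
                   if r.direction == "increase" and r.magnitude_class == mag]
            m = np.vstack([r.normalized() for r in sel])
            jump[mag] = np.nanmean(m[:, 1])
        assert jump["large"] > jump["small"]


class TestDirectionSymmetry:
    def test_reversing_block_order_swaps_directions(self, one_shot_table):
        tab = one_shot_table.copy()
        rev = tab.copy()
        for (s, d), sub in tab.groupby(["subject_id", "day"]):
            top = sub["block_index"].max()
            sel = (rev.subject_id == s) & (rev.day == d)
            rev.loc[sel, "block_index"] = top + 1 - rev.loc[sel, "block_index"]
        fwd_recs = build_transition_records(tab, "first_press")
        rev_recs = build_transition_records(rev, "first_press")
        fwd = sorted((r.subject_id, r.day, r.prev_fi, r.next_fi) for r in fwd_recs)
        swapped = sorted((r.subject_id, r.day, r.next_fi, r.prev_fi) for r in rev_recs)
        assert fwd == swapped
        n_inc = sum(r.direction == "increase" for r in fwd_recs)
        n_dec_rev = sum(r.direction == "decrease" for r in rev_recs)
        assert n_inc == n_dec_rev


class TestModelApi:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            TransitionModel(pd.DataFrame({"subject_id": []}))

    def test_fit_produces_summary_and_tables(self, one_shot_table):
        res = TransitionModel(one_shot_table).fit()
        text = res.summary()
        assert "Adaptation latency" in text and "Pearson" in text
        assert set(res.latencies["metric"]) == set(res.model.metrics)
        rf = res.records_frame("first_press")
        assert {"prev_fi", "next_fi", "post_trial", "normalized_pct"} <= set(rf.columns)
        assert res.curve("first_press", "increase")["n"].iloc[0] > 0

    def test_from_sessions_roundtrip(self, one_shot_cohort):
        res = TransitionModel.from_sessions(one_shot_cohort[:4]).fit()
        assert not res.latencies.empty
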