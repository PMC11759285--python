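"""Adaptation of start times across uncued FI block transitions.

The analysis asks how fast the animal's start times move after the FI
duration changes between blocks.  Each block boundary yields a
transition record: the previous block's mean start time (the baseline),
the direction of the change (increase/decrease), a magnitude class
(small = adjacent durations on the list, large = separated by at least
two intervening durations, intermediate = exactly one in between), and
the start times of the first T trials under the new duration.  Post-
transition values are normalized to the previous-block mean (100 % = no
change), records are aggregated into adaptation curves per direction,
and the adaptation latency is the first post-transition trial whose
normalized values deviate significantly from 100 % (one-sample test,
Holm-corrected across trials).  A complementary view correlates start
times with FI duration at fixed post-transition trial index: the
correlation is absent on trial 1 (the animal cannot yet know the FI
changed) and builds up over the next trials.

Exposed statsmodels-style: build a :class:`TransitionModel` from a
start-time table, call :meth:`~TransitionModel.fit`, and read curves,
latencies and correlations off the :class:`TransitionResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_COLUMNS

__all__ = [
    "TransitionRecord",
    "TransitionModel",
    "TransitionResults",
    "blockwise_means",
    "classify_transition",
    "build_transition_records",
    "normalized_adaptation_curves",
    "post_transition_correlations",
    "adaptation_latency",
]

#: Metrics for which transitions to/from the shortest duration are
#: dropped (sparse pressing on the shortest FI makes them unreliable).
SHORT_EXCLUDED_METRICS = ("first_burst", "rate_increase", "change_point")


@dataclass
class TransitionRecord:
    """One block boundary for one metric."""

    subject_id: str
    day: int
    transition_index: int
    prev_fi: float
    next_fi: float
    direction: str
    magnitude_class: str
    prev_block_mean: float
    post_trial_values: np.ndarray  # length T, NaN-padded

    def normalized(self) -> np.ndarray:
        """Post-transition values as % of the previous-block mean."""
        return 100.0 * self.post_trial_values / self.prev_block_mean


def blockwise_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, day, block) means of each metric, NaNs excluded.

    A block's mean for a metric is missing when every trial is missing.
    """
    if table.empty:
        raise ValueError("start-time table is empty")
    g = table.groupby(["subject_id", "day", "block_index"], sort=True)
    out = g[list(METRIC_COLUMNS)].mean()
    out["fi_duration"] = g["fi_duration"].first()
    out["n_trials"] = g.size()
    return out.reset_index()


def classify_transition(
    prev_fi: float, next_fi: float, duration_list: list[float]
) -> tuple[str, str]:
    """Direction and magnitude class of one FI change.

    Magnitude keys on the rank gap within the ordered duration list:
    gap 1 (adjacent) is ``small``, gap >= 3 (at least two durations
    strictly in between) is ``large``, gap 2 is ``intermediate``.
    """
    durs = sorted(duration_list)
    try:
        r_prev, r_next = durs.index(prev_fi), durs.index(next_fi)
    except ValueError as e:
        raise ValueError(f"FI not in duration list: {e}") from None
    if prev_fi == next_fi:
        raise ValueError("prev and next FI must differ")
    direction = "increase" if next_fi > prev_fi else "decrease"
    gap = abs(r_next - r_prev)
    magnitude = "small" if gap == 1 else ("large" if gap >= 3 else "intermediate")
    return direction, magnitude


def _session_duration_list(sub: pd.DataFrame) -> list[float]:
    return sorted(sub["fi_duration"].unique())


def build_transition_records(
    table: pd.DataFrame,
    metric: str,
    duration_list: list[float] | None = None,
    n_post_trials: int = 10,
    exclude_shortest: bool | None = None,
) -> list[TransitionRecord]:
    """Transition records for one metric from a start-time table.

    One record per block boundary of each (subject, day).  For burst,
    rate-crossing and change-point metrics, boundaries touching the
    shortest duration of the session's list are dropped (keyed on rank,
    so the rule carries over to novel and rescaled duration lists); the
    first-press metric keeps all boundaries.  Records with an undefined
    previous-block mean are dropped.  ``duration_list`` overrides the
    per-session list inferred from the table (needed only when a
    session shows fewer blocks than durations).
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    if exclude_shortest is None:
        exclude_shortest = metric in SHORT_EXCLUDED_METRICS
    records: list[TransitionRecord] = []
    for (subject, day), sub in table.groupby(["subject_id", "day"], sort=True):
        durs = duration_list if duration_list is not None else _session_duration_list(sub)
        shortest = min(durs)
        bmeans = sub.groupby("block_index")[metric].mean()
        blocks = sorted(sub["block_index"].unique())
        for k, (b_prev, b_next) in enumerate(zip(blocks[:-1], blocks[1:]), start=1):
            prev_fi = float(sub.loc[sub.block_index == b_prev, "fi_duration"].iloc[0])
            next_fi = float(sub.loc[sub.block_index == b_next, "fi_duration"].iloc[0])
            if prev_fi == next_fi:
                continue
            if exclude_shortest and shortest in (prev_fi, next_fi):
                continue
            prev_mean = float(bmeans.get(b_prev, math.nan))
            if not math.isfinite(prev_mean):
                continue
            direction, magnitude = classify_transition(prev_fi, next_fi, durs)
            nxt = sub[sub.block_index == b_next].sort_values("trial_index_in_block")
            post = np.full(n_post_trials, math.nan)
            for _, row in nxt.iterrows():
                j = int(row["trial_index_in_block"]) - 1
                if 0 <= j < n_post_trials:
                    post[j] = row[metric]
            records.append(TransitionRecord(
                subject_id=str(subject), day=int(day), transition_index=k,
                prev_fi=prev_fi, next_fi=next_fi, direction=direction,
                magnitude_class=magnitude, prev_block_mean=prev_mean,
                post_trial_values=post,
            ))
    return records


def _normalized_matrix(records: list[TransitionRecord]) -> np.ndarray:
    if not records:
        return np.empty((0, 0))
    return np.vstack([r.normalized() for r in records])


def normalized_adaptation_curves(
    records: list[TransitionRecord],
) -> dict[str, pd.DataFrame]:
    """Mean normalized adaptation curve per direction.

    Each curve row (post-transition trial 1..T) holds the mean and SEM
    of the record-level normalized values (in % of the previous-block
    mean) and the number of records contributing (pairwise deletion).
    """
    out: dict[str, pd.DataFrame] = {}
    for direction in ("increase", "decrease"):
        recs = [r for r in records if r.direction == direction]
        if not recs:
            continue
        m = _normalized_matrix(recs)
        n = np.sum(np.isfinite(m), axis=0)
        with warnings.catch_warnings():
            # trailing post-trial columns can be all-NaN (short blocks)
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(m, axis=0)
            sd = np.nanstd(m, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        out[direction] = pd.DataFrame({
            "post_trial": np.arange(1, m.shape[1] + 1),
            "mean_pct": mean,
            "sem_pct": sem,
            "n": n,
        })
    return out


def post_transition_correlations(
    table: pd.DataFrame,
    metric: str,
    trial_index: int,
    blocks: tuple[int, int] = (2, 5),
) -> dict:
    """Pearson correlation of a metric with FI duration at fixed post-trial.

    Pools (FI duration, value) pairs at post-transition trial
    ``trial_index`` across blocks 2..5 (block 1 has no preceding
    transition and is excluded) and across subjects and days.  Returns
    r, R^2, the two-sided p-value, and n; all-NaN when fewer than three
    pairs survive or the FI durations are constant.
    """
    sel = table[
        (table["trial_index_in_block"] == trial_index)
        & (table["block_index"] >= blocks[0])
        & (table["block_index"] <= blocks[1])
    ][["fi_duration", metric]].dropna()
    missing = {"r": math.nan, "r2": math.nan, "p": math.nan, "n": len(sel)}
    if len(sel) < 3 or sel["fi_duration"].nunique() < 2:
        return missing
    r, p = stats.pearsonr(sel["fi_duration"], sel[metric])
    return {"r": float(r), "r2": float(r) ** 2, "p": float(p), "n": len(sel)}


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def adaptation_latency(
    records: list[TransitionRecord], alpha: float = 0.05
) -> tuple[int | None, pd.DataFrame]:
    """First post-transition trial deviating significantly from 100 %.

    Per trial index, the record-level normalized values are tested
    against 100 % (two-sided one-sample t test); p-values are Holm-
    adjusted across the T trial indices.  Returns the smallest trial
    index with adjusted p < alpha (None if no trial deviates) together
    with the per-trial test table.
    """
    m = _normalized_matrix(records)
    if m.size == 0:
        return None, pd.DataFrame()
    T = m.shape[1]
    pvals = np.ones(T)
    means = np.full(T, math.nan)
    ns = np.zeros(T, dtype=int)
    for j in range(T):
        vals = m[:, j]
        vals = vals[np.isfinite(vals)]
        ns[j] = vals.size
        if vals.size >= 2:
            means[j] = vals.mean()
            if np.ptp(vals) > 0:
                pvals[j] = stats.ttest_1samp(vals, 100.0).pvalue
    adj = _holm(pvals)
    table = pd.DataFrame({
        "post_trial": np.arange(1, T + 1),
        "mean_pct": means,
        "n": ns,
        "p_raw": pvals,
        "p_holm": adj,
    })
    sig = np.flatnonzero(adj < alpha)
    latency = int(sig[0]) + 1 if sig.size else None
    return latency, table


class TransitionModel:
    """Block-transition adaptation model over a start-time table.

    Parameters
    ----------
    table : DataFrame
        Start-time table from :func:`sfi_timing.metrics.estimate_all`
        (columns ``subject_id, day, block_index, trial_index_in_block,
        fi_duration`` plus the four metric columns).
    metrics : sequence of str
        Metric columns to analyze (default: all four).
    n_post_trials : int
        T, the number of post-transition trials retained per record.
    duration_list : list of float, optional
        Ordered duration list override; by default each session's list
        is inferred from its own table rows.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        metrics: tuple[str, ...] = METRIC_COLUMNS,
        n_post_trials: int = 10,
        duration_list: list[float] | None = None,
    ):
        required = {"subject_id", "day", "block_index", "trial_index_in_block",
                    "fi_duration", *metrics}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks columns: {sorted(missing)}")
        self.table = table.copy()
        self.metrics = tuple(metrics)
        self.n_post_trials = int(n_post_trials)
        self.duration_list = duration_list

    @classmethod
    def from_sessions(cls, sessions, cfg=None, **kw) -> "TransitionModel":
        """Convenience: run the start-time estimators, then build the model."""
        from .metrics import MetricConfig, estimate_all

        table = estimate_all(sessions, cfg or MetricConfig())
        return cls(table, **kw)

    def fit(self, alpha: float = 0.05) -> "TransitionResults":
        records = {
            m: build_transition_records(
                self.table, m, self.duration_list, self.n_post_trials)
            for m in self.metrics
        }
        curves = {m: normalized_adaptation_curves(r) for m, r in records.items()}
        lat_rows, lat_tables = [], {}
        for m, recs in records.items():
            for direction in ("increase", "decrease"):
                sub = [r for r in recs if r.direction == direction]
                lat, tab = adaptation_latency(sub, alpha=alpha)
                lat_rows.append({
                    "metric": m, "direction": direction,
                    "latency": lat, "n_records": len(sub),
                })
                lat_tables[(m, direction)] = tab
        corr_rows = []
        for m in self.metrics:
            for j in (1, 2, 3, 4):
                c = post_transition_correlations(self.table, m, j)
                corr_rows.append({"metric": m, "post_trial": j, **c})
        return TransitionResults(
            model=self,
            records=records,
            curves=curves,
            latencies=pd.DataFrame(lat_rows),
            latency_tables=lat_tables,
            correlations=pd.DataFrame(corr_rows),
            alpha=alpha,
        )


@dataclass
class TransitionResults:
    """Fitted transition analysis: curves, latencies, correlations."""

    model: TransitionModel
    records: dict[str, list[TransitionRecord]]
    curves: dict[str, dict[str, pd.DataFrame]]
    latencies: pd.DataFrame
    latency_tables: dict[tuple[str, str], pd.DataFrame]
    correlations: pd.DataFrame
    alpha: float

    def curve(self, metric: str, direction: str) -> pd.DataFrame:
        return self.curves[metric][direction]

    def latency(self, metric: str, direction: str) -> int | None:
        row = self.latencies[
            (self.latencies.metric == metric)
            & (self.latencies.direction == direction)
        ]
        if row.empty:
            return None
        v = row["latency"].iloc[0]
        return None if pd.isna(v) else int(v)

    def earliest_adaptation(self, direction: str, min_trial: int = 2) -> int | None:
        """Earliest significant post-transition trial across all metrics.

        Scans the Holm-adjusted per-trial tests of every metric for the
        given direction and returns the smallest significant trial index
        at or after ``min_trial``.  The default skips trial 1: the
        animal cannot yet know the FI changed, so trial-1 deviations
        reflect block-context artifacts of the estimators rather than
        adaptation (see the per-trial tables for the full picture).
        """
        best: int | None = None
        for m in self.model.metrics:
            t = self.latency_tables.get((m, direction))
            if t is None or t.empty:
                continue
            sig = t[(t.post_trial >= min_trial) & (t.p_holm < self.alpha)]
            if not sig.empty:
                v = int(sig.post_trial.iloc[0])
                best = v if best is None else min(best, v)
        return best

    def records_frame(self, metric: str) -> pd.DataFrame:
        """Tidy per-record table (for export to external stats tools)."""
        rows = []
        for r in self.records[metric]:
            base = {
                "subject_id": r.subject_id, "day": r.day,
                "transition_index": r.transition_index,
                "prev_fi": r.prev_fi, "next_fi": r.next_fi,
                "direction": r.direction, "magnitude_class": r.magnitude_class,
                "prev_block_mean": r.prev_block_mean,
            }
            for j, v in enumerate(r.post_trial_values, start=1):
                rows.append({**base, "post_trial": j, "value": v,
                             "normalized_pct": 100.0 * v / r.prev_block_mean})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Block-transition adaptation summary",
                 "=" * 52]
        lines.append(f"post-transition trials analyzed: T = {self.model.n_post_trials}")
        lines.append("")
        lines.append("Adaptation latency (first trial deviating from previous-")
        lines.append(f"block mean, Holm-adjusted alpha = {self.alpha}):")
        lines.append(self.latencies.to_string(index=False))
        lines.append("")
        lines.append("Start time vs FI duration (Pearson), post-transition trials 1-4:")
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(self.correlations.to_string(index=False))
        return "\n".join(lines)

    def plot_adaptation(self, metric: str, ax=None):
        """Plot normalized adaptation curves for one metric."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for direction, style in (("increase", "-o"), ("decrease", "-s")):
            if direction not in self.curves[metric]:
                continue
            c = self.curves[metric][direction]
            ax.errorbar(c["post_trial"], c["mean_pct"], yerr=c["sem_pct"],
                        fmt=style, label=direction, capsize=3)
        ax.axhline(100.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("trial after block transition")
        ax.set_ylabel("start time (% of previous-block mean)")
        ax.set_title(metric)
        ax.legend()
        return ax
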