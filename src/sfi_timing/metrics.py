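"""Single-trial start-time estimators for sFI press streams.

Four per-trial estimates of the onset of timed, high-rate pressing are
computed independently of one another:

``first_press``
    time of the earliest press at or after the censoring floor (5 s).
``first_burst``
    time of the first press of the earliest triple of presses whose two
    inter-press intervals both fall within the smallest 40 % of the
    experiment-wide pooled IPI distribution.
``rate_increase``
    left edge of the earliest 1-s bin whose 3-s moving-average press
    rate exceeds twice the session-average press rate.
``change_point``
    first Bayesian change point in the IPI sequence with Bayes factor
    at or above 10 (see :mod:`sfi_timing.changepoint`).

All trials end in reward and pressing routinely continues past the
deadline into the next trial's food retrieval, so values earlier than
``min_start_time`` (default 5 s) are censored: no estimator ever
reports a start before it.  Analysis is restricted to the first five
blocks of each session, where engagement is reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Session, Trial

__all__ = [
    "MetricConfig",
    "ipi_threshold",
    "pooled_ipis",
    "first_press_time",
    "first_burst_time",
    "smoothed_rate_series",
    "moving_average",
    "session_baseline_rate",
    "rate_increase_time",
    "estimate_all",
    "METRIC_COLUMNS",
]

#: Column names of the four estimators in a start-time table.
METRIC_COLUMNS = ("first_press", "first_burst", "rate_increase", "change_point")


@dataclass(frozen=True)
class MetricConfig:
    """Tunable constants of the start-time estimators.

    Defaults implement the standard analysis: 5-s censoring, bursts of
    three presses inside the fastest 40 % of IPIs, per-second rates
    smoothed with a centered 3-s window, a 2x session-average crossing,
    and a Bayes-factor threshold of 10 for change points.
    """

    min_start_time: float = 5.0
    burst_length: int = 3
    burst_ipi_quantile: float = 0.40
    rate_bin: float = 1.0
    smooth_window: int = 3
    rate_multiplier: float = 2.0
    bf_threshold: float = 10.0
    max_blocks: int = 5
    per_subject_ipi_pool: bool = False

    def __post_init__(self) -> None:
        if self.min_start_time < 0:
            raise ValueError("min_start_time must be >= 0")
        if not 0.0 < self.burst_ipi_quantile < 1.0:
            raise ValueError("burst_ipi_quantile must be in (0, 1)")
        if self.burst_length < 2:
            raise ValueError("burst_length must be >= 2")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.rate_multiplier <= 1.0:
            raise ValueError("rate_multiplier must be > 1")
        if self.bf_threshold <= 1.0:
            raise ValueError("bf_threshold must be > 1")


def pooled_ipis(sessions: list[Session]) -> np.ndarray:
    """Within-trial IPIs pooled over all trials of all sessions.

    IPIs never span a reward: trials end at reward delivery, so only
    gaps between consecutive presses of the same trial are pooled.
    """
    parts = [t.ipis() for s in sessions for t in s.trials if len(t.press_times) > 1]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def ipi_threshold(experiment_ipis: np.ndarray, quantile: float = 0.40) -> float:
    """Nearest-rank (type-1) empirical quantile of the pooled IPIs.

    An IPI counts as "fast" iff it is <= this threshold.
    """
    x = np.asarray(experiment_ipis, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one IPI")
    xs = np.sort(x)
    k = max(1, math.ceil(quantile * xs.size))
    return float(xs[k - 1])


def first_press_time(trial: Trial, cfg: MetricConfig = MetricConfig()) -> float:
    """Earliest press at or after the censoring floor; NaN if none."""
    p = trial.press_times
    late = p[p >= cfg.min_start_time]
    return float(late[0]) if late.size else math.nan


def first_burst_time(
    trial: Trial, threshold: float, cfg: MetricConfig = MetricConfig()
) -> float:
    """Time of the first press of the earliest qualifying burst; NaN if none.

    A burst is ``burst_length`` consecutive presses whose successive
    IPIs are all <= ``threshold``; the burst's first press must itself
    clear the censoring floor.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    p = trial.press_times
    m = cfg.burst_length
    if p.size < m:
        return math.nan
    ipis = np.diff(p)
    fast = ipis <= threshold
    for i in range(p.size - m + 1):
        if p[i] < cfg.min_start_time:
            continue
        if fast[i : i + m - 1].all():
            return float(p[i])
    return math.nan


def smoothed_rate_series(
    trial: Trial, cfg: MetricConfig = MetricConfig()
) -> np.ndarray:
    """Per-second press counts smoothed by a centered moving average.

    Presses are counted in 1-s bins ``[t, t+1)`` covering the whole
    trial; the moving average has width ``smooth_window`` and truncates
    at the edges (averaging only over available bins), so there is no
    phase lag.
    """
    n_bins = max(1, math.ceil(trial.reward_time / cfg.rate_bin))
    raw, _ = np.histogram(
        trial.press_times, bins=n_bins, range=(0.0, n_bins * cfg.rate_bin)
    )
    return moving_average(raw, cfg.smooth_window) / cfg.rate_bin


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation.

    At the edges the window shrinks to the available samples, so a
    constant series is reproduced exactly and there is no phase lag.
    """
    x = np.asarray(x, dtype=float)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(x.size)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def session_baseline_rate(session: Session) -> float:
    """Average press rate over the whole session (presses/s)."""
    if not session.trials:
        raise ValueError("session has no trials")
    presses = sum(t.press_times.size for t in session.trials)
    duration = session.total_time()
    return presses / duration


def rate_increase_time(
    trial: Trial, baseline: float, cfg: MetricConfig = MetricConfig()
) -> float:
    """Left edge of the first bin whose smoothed rate crosses the bar.

    The bar is ``rate_multiplier * baseline`` (strictly greater-than);
    bins starting before the censoring floor are ignored.  NaN if the
    smoothed rate never crosses.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    smoothed = smoothed_rate_series(trial, cfg)
    bar = cfg.rate_multiplier * baseline
    edges = np.arange(smoothed.size) * cfg.rate_bin
    ok = (smoothed > bar) & (edges >= cfg.min_start_time)
    idx = np.flatnonzero(ok)
    return float(edges[idx[0]]) if idx.size else math.nan


def estimate_all(
    sessions: list[Session], cfg: MetricConfig = MetricConfig()
) -> pd.DataFrame:
    """Start-time table: one row per trial of the first ``max_blocks`` blocks.

    The burst IPI threshold and the change-point prior scale are fixed
    once from the experiment-wide pooled IPI distribution before any
    per-trial analysis; the rate-crossing baseline is per session.  Each
    of the four estimators is computed independently; undefined values
    are NaN and are never imputed.
    """
    from .changepoint import CprlConfig, default_config, first_change_point

    if not sessions:
        raise ValueError("need at least one session")

    pool_all = pooled_ipis(sessions)
    if pool_all.size:
        thr_all = ipi_threshold(pool_all, cfg.burst_ipi_quantile)
        cprl_all = default_config(pool_all, bf_threshold=cfg.bf_threshold)
    else:
        thr_all, cprl_all = math.nan, None

    rows = []
    for sess in sessions:
        if cfg.per_subject_ipi_pool:
            pool = pooled_ipis([sess])
            thr = ipi_threshold(pool, cfg.burst_ipi_quantile) if pool.size else math.nan
            cprl = default_config(pool, bf_threshold=cfg.bf_threshold) if pool.size else None
        else:
            thr, cprl = thr_all, cprl_all
        baseline = session_baseline_rate(sess)
        for t in sess.trials:
            if t.block_index > cfg.max_blocks:
                continue
            cp = math.nan
            if cprl is not None:
                cp_res = first_change_point(t, cprl, cfg.min_start_time)
                cp = cp_res.change_time
            rows.append({
                "subject_id": sess.subject_id,
                "day": sess.day,
                "block_index": t.block_index,
                "trial_index_in_block": t.trial_index_in_block,
                "fi_duration": t.fi_duration,
                "first_press": first_press_time(t, cfg),
                "first_burst": (
                    first_burst_time(t, thr, cfg) if thr > 0 else math.nan
                ),
                "rate_increase": rate_increase_time(t, baseline, cfg),
                "change_point": cp,
            })
    return pd.DataFrame(rows)
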