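"""A reduced scalar-start-time agent for the sFI task.

The agent is a surrogate for accumulator-style timing models: it holds a
running estimate of the current FI duration, begins high-rate pressing
at a threshold fraction ``k`` of that estimate (k ~ 0.5, i.e. a response
threshold at about half the accumulator's maximum height), and carries
scalar timing noise — the standard deviation of the start time grows in
proportion to its mean with coefficient of variation ``w`` (Weber
fraction).  After each reward the estimate moves toward the experienced
trial duration by a delta rule with learning rate ``alpha``; ``alpha=1``
is one-shot updating, small ``alpha`` is gradual, iterative learning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["AgentParams", "AgentState", "sample_start_time", "update_estimate",
           "RAT_FAST", "RAT_SLOW", "RAT_GRADUAL", "MOUSE_FAST", "PRESETS"]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the synthetic presser.

    baseline_rate : presses/s
        Poisson rate of unscheduled "lever sampling" presses, active from
        the end of the consumption pause onward.
    high_rate : presses/s
        Poisson rate of timed pressing, active from the sampled start
        time onward.  Must exceed ``2 * baseline_rate`` so a twofold
        rate elevation is detectable.
    threshold_fraction : dimensionless
        k, mean start time as a fraction of the current FI estimate.
    weber_cv : dimensionless
        w, coefficient of variation of the start time (scalar noise).
    learning_rate : dimensionless in [0, 1]
        alpha of the delta rule applied after each reward.
    consumption_delay : s
        Hard no-press window at the start of every trial while the
        animal consumes the pellet earned on the previous trial.
    initial_estimate : s
        FI estimate before the first trial of a session.
    """

    baseline_rate: float = 0.1
    high_rate: float = 2.0
    threshold_fraction: float = 0.5
    weber_cv: float = 0.2
    learning_rate: float = 1.0
    consumption_delay: float = 2.0
    initial_estimate: float = 36.0

    def __post_init__(self) -> None:
        if self.high_rate <= 0:
            raise ValueError("high_rate must be > 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.high_rate <= 2.0 * self.baseline_rate:
            raise ValueError("high_rate must exceed 2 * baseline_rate")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.weber_cv < 0:
            raise ValueError("weber_cv must be >= 0")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1]")
        if self.consumption_delay < 0:
            raise ValueError("consumption_delay must be >= 0")
        if self.initial_estimate <= 0:
            raise ValueError("initial_estimate must be > 0")


@dataclass
class AgentState:
    """Mutable per-session state: the current FI estimate (s)."""

    estimate: float


#: One-shot rat-like preset (fast learner).
RAT_FAST = AgentParams(learning_rate=1.0)
#: Gradual rat-like preset for learning-rate contrasts.
RAT_SLOW = AgentParams(learning_rate=0.2)
#: Very gradual preset (iterative-learning contrast cohort).
RAT_GRADUAL = AgentParams(learning_rate=0.05)
#: Mouse-like preset: long pellet-consumption pause, higher press rate.
#: The 8 s pause reproduces the near-absence of pressing on 12 s trials.
MOUSE_FAST = AgentParams(
    baseline_rate=0.1, high_rate=3.0, consumption_delay=8.0, learning_rate=1.0
)

PRESETS = {
    "rat_fast": RAT_FAST,
    "rat_slow": RAT_SLOW,
    "rat_gradual": RAT_GRADUAL,
    "mouse_fast": MOUSE_FAST,
}


def sample_start_time(
    current_estimate: float, params: AgentParams, rng: np.random.Generator
) -> float:
    """Sample the high-rate pressing onset for one trial.

    Drawn from Normal(k * estimate, (w * k * estimate)^2), truncated
    below at the consumption delay (the agent cannot start pressing
    while still eating).  With ``w = 0`` the start time is exactly
    ``k * estimate`` (or the delay floor if larger).
    """
    if current_estimate <= 0:
        raise ValueError("current_estimate must be > 0")
    mean = params.threshold_fraction * current_estimate
    sd = params.weber_cv * mean
    start = mean if sd == 0 else rng.normal(mean, sd)
    return max(start, params.consumption_delay)


def update_estimate(
    old_estimate: float, experienced_interval: float, learning_rate: float
) -> float:
    """Delta-rule update of the FI estimate after a reward.

    ``new = old + alpha * (experienced - old)``; with alpha = 1 a single
    exposure fully overwrites the stored duration.
    """
    if old_estimate <= 0 or experienced_interval <= 0:
        raise ValueError("estimates and intervals must be > 0")
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must be in [0, 1]")
    return old_estimate + learning_rate * (experienced_interval - old_estimate)
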