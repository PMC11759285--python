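"""Simulation of complete sFI sessions.

A trial is a superposition of two homogeneous Poisson press processes:
a baseline ("lever sampling") process active from the end of the
consumption pause, and a high-rate timed process active from the
agent's sampled start time.  The first press at or after the FI
deadline earns the reward and ends the trial; only pellet delivery
signals the trial boundary, so the experienced interval the agent
learns from is the reward time itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agent import AgentParams, AgentState, sample_start_time, update_estimate
from .protocol import Protocol, without_replacement_stream

__all__ = ["Trial", "Session", "simulate_trial", "simulate_session",
           "simulate_cohort"]


@dataclass
class Trial:
    """One fixed-interval trial.

    ``press_times`` are seconds from trial start, strictly increasing;
    the last press is the rewarded one, so ``reward_time`` equals
    ``press_times[-1]`` and is the first press at or after
    ``fi_duration``.
    """

    block_index: int
    trial_index_in_block: int
    fi_duration: float
    press_times: np.ndarray
    reward_time: float

    def ipis(self) -> np.ndarray:
        """Within-trial inter-press intervals (s)."""
        return np.diff(self.press_times)

    def validate(self) -> None:
        p = self.press_times
        if p.size == 0:
            raise ValueError("trial must contain at least one press")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError("press times must be strictly increasing")
        if self.reward_time != p[-1]:
            raise ValueError("reward_time must be the last press")
        if self.reward_time < self.fi_duration:
            raise ValueError("reward_time must be >= fi_duration")
        if np.any(p[:-1] >= self.fi_duration):
            raise ValueError("only the rewarded press may be >= fi_duration")


@dataclass
class Session:
    """One day of sFI training for one subject."""

    subject_id: str
    day: int
    trials: list[Trial]
    protocol: Protocol
    rng_seed: int
    #: Duration list in force this day (== base list except de_novo).
    durations: tuple[float, ...] = ()

    def n_blocks(self) -> int:
        return max((t.block_index for t in self.trials), default=0)

    def total_time(self) -> float:
        """Summed trial durations (s); trials are back to back."""
        return float(sum(t.reward_time for t in self.trials))


def _poisson_events(
    rate: float, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def simulate_trial(
    fi: float,
    state: AgentState,
    params: AgentParams,
    rng: np.random.Generator,
    start_time: float | None = None,
) -> Trial:
    """Simulate one trial at FI ``fi`` given the agent's current estimate.

    ``start_time`` overrides the sampled high-rate onset (used in
    deterministic tests); block/trial indices are filled in by the
    session loop.
    """
    if fi <= 0:
        raise ValueError("fi must be > 0")
    if start_time is None:
        start_time = sample_start_time(state.estimate, params, rng)

    # Extend the observation window until some press lands at/after fi.
    lo = 0.0
    window = max(fi, start_time) + 5.0 / params.high_rate
    base_ev: list[np.ndarray] = []
    high_ev: list[np.ndarray] = []
    while True:
        base_ev.append(_poisson_events(
            params.baseline_rate, max(params.consumption_delay, lo), window, rng))
        high_ev.append(_poisson_events(
            params.high_rate, max(start_time, lo), window, rng))
        presses = np.concatenate(base_ev + high_ev)
        presses = np.unique(presses)  # sorts; exact ties have measure zero
        if presses.size and presses[-1] >= fi:
            break
        lo = window
        window += 10.0 / params.high_rate
    cut = int(np.searchsorted(presses, fi, side="left"))
    presses = presses[: cut + 1]
    return Trial(
        block_index=0,
        trial_index_in_block=0,
        fi_duration=fi,
        press_times=presses,
        reward_time=float(presses[-1]),
    )


def simulate_session(
    protocol: Protocol,
    params: AgentParams,
    rng: np.random.Generator | int,
    subject_id: str = "S1",
    day: int = 1,
) -> Session:
    """Simulate one full session.

    Blocks draw FI durations and block lengths without replacement from
    independently refreshing lists; the agent updates its estimate after
    every reward.  The session ends at ``max_rewards`` rewards or when
    the session clock passes ``max_session_time`` (the trial in progress
    completes, then the session stops).
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    durations = protocol.session_durations(rng)
    dur_stream = without_replacement_stream(durations, rng)
    len_stream = without_replacement_stream(protocol.block_length_choices, rng)

    state = AgentState(estimate=params.initial_estimate)
    trials: list[Trial] = []
    elapsed = 0.0
    block = 0
    done = False
    while not done:
        block += 1
        fi = float(next(dur_stream))
        block_len = int(next(len_stream))
        for idx in range(1, block_len + 1):
            trial = simulate_trial(fi, state, params, rng)
            trial.block_index = block
            trial.trial_index_in_block = idx
            trials.append(trial)
            elapsed += trial.reward_time
            state.estimate = update_estimate(
                state.estimate, trial.reward_time, params.learning_rate)
            if len(trials) >= protocol.max_rewards or elapsed >= protocol.max_session_time:
                done = True
                break
    return Session(
        subject_id=subject_id,
        day=day,
        trials=trials,
        protocol=protocol,
        rng_seed=seed,
        durations=durations,
    )


def simulate_cohort(
    protocol: Protocol,
    params: AgentParams,
    n_subjects: int,
    n_days: int = 1,
    master_seed: int = 0,
) -> list[Session]:
    """Simulate ``n_subjects`` x ``n_days`` independent sessions.

    Each (subject, day) pair gets its own child seed spawned from the
    master seed, so cohorts are reproducible and sessions independent.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects * n_days)
    sessions = []
    i = 0
    for s in range(1, n_subjects + 1):
        for d in range(1, n_days + 1):
            child_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            sessions.append(
                simulate_session(
                    protocol, params, child_seed,
                    subject_id=f"S{s:02d}", day=d,
                )
            )
            i += 1
    return sessions
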