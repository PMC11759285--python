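"""Serial fixed-interval (sFI) task protocols.

A session is built from blocks of fixed-interval (FI) trials.  The FI
duration of each block is drawn without replacement from a short list
(classically 12, 24, 36, 48, 60 s) and the block length from a second
list (13, 15, 17, 19, 21 trials).  When a list is exhausted it is
refreshed, so within every refresh window each value appears exactly
once.  Both lists start fresh at the beginning of every session.

Three protocol variants are supported:

``fixed``
    the base duration list is used verbatim every day.
``novel``
    a hand-picked list of never-before-seen durations (13, 15, 31, 45,
    57 s) replaces the trained list; each novel value lies within
    60–140 % of the base value it replaces.
``de_novo``
    each session rescales every base duration by an independent factor
    drawn uniformly from [0.8, 1.2], so the animal faces a distinct set
    of durations every day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "EXPERIMENT1_DURATIONS",
    "EXPERIMENT2_DURATIONS",
    "BLOCK_LENGTHS",
    "draw_without_replacement_sequence",
    "without_replacement_stream",
    "scale_durations_de_novo",
    "validate_duration_ratios",
]

#: Trained duration list (s).
EXPERIMENT1_DURATIONS = (12.0, 24.0, 36.0, 48.0, 60.0)
#: Novel-duration list (s); positionally matched to the trained list.
EXPERIMENT2_DURATIONS = (13.0, 15.0, 31.0, 45.0, 57.0)
#: Block length choices (trials).
BLOCK_LENGTHS = (13, 15, 17, 19, 21)


@dataclass(frozen=True)
class Protocol:
    """Task parameters for one sFI variant.

    Parameters
    ----------
    base_durations
        FI durations in seconds, strictly increasing.
    block_length_choices
        Possible trials-per-block counts.
    max_rewards
        Session ends once this many rewards have been earned.
    max_session_time
        Session ends once this much time (s) has elapsed; the trial in
        progress at timeout completes first.
    experiment_variant
        One of ``fixed``, ``novel``, ``de_novo``.
    """

    base_durations: tuple[float, ...] = EXPERIMENT1_DURATIONS
    block_length_choices: tuple[int, ...] = BLOCK_LENGTHS
    max_rewards: int = 100
    max_session_time: float = 90.0 * 60.0
    experiment_variant: str = "fixed"

    def __post_init__(self) -> None:
        d = np.asarray(self.base_durations, dtype=float)
        if d.size == 0 or np.any(d <= 0):
            raise ValueError("base_durations must be non-empty and positive")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("base_durations must be strictly increasing")
        if len(self.block_length_choices) == 0 or min(self.block_length_choices) < 1:
            raise ValueError("block_length_choices must all be >= 1")
        if self.max_rewards < 1:
            raise ValueError("max_rewards must be >= 1")
        if self.max_session_time <= 0:
            raise ValueError("max_session_time must be > 0")
        if self.experiment_variant not in {"fixed", "novel", "de_novo"}:
            raise ValueError(f"unknown variant {self.experiment_variant!r}")

    def session_durations(self, rng: np.random.Generator) -> tuple[float, ...]:
        """Duration list actually in force for one session/day."""
        if self.experiment_variant == "de_novo":
            return tuple(scale_durations_de_novo(self.base_durations, rng))
        return tuple(self.base_durations)


def novel_protocol(**kw) -> Protocol:
    """Experiment-2 protocol with the printed novel durations."""
    return Protocol(
        base_durations=EXPERIMENT2_DURATIONS, experiment_variant="novel", **kw
    )


def de_novo_protocol(**kw) -> Protocol:
    """Experiment-3 protocol; durations rescaled by 80–120 % per day."""
    return Protocol(experiment_variant="de_novo", **kw)


def without_replacement_stream(
    values: Sequence, rng: np.random.Generator
) -> Iterator:
    """Yield values drawn without replacement, refreshing on exhaustion.

    Every window of ``len(values)`` consecutive draws (aligned to refresh
    boundaries) is a permutation of ``values``.  The stream is infinite.
    """
    vals = list(values)
    if not vals:
        raise ValueError("value list must be non-empty")
    while True:
        order = rng.permutation(len(vals))
        for i in order:
            yield vals[i]


def draw_without_replacement_sequence(
    values: Sequence, n_items: int, rng: np.random.Generator
) -> list:
    """Draw ``n_items`` values without replacement with list refresh.

    The list is refreshed (reshuffled in full) whenever it is exhausted,
    so entries ``1..k``, ``k+1..2k``, ... (``k = len(values)``) are each
    permutations of ``values``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    stream = without_replacement_stream(values, rng)
    return [next(stream) for _ in range(n_items)]


def scale_durations_de_novo(
    base_durations: Sequence[float], rng: np.random.Generator
) -> list[float]:
    """Rescale each duration by an independent factor in [0.8, 1.2].

    Each base duration d is multiplied by ``0.8 + X * 0.4`` with X drawn
    uniformly on [0, 1], yielding durations in 80–120 % of the original.
    """
    base = np.asarray(base_durations, dtype=float)
    if base.size == 0 or np.any(base <= 0):
        raise ValueError("base durations must be non-empty and positive")
    factors = 0.8 + rng.uniform(0.0, 1.0, size=base.size) * 0.4
    return list(base * factors)


def validate_duration_ratios(
    base: Sequence[float],
    novel: Sequence[float],
    low: float = 60.0,
    high: float = 140.0,
) -> pd.DataFrame:
    """Check positionally-matched novel/base duration ratios against bounds.

    Returns a table with columns ``base``, ``novel``, ``ratio_pct`` and
    ``within_bounds``; the table's ``.attrs['pass']`` flag is True iff
    every ratio (in percent) lies in ``[low, high]``.
    """
    b = np.asarray(base, dtype=float)
    n = np.asarray(novel, dtype=float)
    if b.shape != n.shape:
        raise ValueError("base and novel lists must have matching length")
    if np.any(b <= 0):
        raise ValueError("base durations must be positive")
    ratio = 100.0 * n / b
    ok = (ratio >= low) & (ratio <= high)
    out = pd.DataFrame(
        {"base": b, "novel": n, "ratio_pct": ratio, "within_bounds": ok}
    )
    out.attrs["pass"] = bool(ok.all())
    return out
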