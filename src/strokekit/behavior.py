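"""Behavioral and neurological endpoints of the tMCAO mouse model.

Three assays are scored:

* **Hargreaves plantar test** — thermal-pain withdrawal latency of each
  hind paw over five trials; the session latency is the mean of the
  three central trials after discarding the single highest and single
  lowest value.
* **Corner test** — vibrissae/motor asymmetry; the fraction of right
  turns over ten trials (left-side occlusion biases turning rightward).
* **Five-point neurological score** — 0 (no deficit) to 4 (no
  spontaneous walk, decreased consciousness); a score of 1–4 counts as
  successful occlusion induction.

Missing sessions (e.g. animals that died) are represented as absent
rows and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HargreavesSession",
    "CornerSession",
    "NeuroScore",
    "hargreaves_latency",
    "corner_right_frequency",
    "validate_tmcao_induction",
    "hargreaves_table",
    "corner_table",
]

N_HARGREAVES_TRIALS = 5
N_CORNER_TRIALS = 10


@dataclass
class HargreavesSession:
    animal: str
    day: int
    paw: str
    latencies_s: np.ndarray

    def __post_init__(self) -> None:
        self.latencies_s = np.asarray(self.latencies_s, dtype=float)
        if self.latencies_s.shape != (N_HARGREAVES_TRIALS,):
            raise ValueError(f"exactly {N_HARGREAVES_TRIALS} trials required")
        if np.any(self.latencies_s <= 0):
            raise ValueError("withdrawal latencies must be positive")
        if self.paw not in ("left", "right"):
            raise ValueError("paw must be 'left' or 'right'")


@dataclass
class CornerSession:
    animal: str
    day: int
    turns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.turns) != N_CORNER_TRIALS:
            raise ValueError(f"exactly {N_CORNER_TRIALS} trials required")
        if any(t not in ("L", "R") for t in self.turns):
            raise ValueError("turn outcomes must be 'L' or 'R'")


@dataclass
class NeuroScore:
    animal: str
    day: int
    score: int

    def __post_init__(self) -> None:
        if not isinstance(self.score, (int, np.integer)) or not 0 <= self.score <= 4:
            raise ValueError("neuro score must be an integer in [0, 4]")


def hargreaves_latency(latencies_s: Sequence[float] | HargreavesSession) -> float:
    """Trimmed-mean withdrawal latency of a five-trial session.

    Removes exactly one instance of the maximum and one of the minimum
    (order-agnostic, stable under ties) and returns the mean of the
    remaining three trials.
    """
    if isinstance(latencies_s, HargreavesSession):
        values = latencies_s.latencies_s
    else:
        values = np.asarray(latencies_s, dtype=float)
    if values.shape != (N_HARGREAVES_TRIALS,):
        raise ValueError(f"exactly {N_HARGREAVES_TRIALS} trials required")
    if np.any(values <= 0):
        raise ValueError("withdrawal latencies must be positive")
    return float(np.sort(values)[1:-1].mean())


def corner_right_frequency(turns: Sequence[str] | CornerSession) -> float:
    """Fraction of right turns in a ten-trial corner-test session."""
    if isinstance(turns, CornerSession):
        outcomes = turns.turns
    else:
        outcomes = tuple(turns)
    if len(outcomes) != N_CORNER_TRIALS:
        raise ValueError(f"exactly {N_CORNER_TRIALS} trials required")
    if any(t not in ("L", "R") for t in outcomes):
        raise ValueError("turn outcomes must be 'L' or 'R'")
    return sum(t == "R" for t in outcomes) / N_CORNER_TRIALS


def validate_tmcao_induction(score: int | NeuroScore) -> bool:
    """True iff the neurological score (1–4) indicates successful tMCAO."""
    if isinstance(score, NeuroScore):
        value = score.score
    else:
        value = score
    if not isinstance(value, (int, np.integer)) or not 0 <= value <= 4:
        raise ValueError("neuro score must be an integer in [0, 4]")
    return 1 <= value <= 4


def hargreaves_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Session latencies from a tidy trial table.

    Input columns: ``animal, group?, day, paw, trial, latency_s`` with
    five trials per (animal, day, paw) session; returns one row per
    session with the trimmed-mean ``latency_s``.
    """
    keys = [c for c in ("animal", "group", "day", "paw") if c in trials.columns]
    return (
        trials.groupby(keys, sort=False)["latency_s"]
        .apply(lambda v: hargreaves_latency(v.to_numpy()))
        .reset_index()
    )


def corner_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Right-turn frequencies from a tidy trial table.

    Input columns: ``animal, group?, day, trial, turn`` with ten trials
    per (animal, day) session; returns one row per session with
    ``right_frequency``.
    """
    keys = [c for c in ("animal", "group", "day") if c in trials.columns]
    out = (
        trials.groupby(keys, sort=False)["turn"]
        .apply(lambda v: corner_right_frequency(tuple(v)))
        .reset_index()
    )
    return out.rename(columns={"turn": "right_frequency"})
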