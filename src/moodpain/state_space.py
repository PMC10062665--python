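"""State spaces for joint mood-pain diary records.

Participants rate mood and pain on 1-5 Likert scales each reporting day,
giving a 5 x 5 = 25 state "full" space.  For clustering, the scales are
dichotomised -- mood 1-3 Bad / 4-5 Good, pain 1-2 Low / 3-5 High -- which
reduces the space to four states, ordered canonically as

    GL (good mood, low pain), GH, BL, BH (bad mood, high pain).

This module holds the state-space definitions, the Likert -> reduced-state
recoding, trajectory construction from long-format records, and
transition counting between consecutive reporting days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "Trajectory",
    "full_space",
    "reduced_space",
    "recode_reduced",
    "recode_full",
    "full_to_reduced_index",
    "build_trajectory",
    "count_transitions",
    "pool_counts",
    "trajectories_from_frame",
    "read_diary_csv",
]

REDUCED_LABELS = ("GL", "GH", "BL", "BH")

#: mood levels considered "Good"; the rest (1-3) are "Bad"
GOOD_MOOD = frozenset({4, 5})
#: pain levels considered "Low"; the rest (3-5) are "High"
LOW_PAIN = frozenset({1, 2})


@dataclass(frozen=True)
class StateSpace:
    """A finite state space with a fixed label order.

    Attributes
    ----------
    n : int
        Number of states (25 full, 4 reduced).
    labels : tuple of str
        State names, index-aligned with matrix rows/columns everywhere.
    """

    n: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n != len(self.labels):
            raise ValueError("n must equal the number of labels")
        if len(set(self.labels)) != self.n:
            raise ValueError("state labels must be unique")

    @property
    def is_reduced(self) -> bool:
        return self.labels == REDUCED_LABELS


def reduced_space() -> StateSpace:
    """The four-state space (GL, GH, BL, BH) in its canonical order."""
    return StateSpace(4, REDUCED_LABELS)


def full_space() -> StateSpace:
    """The 25-state space of raw (mood, pain) Likert pairs.

    Index order is row-major over mood then pain: state
    ``5 * (mood - 1) + (pain - 1)`` has label ``"M<mood>P<pain>"``.
    """
    labels = tuple(f"M{m}P{p}" for m in range(1, 6) for p in range(1, 6))
    return StateSpace(25, labels)


def _check_scores(mood: int, pain: int) -> None:
    if not (1 <= mood <= 5 and 1 <= pain <= 5):
        raise ValueError(
            f"mood and pain scores must be in 1..5, got mood={mood}, pain={pain}"
        )


def recode_reduced(mood: int, pain: int) -> int:
    """Map a (mood, pain) Likert pair to its reduced-state index.

    Mood 1-3 is Bad, 4-5 Good; pain 1-2 is Low, 3-5 High.  The returned
    index follows the canonical (GL, GH, BL, BH) order.
    """
    _check_scores(mood, pain)
    good = mood in GOOD_MOOD
    low = pain in LOW_PAIN
    if good:
        return 0 if low else 1
    return 2 if low else 3


def recode_full(mood: int, pain: int) -> int:
    """Map a (mood, pain) Likert pair to its index in the 25-state space."""
    _check_scores(mood, pain)
    return 5 * (mood - 1) + (pain - 1)


def full_to_reduced_index() -> np.ndarray:
    """Length-25 array mapping each full state index to its reduced index."""
    out = np.empty(25, dtype=np.intp)
    for m in range(1, 6):
        for p in range(1, 6):
            out[recode_full(m, p)] = recode_reduced(m, p)
    return out


@dataclass(frozen=True)
class Trajectory:
    """One participant's ordered sequence of observed states.

    ``days`` are strictly increasing reporting-day indices; ``states`` are
    index-aligned state indices into the associated :class:`StateSpace`.
    """

    participant_id: str
    days: np.ndarray
    states: np.ndarray
    space: StateSpace = field(compare=False)

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=np.int64)
        states = np.asarray(self.states, dtype=np.intp)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "states", states)
        if days.shape != states.shape or days.ndim != 1:
            raise ValueError("days and states must be 1-D and equal length")
        if days.size > 1 and not np.all(np.diff(days) > 0):
            raise ValueError("day indices must be strictly increasing")
        if states.size and (states.min() < 0 or states.max() >= self.space.n):
            raise ValueError("state index out of range for this space")

    def __len__(self) -> int:
        return int(self.days.size)


def build_trajectory(
    records: Iterable[tuple],
    space: StateSpace | None = None,
    participant_id: str = "",
) -> Trajectory:
    """Build a trajectory from raw ``(day, mood, pain)`` records.

    Days where either score is missing (None or NaN) are dropped: only
    complete pairs enter the analysis.  Remaining days are sorted
    ascending; a day reported twice is a data-integrity error.
    """
    if space is None:
        space = reduced_space()
    recode = recode_reduced if space.is_reduced else recode_full
    days: list[int] = []
    states: list[int] = []
    for day, mood, pain in records:
        if mood is None or pain is None:
            continue
        if isinstance(mood, float) and np.isnan(mood):
            continue
        if isinstance(pain, float) and np.isnan(pain):
            continue
        days.append(int(day))
        states.append(recode(int(mood), int(pain)))
    order = np.argsort(days, kind="stable")
    days_arr = np.asarray(days, dtype=np.int64)[order]
    if days_arr.size > 1 and np.any(np.diff(days_arr) == 0):
        dup = int(days_arr[np.where(np.diff(days_arr) == 0)[0][0]])
        raise ValueError(
            f"participant {participant_id!r} reported day {dup} more than once"
        )
    return Trajectory(
        participant_id=participant_id,
        days=days_arr,
        states=np.asarray(states, dtype=np.intp)[order],
        space=space,
    )


def count_transitions(traj: Trajectory, space: StateSpace | None = None) -> np.ndarray:
    """Tabulate transitions between consecutive reporting days.

    Each consecutive pair of *reporting* days contributes one count,
    regardless of the calendar gap between them; m observations yield
    m - 1 counts.  Returns an n x n integer matrix.
    """
    if space is None:
        space = traj.space
    n = space.n
    counts = np.zeros((n, n), dtype=np.int64)
    if len(traj) >= 2:
        src = traj.states[:-1]
        dst = traj.states[1:]
        np.add.at(counts, (src, dst), 1)
    return counts


def pool_counts(counts: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise sum of same-shaped transition-count matrices."""
    counts = list(counts)
    if not counts:
        raise ValueError("no count matrices to pool")
    shape = counts[0].shape
    for c in counts:
        if c.shape != shape:
            raise ValueError(f"count matrix shapes differ: {c.shape} vs {shape}")
    return np.sum(np.stack(counts), axis=0)


def trajectories_from_frame(
    frame: pd.DataFrame, space: StateSpace | None = None
) -> list[Trajectory]:
    """Split a long-format diary frame into per-participant trajectories.

    Expects columns ``participant_id, day, mood, pain``; missing scores
    may be empty/NaN.  Participants appear in first-occurrence order.
    """
    if space is None:
        space = reduced_space()
    required = {"participant_id", "day", "mood", "pain"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"diary frame missing columns: {sorted(missing)}")
    out: list[Trajectory] = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        records = zip(
            grp["day"].to_numpy(),
            grp["mood"].to_numpy(),
            grp["pain"].to_numpy(),
        )
        out.append(build_trajectory(records, space, participant_id=str(pid)))
    return out


def read_diary_csv(path, space: StateSpace | None = None) -> list[Trajectory]:
    """Read a long-format diary CSV into per-participant trajectories.

    The file must have header ``participant_id,day,mood,pain``; empty
    cells denote missing scores.  ``day`` may be an integer index or an
    ISO date (converted to day offsets from the file's earliest date).
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    if frame["day"].dtype == object:
        dates = pd.to_datetime(frame["day"], format="ISO8601")
        frame["day"] = (dates - dates.min()).dt.days
    return trajectories_from_frame(frame, space)
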