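"""Observation-period grid and per-user per-period post-count aggregation.

The study design divides March 2019 - August 2022 into seven consecutive
half-year windows: two pre-pandemic (T1, T2) and five peri-pandemic
(T3-T7, starting March 1, 2020).  Raw post records are mapped onto this
grid to produce one 7-vector of post counts per user; periods in which a
user never posted (including every period before a late joiner's first
post) count as zero, and users with no posts at all are ineligible.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodGrid",
    "PostRecord",
    "UserSeries",
    "default_grid",
    "assign_period",
    "build_user_series",
    "series_to_frame",
    "frame_to_series",
]


@dataclass(frozen=True)
class PeriodGrid:
    """Seven contiguous half-year observation windows.

    Parameters
    ----------
    periods
        Ordered ``(label, start, end)`` triples with date-inclusive bounds.
    time_codes
        Numeric time covariate per period used in polynomial trends.
        Defaults to the symmetric coding ``(-3..3)/3`` so the covariate
        spans roughly ``[-1, 1]``, which keeps cubic terms well scaled
        during optimisation.
    """

    periods: tuple[tuple[str, dt.date, dt.date], ...]
    time_codes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.time_codes):
            raise ValueError("periods and time_codes must have equal length")
        for (_, s, e) in self.periods:
            if e < s:
                raise ValueError(f"period end {e} precedes start {s}")
        for (_, _, e0), (_, s1, _) in zip(self.periods, self.periods[1:]):
            if s1 != e0 + dt.timedelta(days=1):
                raise ValueError("periods must be contiguous and non-overlapping")
        if not all(a < b for a, b in zip(self.time_codes, self.time_codes[1:])):
            raise ValueError("time_codes must be strictly increasing")

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.periods)

    @property
    def start(self) -> dt.date:
        return self.periods[0][1]

    @property
    def end(self) -> dt.date:
        return self.periods[-1][2]


def default_grid() -> PeriodGrid:
    """The canonical T1-T7 grid: half years from 2019-03-01 to 2022-08-31."""
    windows = [
        ("T1", dt.date(2019, 3, 1), dt.date(2019, 8, 31)),
        ("T2", dt.date(2019, 9, 1), dt.date(2020, 2, 29)),
        ("T3", dt.date(2020, 3, 1), dt.date(2020, 8, 31)),
        ("T4", dt.date(2020, 9, 1), dt.date(2021, 2, 28)),
        ("T5", dt.date(2021, 3, 1), dt.date(2021, 8, 31)),
        ("T6", dt.date(2021, 9, 1), dt.date(2022, 2, 28)),
        ("T7", dt.date(2022, 3, 1), dt.date(2022, 8, 31)),
    ]
    codes = tuple(k / 3.0 for k in range(-3, 4))
    return PeriodGrid(periods=tuple(windows), time_codes=codes)


@dataclass(frozen=True)
class PostRecord:
    """One raw forum post: author, timestamp and (possibly empty) text."""

    user_id: str
    timestamp: dt.datetime
    text: str = ""


@dataclass(frozen=True)
class UserSeries:
    """One user's per-period post counts (the trajectory variable)."""

    user_id: str
    y: tuple[int, ...]

    def __post_init__(self) -> None:
        if any((c < 0 or int(c) != c) for c in self.y):
            raise ValueError("post counts must be nonnegative integers")
        if sum(self.y) < 1:
            raise ValueError(
                f"user {self.user_id!r}: all-zero series is ineligible "
                "(users must have posted at least once)"
            )


def _as_date(ts: dt.datetime | dt.date) -> dt.date:
    # timestamps are compared at date granularity (UTC calendar dates)
    if isinstance(ts, dt.datetime):
        return ts.date()
    return ts


def assign_period(timestamp: dt.datetime | dt.date, grid: PeriodGrid) -> int:
    """Return the 0-based index of the grid window containing *timestamp*.

    Window bounds are date-inclusive on both ends; a timestamp outside
    the overall grid range raises :class:`ValueError`.
    """
    d = _as_date(timestamp)
    for i, (_, start, end) in enumerate(grid.periods):
        if start <= d <= end:
            return i
    raise ValueError(
        f"timestamp {timestamp} outside grid range {grid.start}..{grid.end}"
    )


def build_user_series(
    records: Iterable[PostRecord], grid: PeriodGrid
) -> list[UserSeries]:
    """Aggregate post records into per-user per-period count vectors.

    Every period without a post is recorded as 0, including all periods
    before a late joiner's first post.  Users whose series would be
    all-zero are excluded (eligibility: at least one post overall --
    vacuous here since a user only appears through a record).
    """
    counts: dict[str, np.ndarray] = {}
    n_records = 0
    for rec in records:
        idx = assign_period(rec.timestamp, grid)
        if rec.user_id not in counts:
            counts[rec.user_id] = np.zeros(grid.n_periods, dtype=int)
        counts[rec.user_id][idx] += 1
        n_records += 1
    if n_records == 0:
        logger.warning("build_user_series: empty record collection")
        return []
    out = []
    for uid, y in counts.items():
        if y.sum() >= 1:
            out.append(UserSeries(user_id=uid, y=tuple(int(c) for c in y)))
    return out


def series_to_frame(series: Sequence[UserSeries], grid: PeriodGrid) -> pd.DataFrame:
    """Wide count table: one row per user, columns ``user_id, T1..T7``."""
    data = {"user_id": [s.user_id for s in series]}
    for t, label in enumerate(grid.labels):
        data[label] = [s.y[t] for s in series]
    return pd.DataFrame(data)


def frame_to_series(frame: pd.DataFrame, grid: PeriodGrid) -> list[UserSeries]:
    """Inverse of :func:`series_to_frame`; validates column presence."""
    missing = [c for c in ("user_id", *grid.labels) if c not in frame.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            UserSeries(
                user_id=str(row["user_id"]),
                y=tuple(int(row[label]) for label in grid.labels),
            )
        )
    return out
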