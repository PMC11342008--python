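"""Per-user per-period category hit counts and normalized frequencies.

The normalized frequency of a category in a user-period is its total hit
count divided by the user's total word count in that period.  A period in
which the user posted nothing has no words at all; it is *structurally
missing*, not a zero frequency, and downstream contrasts must be able to
tell the two apart — hence the parallel missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, count_hits, tokenize
from .periods import PeriodGrid, PostRecord, assign_period

__all__ = ["FeatureMatrix", "build_feature_matrix", "normalized_frequency"]


@dataclass
class FeatureMatrix:
    """Category hits and word totals on a user x period x category cube.

    ``hits[u, t, c]`` counts pattern matches of category ``c`` in user
    ``u``'s period-``t`` posts; ``total_words[u, t]`` is the period's
    word count (0 where the user did not post).
    """

    user_ids: list[str]
    period_labels: tuple[str, ...]
    categories: tuple[str, ...]
    hits: np.ndarray
    total_words: np.ndarray

    def __post_init__(self) -> None:
        n, T, C = len(self.user_ids), len(self.period_labels), len(self.categories)
        if self.hits.shape != (n, T, C):
            raise ValueError(f"hits shape {self.hits.shape} != {(n, T, C)}")
        if self.total_words.shape != (n, T):
            raise ValueError("total_words shape mismatch")
        if np.any(self.hits < 0) or np.any(self.total_words < 0):
            raise ValueError("negative counts")

    def category_index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise KeyError(f"unknown category {category!r}") from None

    def period_index(self, period: str) -> int:
        try:
            return self.period_labels.index(period)
        except ValueError:
            raise KeyError(f"unknown period {period!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: user_id, period, category, hits, total_words."""
        n, T, C = self.hits.shape
        idx = pd.MultiIndex.from_product(
            [self.user_ids, self.period_labels, self.categories],
            names=["user_id", "period", "category"],
        )
        df = pd.DataFrame(
            {
                "hits": self.hits.reshape(-1),
                "total_words": np.repeat(self.total_words.reshape(-1), C),
            },
            index=idx,
        ).reset_index()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        users = list(dict.fromkeys(df["user_id"].astype(str)))
        periods = tuple(dict.fromkeys(df["period"]))
        cats = tuple(dict.fromkeys(df["category"]))
        n, T, C = len(users), len(periods), len(cats)
        hits = np.zeros((n, T, C), dtype=int)
        words = np.zeros((n, T), dtype=int)
        u_ix = {u: i for i, u in enumerate(users)}
        t_ix = {p: i for i, p in enumerate(periods)}
        c_ix = {c: i for i, c in enumerate(cats)}
        for row in df.itertuples(index=False):
            u, t, c = u_ix[str(row.user_id)], t_ix[row.period], c_ix[row.category]
            hits[u, t, c] = row.hits
            words[u, t] = row.total_words
        return cls(users, periods, cats, hits, words)


def build_feature_matrix(
    records: Iterable[PostRecord], grid: PeriodGrid, lexicon: CategoryLexicon
) -> FeatureMatrix:
    """Tokenise every post, count category hits, and aggregate per
    user-period.  Word totals sum the posts' token counts."""
    cats = lexicon.categories
    c_ix = {c: i for i, c in enumerate(cats)}
    users: list[str] = []
    u_ix: dict[str, int] = {}
    rows_hits: list[np.ndarray] = []
    rows_words: list[np.ndarray] = []
    T = grid.n_periods
    for rec in records:
        t = assign_period(rec.timestamp, grid)
        if rec.user_id not in u_ix:
            u_ix[rec.user_id] = len(users)
            users.append(rec.user_id)
            rows_hits.append(np.zeros((T, len(cats)), dtype=int))
            rows_words.append(np.zeros(T, dtype=int))
        u = u_ix[rec.user_id]
        tokens = tokenize(rec.text)
        rows_words[u][t] += len(tokens)
        for cat, k in count_hits(tokens, lexicon).items():
            if k:
                rows_hits[u][t, c_ix[cat]] += k
    hits = np.stack(rows_hits) if rows_hits else np.zeros((0, T, len(cats)), dtype=int)
    words = np.stack(rows_words) if rows_words else np.zeros((0, T), dtype=int)
    return FeatureMatrix(users, grid.labels, cats, hits, words)


def normalized_frequency(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """``(freq, missing)``: hits / total_words, with a mask for periods
    that have no words (freq set to 0 there, missing True)."""
    words = matrix.total_words.astype(float)
    missing = words == 0
    denom = np.where(missing, 1.0, words)
    freq = matrix.hits / denom[:, :, None]
    freq[missing, :] = 0.0
    return freq, missing
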