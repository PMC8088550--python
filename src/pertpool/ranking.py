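"""Pilot-survey prioritisation: Borda-style tally of forced rankings.

Each representative ranks S statements from most important (rank 1) to least
important (rank S).  A statement ranked r in a row earns S + 1 - r points
(so rank 1 earns S points — seven, for the seven-statement pilot), and the
final ordering sorts statements by total points across representatives.
Ties in totals are broken by input statement order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankingError", "RankingTable", "RankingTally", "tally_rankings",
           "read_ranking_csv", "write_tally_csv"]


class RankingError(ValueError):
    """Raised for malformed ranking tables."""


@dataclass(frozen=True)
class RankingTable:
    """Per-representative ranks: one row each, every row a permutation of 1..S."""

    statements: tuple[str, ...]
    ranks: np.ndarray  # shape (R, S), int
    representatives: tuple[str, ...]

    def __post_init__(self) -> None:
        s = len(self.statements)
        if s < 2:
            raise RankingError("need at least 2 statements to rank")
        if self.ranks.ndim != 2 or self.ranks.shape[1] != s:
            raise RankingError(
                f"ranks must be R x {s}, got shape {self.ranks.shape}"
            )
        if self.ranks.shape[0] != len(self.representatives):
            raise RankingError("one representative label per row is required")
        expected = np.arange(1, s + 1)
        for rep, row in zip(self.representatives, self.ranks):
            if not np.array_equal(np.sort(row), expected):
                raise RankingError(
                    f"representative {rep!r}: ranks {row.tolist()} are not a "
                    f"permutation of 1..{s} (incomplete rankings are rejected, "
                    "not imputed)"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankingTable":
        return cls(
            statements=tuple(str(c) for c in df.columns),
            ranks=df.to_numpy(dtype=int),
            representatives=tuple(str(i) for i in df.index),
        )

    @property
    def n_statements(self) -> int:
        return len(self.statements)

    @property
    def n_representatives(self) -> int:
        return self.ranks.shape[0]


@dataclass(frozen=True)
class RankingTally:
    """Point totals and final ordering; tied statements are flagged."""

    points: pd.Series  # indexed by statement, input order
    order: tuple[str, ...]  # descending points, stable on ties
    tied: tuple[str, ...]  # statements sharing a total with another statement

    @property
    def has_ties(self) -> bool:
        return bool(self.tied)


def tally_rankings(t: RankingTable) -> RankingTally:
    """Tally points (rank r -> S + 1 - r) and sort statements by total.

    Total points always sum to R * S * (S + 1) / 2.
    """
    s = t.n_statements
    points = (s + 1 - t.ranks).sum(axis=0)
    series = pd.Series(points, index=list(t.statements), name="points")
    # stable sort keeps input order among equal totals
    order = tuple(series.sort_values(ascending=False, kind="stable").index)
    counts = series.value_counts()
    tied = tuple(st for st in t.statements if counts[series[st]] > 1)
    return RankingTally(points=series, order=order, tied=tied)


def read_ranking_csv(path) -> RankingTable:
    """Rows = representatives (first column), columns = statements, cells = ranks."""
    df = pd.read_csv(path, index_col=0)
    try:
        return RankingTable.from_frame(df)
    except (ValueError, TypeError) as err:
        raise RankingError(f"{path}: {err}") from err


def write_tally_csv(tally: RankingTally, path) -> pd.DataFrame:
    """Write statement, points, final position and tie flag; returns the frame."""
    position = {st: i + 1 for i, st in enumerate(tally.order)}
    out = pd.DataFrame(
        {
            "statement": list(tally.points.index),
            "points": tally.points.to_numpy(),
            "final_position": [position[st] for st in tally.points.index],
            "tied": [st in tally.tied for st in tally.points.index],
        }
    )
    out.to_csv(path, index=False)
    return out
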