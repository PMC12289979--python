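"""Symmetric 2x2 social-dilemma games and gain/loss payoff categories.

A 2x2 game is described by its four role-labelled outcomes:

* ``T`` (temptation): defect while the other cooperates,
* ``R`` (reward): mutual cooperation,
* ``P`` (punishment): mutual defection,
* ``S`` (sucker): cooperate while the other defects.

The strict rank ordering of the four outcomes defines the game: the
Prisoner's Dilemma has T > R > P > S, Stag Hunt swaps the top two
(R > T > P > S), and Chicken swaps the bottom two (T > R > S > P).

Subtracting a constant from all four payoffs never changes their ranks, so
the same strategic situation can be placed anywhere on the gain/loss axis.
The sign pattern of the rank-ordered payoffs then falls into exactly five
categories, from all-gain (C1) through mixed (C2-C4) to all-loss (C5).
Zero counts as a gain (non-negative branch), so the categories are total
at the boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GameType",
    "Category",
    "PayoffMatrix",
    "MatrixSeries",
    "GameOrderingError",
    "validate_game",
    "assert_game",
    "classify_category",
    "build_series",
    "canonical_base",
    "canonical_series",
    "shifts_for_categories",
    "series_to_frame",
    "CANONICAL_SHIFTS",
]

ROLES = ("T", "R", "P", "S")


class GameType(enum.Enum):
    """The three symmetric social dilemmas, defined by their outcome ranking."""

    PD = "PD"
    SH = "SH"
    CH = "CH"

    @property
    def ordering(self) -> tuple[str, str, str, str]:
        """Role labels from highest to lowest required payoff."""
        return _ORDERINGS[self]


_ORDERINGS = {
    GameType.PD: ("T", "R", "P", "S"),
    GameType.SH: ("R", "T", "P", "S"),
    GameType.CH: ("T", "R", "S", "P"),
}


class Category(enum.Enum):
    """Sign class of a rank-ordered payoff matrix (C1 all-gain .. C5 all-loss)."""

    C1 = 1
    C2 = 2
    C3 = 3
    C4 = 4
    C5 = 5


class GameOrderingError(ValueError):
    """A payoff matrix violates the strict ordering its game requires."""


@dataclass(frozen=True)
class PayoffMatrix:
    """The four outcomes of a symmetric 2x2 game, in signed payoff units."""

    T: float
    R: float
    P: float
    S: float

    def __post_init__(self) -> None:
        for role in ROLES:
            v = getattr(self, role)
            if not math.isfinite(v):
                raise ValueError(f"payoff {role} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {role: getattr(self, role) for role in ROLES}

    def values(self) -> tuple[float, float, float, float]:
        """Payoffs in role order (T, R, P, S)."""
        return (self.T, self.R, self.P, self.S)

    def shifted(self, c: float) -> "PayoffMatrix":
        """Subtract a constant from all four payoffs (rank-preserving)."""
        return PayoffMatrix(self.T - c, self.R - c, self.P - c, self.S - c)

    def scaled(self, k: float) -> "PayoffMatrix":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return PayoffMatrix(self.T * k, self.R * k, self.P * k, self.S * k)


def validate_game(matrix: PayoffMatrix, game: GameType) -> bool:
    """True iff ``matrix`` satisfies ``game``'s strict ordering (ties fail)."""
    vals = [getattr(matrix, role) for role in game.ordering]
    return all(a > b for a, b in zip(vals, vals[1:]))


def assert_game(matrix: PayoffMatrix, game: GameType) -> None:
    """Raise :class:`GameOrderingError` naming the first violated inequality."""
    order = game.ordering
    vals = [getattr(matrix, role) for role in order]
    for (la, a), (lb, b) in zip(zip(order, vals), zip(order[1:], vals[1:])):
        if not a > b:
            raise GameOrderingError(
                f"{game.value} requires {' > '.join(order)}; "
                f"violated at {la} > {lb} ({a} > {b} is false)"
            )


def classify_category(matrix: PayoffMatrix) -> Category:
    """Classify a matrix into C1..C5 by the sign pattern of its payoffs.

    The classification uses rank positions, not role labels, so it applies
    unchanged to games whose role orderings differ.  Zero payoffs count as
    gains.  Under a strict ordering the negative payoffs are always the
    lowest ones, so counting them determines the category uniquely.
    """
    ranked = sorted(matrix.values(), reverse=True)
    n_negative = sum(v < 0 for v in ranked)
    # Negatives must occupy the bottom ranks; anything else cannot arise
    # from a totally ordered set of reals.
    assert all(v < 0 for v in ranked[4 - n_negative:]), "non-suffix sign pattern"
    return Category(n_negative + 1)


@dataclass(frozen=True)
class MatrixSeries:
    """A family of rank-equivalent matrices spanning the gain/loss axis.

    Constructed as ``stake_multiplier * base - shift`` for each shift; every
    member keeps the base game's strict ordering, and each is tagged with
    its gain/loss category.
    """

    game: GameType
    base: PayoffMatrix
    shifts: tuple[float, ...]
    stake_multiplier: float = 1.0
    matrices: tuple[PayoffMatrix, ...] = field(default=(), compare=False)
    categories: tuple[Category, ...] = field(default=(), compare=False)

    def __iter__(self):
        return iter(zip(self.matrices, self.categories, self.shifts))

    def by_category(self) -> dict[Category, list[PayoffMatrix]]:
        out: dict[Category, list[PayoffMatrix]] = {c: [] for c in Category}
        for m, c, _ in self:
            out[c].append(m)
        return out

    def covers_all_categories(self) -> bool:
        return all(self.by_category()[c] for c in Category)


def build_series(
    base: PayoffMatrix,
    game: GameType,
    shifts: Sequence[float],
    stake_multiplier: float = 1.0,
) -> MatrixSeries:
    """Build the shifted series ``stake_multiplier * base - shift``.

    Raises if ``base`` is not a valid instance of ``game`` or ``shifts`` is
    empty.  Shifting preserves ranks, so every member is re-validated only
    as a safety assertion.
    """
    assert_game(base, game)
    if len(shifts) == 0:
        raise ValueError("shifts must be non-empty")
    scaled = base.scaled(stake_multiplier)
    matrices = tuple(scaled.shifted(s) for s in shifts)
    for m in matrices:
        assert validate_game(m, game)
    categories = tuple(classify_category(m) for m in matrices)
    return MatrixSeries(
        game=game,
        base=base,
        shifts=tuple(float(s) for s in shifts),
        stake_multiplier=float(stake_multiplier),
        matrices=matrices,
        categories=categories,
    )


#: Shifts taking the canonical stake-1 bases through C1..C5 in order.
CANONICAL_SHIFTS: tuple[float, ...] = (0.0, 3.0, 4.0, 6.0, 10.0)

_CANONICAL_BASES = {
    # Stag Hunt swaps T and R relative to the PD base; Chicken swaps P and S.
    GameType.PD: PayoffMatrix(T=7, R=5, P=3, S=2),
    GameType.SH: PayoffMatrix(T=5, R=7, P=3, S=2),
    GameType.CH: PayoffMatrix(T=7, R=5, P=2, S=3),
}


def canonical_base(game: GameType) -> PayoffMatrix:
    """The canonical all-gain base matrix for each game (same payoff multiset)."""
    return _CANONICAL_BASES[game]


def canonical_series(game: GameType, stake_multiplier: float = 1.0) -> MatrixSeries:
    """One matrix per category: the canonical base under the canonical shifts.

    Shifts scale with the stake multiplier so category membership is
    preserved at every stake level.
    """
    shifts = tuple(s * stake_multiplier for s in CANONICAL_SHIFTS)
    return build_series(canonical_base(game), game, shifts, stake_multiplier)


def shifts_for_categories(
    base: PayoffMatrix,
    counts: Sequence[int],
    stake_multiplier: float = 1.0,
) -> list[float]:
    """Shifts giving ``counts[i]`` matrices in category C(i+1), i = 0..4.

    The shift axis partitions into five intervals delimited by the sorted
    payoffs of the (scaled) base; shifts are placed evenly inside each
    interval.  The open-ended C5 interval uses the payoff range as its
    width.  Used to assemble iterated-design matrix sets of any size.
    """
    if len(counts) != 5:
        raise ValueError("counts must have five entries (C1..C5)")
    a = sorted(v * stake_multiplier for v in base.values())  # ascending a4<a3<a2<a1
    lo_edges = [None, a[0], a[1], a[2], a[3]]
    hi_edges = [a[0], a[1], a[2], a[3], a[3] + (a[3] - a[0])]
    shifts: list[float] = []
    for i, k in enumerate(counts):
        if k == 0:
            continue
        lo, hi = lo_edges[i], hi_edges[i]
        if lo is None:
            # C1: any shift <= min payoff keeps all payoffs non-negative.
            pts = np.linspace(0.0, hi, k, endpoint=False) if k > 1 else np.array([0.0])
        else:
            # half-open interval (lo, hi]: place k points strictly inside
            pts = lo + (hi - lo) * (np.arange(1, k + 1) / (k + 0.5))
        shifts.extend(float(p) for p in pts)
    return shifts


def balanced_counts(n_matrices: int) -> list[int]:
    """Split ``n_matrices`` across the five categories as evenly as possible."""
    q, r = divmod(n_matrices, 5)
    return [q + (1 if i < r else 0) for i in range(5)]


def series_for_design(
    game: GameType, n_matrices: int, stake_multiplier: float = 1.0
) -> MatrixSeries:
    """A rank-equivalent series of ``n_matrices`` spread over C1..C5."""
    base = canonical_base(game)
    shifts = shifts_for_categories(base, balanced_counts(n_matrices), stake_multiplier)
    return build_series(base, game, shifts, stake_multiplier)


def bundled_canonical_frame() -> pd.DataFrame:
    """The packaged CSV fixture of the canonical series for all three games."""
    from importlib.resources import files

    with (files("lossavoid") / "data" / "canonical_series.csv").open() as fh:
        return pd.read_csv(fh)


def series_to_frame(series: MatrixSeries, stake_level: int = 0) -> pd.DataFrame:
    """Serialize a series to the canonical CSV schema."""
    rows = []
    for i, (m, c, s) in enumerate(series):
        rows.append(
            {
                "game": series.game.value,
                "matrix_id": f"{series.game.value}_s{stake_level}_m{i:02d}",
                "T": m.T,
                "R": m.R,
                "P": m.P,
                "S": m.S,
                "category": c.name,
                "stake_level": stake_level,
                "shift": s,
            }
        )
    return pd.DataFrame(rows)
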