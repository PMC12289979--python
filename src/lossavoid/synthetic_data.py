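"""Synthetic trial generators for the one-shot and iterated designs.

Two experimental designs are emulated:

* **One-shot**: each participant is assigned to one gain/loss category and
  makes a single choice per game (the same category across that
  participant's games), plus a 0-100 rating of how likely they think the
  other is to cooperate.

* **Iterated**: groups of six play round-robin (each member against each
  of the other five).  Within an interaction the matrix order is
  randomized and repetitions of a matrix are played consecutively; roles
  (row/column) are assigned once per interaction.  A ``(12, 5)`` or
  ``(20, 3)`` design gives 5 * 12 * 5 = 5 * 20 * 3 = 300 decisions per
  participant.

Choices are Bernoulli draws from the sigmoid choice model, optionally with
a participant-level random intercept (on the log-odds scale) for
mixed-model exercises.  In iterated play, reciprocity is a probabilistic
Tit-for-Tat mixture: from round 2 onward an agent copies the partner's
previous move with probability ``w`` and otherwise chooses from the model.
All randomness flows from one explicit seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .games import (
    Category,
    GameType,
    MatrixSeries,
    canonical_series,
    series_for_design,
)
from .choice_model import ChoiceModel, ValueFunction, default_choice_model, utility_difference

__all__ = [
    "AgentParams",
    "TRIAL_COLUMNS",
    "simulate_one_shot",
    "simulate_iterated_group",
    "inject_invalid_trials",
    "match_previous_rate",
    "calibrate_reciprocity",
]

#: Canonical long-format column order (one row per decision).
TRIAL_COLUMNS = [
    "experiment_id",
    "group_id",
    "participant_id",
    "partner_id",
    "interaction_id",
    "game",
    "category",
    "matrix_id",
    "repetition",
    "round",
    "role",
    "choice",
    "partner_choice",
    "partner_prev",
    "expectation",
    "stake_level",
    "test_errors",
    "valid",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the simulated participant population.

    ``w`` is the Tit-for-Tat mixture weight (probability of copying the
    partner's previous move instead of a model-based choice); ``w = 0``
    reduces the agent to the pure choice model.  ``expectation_noise`` is
    the SD of the reported 0-100 expectation around ``100 * p``.
    ``intercept_sd`` is the SD of a participant-level normal random
    intercept added to the choice log-odds (0 = homogeneous population).
    """

    vf: ValueFunction = field(default_factory=ValueFunction)
    cm: ChoiceModel = field(default_factory=default_choice_model)
    w: float = 0.0
    expectation_noise: float = 10.0
    intercept_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.expectation_noise < 0 or self.intercept_sd < 0:
            raise ValueError("dispersions must be >= 0")


def _logodds(matrix, vf, cm) -> float:
    return cm.beta * (utility_difference(matrix, vf, cm) - cm.delta0)


def _expectations(rng: np.random.Generator, p: float, noise: float, n: int) -> np.ndarray:
    raw = rng.normal(100.0 * p, noise, size=n)
    return np.clip(np.rint(raw), 0, 100).astype(int)


def simulate_one_shot(
    n_per_category: int,
    games: list[GameType],
    agents: AgentParams,
    seed: int,
    experiment_id: str = "sim_one_shot",
) -> pd.DataFrame:
    """Simulate the one-shot design: one decision per participant per game.

    ``5 * n_per_category`` participants are assigned to categories in
    exact balance; a participant keeps the same category across all games
    (mirroring the multi-game one-shot experiments).  Deterministic for a
    fixed seed.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    if not games:
        raise ValueError("games must be non-empty")
    rng = np.random.default_rng(seed)
    categories = [c for c in Category for _ in range(n_per_category)]
    n = len(categories)
    intercepts = (
        rng.normal(0.0, agents.intercept_sd, size=n)
        if agents.intercept_sd > 0
        else np.zeros(n)
    )
    series = {g: canonical_series(g) for g in games}
    rows = []
    for g in games:
        by_cat = {c: (m, f"{g.value}_m{i}") for i, (m, c, _) in enumerate(series[g])}
        logodds = np.array([_logodds(by_cat[c][0], agents.vf, agents.cm) for c in categories])
        probs = expit(logodds + intercepts)
        choices = rng.random(n) < probs
        expect = _expectations(rng, agents.cm.p, agents.expectation_noise, n)
        for i, cat in enumerate(categories):
            rows.append(
                {
                    "experiment_id": experiment_id,
                    "group_id": pd.NA,
                    "participant_id": f"p{i:04d}",
                    "partner_id": pd.NA,
                    "interaction_id": pd.NA,
                    "game": g.value,
                    "category": cat.name,
                    "matrix_id": by_cat[cat][1],
                    "repetition": 0,
                    "round": 0,
                    "role": pd.NA,
                    "choice": "C" if choices[i] else "D",
                    "partner_choice": pd.NA,
                    "partner_prev": pd.NA,
                    "expectation": expect[i],
                    "stake_level": 0,
                    "test_errors": 0,
                    "valid": True,
                }
            )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["seed"] = seed
    df.attrs["generator"] = "simulate_one_shot"
    return df


def _design_series(
    game: GameType, n_matrices: int, stake_levels: tuple[float, ...] | None
) -> list[tuple]:
    """(matrix, category, matrix_id, stake_level) tuples for one design."""
    out = []
    if stake_levels is None:
        series = series_for_design(game, n_matrices)
        for i, (m, c, _) in enumerate(series):
            out.append((m, c, f"{game.value}_m{i:02d}", 0))
    else:
        if n_matrices != 5 * len(stake_levels):
            raise ValueError(
                "with stake_levels, n_matrices must be 5 * len(stake_levels)"
            )
        for lvl, k in enumerate(stake_levels):
            series = canonical_series(game, stake_multiplier=k)
            for i, (m, c, _) in enumerate(series):
                out.append((m, c, f"{game.value}_s{lvl}_m{i}", lvl))
    return out


def simulate_iterated_group(
    n_groups: int,
    design: tuple[int, int],
    agents: AgentParams,
    seed: int,
    game: GameType = GameType.PD,
    stake_levels: tuple[float, ...] | None = None,
    experiment_id: str = "sim_iterated",
) -> pd.DataFrame:
    """Simulate round-robin groups of six with probabilistic reciprocity.

    ``design = (n_matrices, n_repetitions)``; each player faces each of
    the other five over every matrix/repetition, so decisions per player
    = 5 * n_matrices * n_repetitions (300 for both the 12x5 and 20x3
    designs).  The per-player total must be even in the sense that the
    design replicates identically across the five interactions.
    """
    n_matrices, n_reps = design
    if n_matrices < 1 or n_reps < 1:
        raise ValueError("design entries must be >= 1")
    rng = np.random.default_rng(seed)
    matrices = _design_series(game, n_matrices, stake_levels)
    cat_of = {mid: c for _, c, mid, _ in matrices}

    rows = []
    for gi in range(n_groups):
        group_id = f"g{gi:03d}"
        pids = [f"{group_id}_p{j}" for j in range(6)]
        intercepts = {
            pid: (rng.normal(0.0, agents.intercept_sd) if agents.intercept_sd > 0 else 0.0)
            for pid in pids
        }
        # model cooperation probability per player per matrix
        probs = {
            pid: {
                mid: float(expit(_logodds(m, agents.vf, agents.cm) + intercepts[pid]))
                for m, _, mid, _ in matrices
            }
            for pid in pids
        }
        for ii, (ja, jb) in enumerate(itertools.combinations(range(6), 2)):
            pa, pb = pids[ja], pids[jb]
            interaction_id = f"{group_id}_i{ii:02d}"
            order = rng.permutation(len(matrices))
            role_a, role_b = ("row", "column") if rng.random() < 0.5 else ("column", "row")
            prev = {pa: None, pb: None}
            rnd = 0
            for mi in order:
                m, cat, mid, lvl = matrices[mi]
                for rep in range(n_reps):
                    rnd += 1
                    choice = {}
                    for me, other in ((pa, pb), (pb, pa)):
                        if prev[other] is not None and rng.random() < agents.w:
                            choice[me] = prev[other]
                        else:
                            choice[me] = "C" if rng.random() < probs[me][mid] else "D"
                    for me, other, role in ((pa, pb, role_a), (pb, pa, role_b)):
                        rows.append(
                            {
                                "experiment_id": experiment_id,
                                "group_id": group_id,
                                "participant_id": me,
                                "partner_id": other,
                                "interaction_id": interaction_id,
                                "game": game.value,
                                "category": cat.name,
                                "matrix_id": mid,
                                "repetition": rep,
                                "round": rnd,
                                "role": role,
                                "choice": choice[me],
                                "partner_choice": choice[other],
                                "partner_prev": prev[other] if prev[other] is not None else pd.NA,
                                "expectation": pd.NA,
                                "stake_level": lvl,
                                "test_errors": 0,
                                "valid": True,
                            }
                        )
                    prev = {pa: choice[pa], pb: choice[pb]}
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["seed"] = seed
    df.attrs["generator"] = "simulate_iterated_group"
    return df


def inject_invalid_trials(records: pd.DataFrame, rates, seed: int) -> pd.DataFrame:
    """Flag a random per-participant subset of trials as invalid.

    ``rates`` is a scalar rate applied to everyone or a mapping
    ``participant_id -> rate``; each trial is flagged independently with
    its participant's rate.  Returns a copy; reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    if np.isscalar(rates):
        rate_of = {pid: float(rates) for pid in out["participant_id"].unique()}
    else:
        rate_of = {pid: float(rates.get(pid, 0.0)) for pid in out["participant_id"].unique()}
    bad = [float(r) < 0 or float(r) > 1 for r in rate_of.values()]
    if any(bad):
        raise ValueError("rates must be in [0, 1]")
    invalid = np.zeros(len(out), dtype=bool)
    for pid, rate in rate_of.items():
        mask = (out["participant_id"] == pid).to_numpy()
        invalid[mask] = rng.random(mask.sum()) < rate
    out.loc[invalid, "valid"] = False
    return out


def match_previous_rate(records: pd.DataFrame) -> float:
    """Fraction of decisions equal to the partner's previous move.

    Only rounds with a defined previous move (round > 1 of an interaction)
    enter the denominator.
    """
    has_prev = records["partner_prev"].notna()
    if not has_prev.any():
        raise ValueError("no rounds with a defined previous partner move")
    sub = records.loc[has_prev]
    return float((sub["choice"] == sub["partner_prev"]).mean())


def calibrate_reciprocity(
    target: float,
    agents: AgentParams,
    seed: int,
    n_groups: int = 4,
    design: tuple[int, int] = (12, 5),
    tol: float = 0.01,
    max_iter: int = 20,
) -> float:
    """Find the Tit-for-Tat weight ``w`` reproducing a target match rate.

    Bisection on ``w`` with common random numbers (the same seed per
    evaluation), exploiting that the match rate is monotone in ``w``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must be in (0, 1)")

    def rate(w: float) -> float:
        df = simulate_iterated_group(
            n_groups, design, replace(agents, w=w), seed=seed
        )
        return match_previous_rate(df)

    lo, hi = 0.0, 1.0
    r_lo, r_hi = rate(lo), rate(hi)
    if not r_lo <= target <= r_hi:
        raise ValueError(
            f"target {target} outside attainable range [{r_lo:.3f}, {r_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) < tol:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
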