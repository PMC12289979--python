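"""Piecewise-linear utility, expected utility, and sigmoid choice.

The model maps each objective payoff ``x`` to a subjective value

    v(x) = x            for x >= 0
    v(x) = lambda*x - b for x < 0

``lambda`` (loss slope) > 1 expresses loss aversion: losses loom larger
than equal-sized gains.  ``b`` > 0 expresses loss avoidance: a fixed
"utility fine" applied to any loss irrespective of magnitude.  Both
branches are linear; for the payoff ranges studied here, empirically
estimated curvature exponents (~0.9) are close enough to 1 that linearity
changes none of the category-level predictions.

With ``p`` the probability that the other player cooperates, the expected
utilities of cooperating and defecting are

    u(C) = p*v(R) + (1-p)*v(S)
    u(D) = p*v(T) + (1-p)*v(P)

and the cooperation probability is a logistic function of the utility
difference, ``sigmoid(beta * ((u(C) - u(D)) - delta0))``.  The offset
``delta0`` is calibrated once on the all-gain Prisoner's Dilemma base
matrix with the identity value function, so that the neutral PD predicts
exactly 50% cooperation; the same offset is reused for Stag Hunt and
Chicken, which then predict higher overall cooperation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .games import (
    Category,
    GameType,
    MatrixSeries,
    PayoffMatrix,
    canonical_base,
    classify_category,
)

__all__ = [
    "ValueFunction",
    "ChoiceModel",
    "CategoryProfile",
    "IDENTITY_VF",
    "LOSS_AVERSE_VF",
    "LOSS_AVOIDANT_VF",
    "subjective_value",
    "expected_utilities",
    "calibrate_offset",
    "default_choice_model",
    "utility_difference",
    "coop_probability",
    "predict_profile",
    "analytic_category_shift",
    "profile_frame",
]


@dataclass(frozen=True)
class ValueFunction:
    """Piecewise-linear value function with loss slope and loss intercept.

    Parameters
    ----------
    lambda_ : loss slope (dimensionless, >= 0); 1 means no loss aversion.
    b : loss-avoidance intercept in payoff units (>= 0); 0 means no
        loss avoidance.
    """

    lambda_: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x >= 0, x, self.lambda_ * x - self.b)
        return float(out) if out.ndim == 0 else out


#: Identity utility: no gain/loss asymmetry at all.
IDENTITY_VF = ValueFunction(1.0, 0.0)
#: Pure loss aversion at the conventional population value.
LOSS_AVERSE_VF = ValueFunction(2.0, 0.0)
#: Pure loss avoidance at the reference intercept.
LOSS_AVOIDANT_VF = ValueFunction(1.0, 4.0)


def subjective_value(x: float, vf: ValueFunction) -> float:
    """Value of a single payoff: x on gains (x >= 0), lambda*x - b on losses."""
    return vf(x)


def expected_utilities(
    matrix: PayoffMatrix, p: float, vf: ValueFunction
) -> tuple[float, float]:
    """Expected utilities (u(C), u(D)) given the other cooperates with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    uC = p * vf(matrix.R) + (1.0 - p) * vf(matrix.S)
    uD = p * vf(matrix.T) + (1.0 - p) * vf(matrix.P)
    return uC, uD


def calibrate_offset(reference: PayoffMatrix, p: float = 0.5) -> float:
    """Sigmoid inflection offset: u(C) - u(D) on the all-gain reference.

    Computed with the *identity* value function, so the neutral reference
    game sits exactly at the sigmoid's 50% point regardless of the loss
    parameters later applied.  The reference must be all-gain (category C1).
    """
    if classify_category(reference) is not Category.C1:
        raise ValueError("calibration reference must be all-gain (C1)")
    uC, uD = expected_utilities(reference, p, IDENTITY_VF)
    return uC - uD


@dataclass(frozen=True)
class ChoiceModel:
    """Sigmoid choice rule: p (expectation), beta (inverse temperature), delta0."""

    p: float = 0.5
    beta: float = 1.0
    delta0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def with_p(self, p: float) -> "ChoiceModel":
        return replace(self, p=p)


def default_choice_model(p: float = 0.5, beta: float = 1.0) -> ChoiceModel:
    """Choice model calibrated on the canonical all-gain PD base matrix."""
    return ChoiceModel(p=p, beta=beta, delta0=calibrate_offset(canonical_base(GameType.PD), p))


def utility_difference(matrix: PayoffMatrix, vf: ValueFunction, cm: ChoiceModel) -> float:
    """u(C) - u(D) under the model's expectation and value function."""
    uC, uD = expected_utilities(matrix, cm.p, vf)
    return uC - uD


def coop_probability(
    matrix: PayoffMatrix,
    game: GameType,
    vf: ValueFunction,
    cm: ChoiceModel,
) -> float:
    """Predicted cooperation probability sigmoid(beta*((uC-uD) - delta0))."""
    from .games import assert_game

    assert_game(matrix, game)
    du = utility_difference(matrix, vf, cm)
    return float(expit(cm.beta * (du - cm.delta0)))


@dataclass(frozen=True)
class CategoryProfile:
    """Mean predicted cooperation probability per category for one game."""

    game: GameType
    probs: dict  # Category -> float in [0, 1]
    vf: ValueFunction
    cm: ChoiceModel

    def __getitem__(self, category: Category) -> float:
        return self.probs[category]

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[c] for c in Category])


def predict_profile(series: MatrixSeries, vf: ValueFunction, cm: ChoiceModel) -> CategoryProfile:
    """Per-category mean cooperation probability over a matrix series.

    Aggregation is the unweighted arithmetic mean over the matrices in each
    category; every category must be represented by at least one matrix.
    """
    grouped = series.by_category()
    probs: dict[Category, float] = {}
    for cat in Category:
        mats = grouped[cat]
        if not mats:
            raise ValueError(f"series has no matrix in category {cat.name}")
        probs[cat] = float(
            np.mean([coop_probability(m, series.game, vf, cm) for m in mats])
        )
    return CategoryProfile(game=series.game, probs=probs, vf=vf, cm=cm)


# Which side of the utility difference the lone negative payoff lands on,
# per game: the minimum payoff (C2 case) and the payoffs below the maximum
# (C4 case) differ between orderings.  Signs derived from u(C) - u(D) with
# v(x) = x - b on losses.
_C2_SIGN = {GameType.PD: -1.0, GameType.SH: -1.0, GameType.CH: +1.0}


def analytic_category_shift(
    game: GameType, category: Category, vf: ValueFunction, p: float
) -> float:
    """Closed-form change in u(C) - u(D) vs. the all-gain baseline (lambda=1).

    With a pure loss-avoidance value function (lambda = 1, intercept b),
    the intercept subtracts b from every negative payoff's value, so the
    utility-difference shift depends only on which side (C or D) carries
    the negative payoffs:

    * C1 (none negative), C3 (both players' low pair negative) and C5
      (all negative) penalize C and D equally: shift 0.
    * C2 (only the minimum negative): the minimum sits on the C side for
      PD and SH (it is S) but on the D side for Chicken (it is P).
    * C4 (only the maximum non-negative): complementary to C2 plus an
      equal -b on both sides, giving the opposite-signed p-weighted term.
    """
    if vf.lambda_ != 1.0:
        raise ValueError("analytic shifts require lambda = 1 (pure loss avoidance)")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    b = vf.b
    if category in (Category.C1, Category.C3, Category.C5):
        return 0.0
    if category is Category.C2:
        return _C2_SIGN[game] * (1.0 - p) * b
    # C4: all payoffs penalized except the maximum; net of the shared -b
    # terms this is the p-weighted complement of the C2 case.
    if game is GameType.PD:
        return -p * b
    if game is GameType.SH:
        return +p * b
    return -p * b  # Chicken


def profile_frame(profiles: list[CategoryProfile]) -> "np.typing.ArrayLike":
    """Tidy export of prediction profiles (game, category, rate, parameters)."""
    import pandas as pd

    rows = []
    for pr in profiles:
        for cat in Category:
            rows.append(
                {
                    "game": pr.game.value,
                    "category": cat.name,
                    "predicted_coop_rate": pr.probs[cat],
                    "lambda": pr.vf.lambda_,
                    "b": pr.vf.b,
                    "beta": pr.cm.beta,
                    "p": pr.cm.p,
                }
            )
    return pd.DataFrame(rows)
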