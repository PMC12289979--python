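# lossavoid

Loss avoidance versus loss aversion in gain/loss-shifted 2×2 social
dilemmas: a choice model, synthetic experiment generators, and the full
statistical contrast battery.

## The problem

When the outcomes of a social dilemma can be gains or losses, do people
merely *weigh* losses more than gains (loss aversion, the steeper loss
slope of prospect theory), or do they try to *avoid* losses altogether
(loss avoidance, a fixed "utility fine" on any loss regardless of
magnitude)? The two asymmetries are usually conflated. They can be
disentangled by taking a symmetric 2×2 game — Prisoner's Dilemma
(T > R > P > S), Stag Hunt (R > T > P > S), or Chicken (T > R > S > P) —
and subtracting a constant from all four payoffs. Shifting never changes
the strategic structure (ranks are invariant), but it moves the matrix
through five sign categories: all-gain (C1), only the minimum negative
(C2), the two lowest negative (C3), only the maximum non-negative (C4),
and all-loss (C5). The two asymmetries then make different, testable
predictions about cooperation across categories — and in Stag Hunt and
Chicken the predictions flip sign relative to the Prisoner's Dilemma, so
avoiding a loss sometimes means cooperating *more* and sometimes *less*.

This package is for behavioural/experimental researchers who want to
simulate those predictions, generate synthetic one-shot or iterated
experiments with the same statistical structure, run the associated
contrast battery, or re-analyse deposited trial data.

## The model

Each payoff x is filtered through a piecewise-linear value function

    v(x) = x             if x ≥ 0
    v(x) = λx − b        if x < 0

where λ ≥ 1 is the loss-aversion slope and b ≥ 0 the loss-avoidance
intercept. With p the probability that the other player cooperates,

    u(C) = p·v(R) + (1−p)·v(S)
    u(D) = p·v(T) + (1−p)·v(P)

and the cooperation probability is logistic,
`P(C) = σ(β·((u(C) − u(D)) − δ₀))`, with β = 1 and the inflection offset
δ₀ calibrated once on the all-gain Prisoner's Dilemma base matrix
(T,R,P,S) = (7,5,3,2) under identity utility, so the neutral PD predicts
exactly 50 % cooperation.

## Worked example

```python
from lossavoid import *
from lossavoid.choice_model import LOSS_AVOIDANT_VF

cm = default_choice_model()          # delta0 calibrated on the all-gain PD base
for game in GameType:
    profile = predict_profile(canonical_series(game), LOSS_AVOIDANT_VF, cm)
    print(game.value, {c.name: round(p, 3) for c, p in profile.probs.items()})

table = reconstruct_counts(38.7, 63.5, 83)   # printed one-shot rates -> counts
print("table:", table)
r = chi2_2x2(*table, seed=0)
print(f"chi2(1, N={r.n}) = {r.statistic:.2f}, p = {r.p_value:.3f}, "
      f"phi = {r.effect_size:.2f}, 95% CI [{r.effect_size_ci[0]:.3f}, {r.effect_size_ci[1]:.3f}]")
```

prints

```
PD {'C1': 0.5, 'C2': 0.119, 'C3': 0.5, 'C4': 0.119, 'C5': 0.5}
SH {'C1': 0.881, 'C2': 0.5, 'C3': 0.881, 'C4': 0.982, 'C5': 0.881}
CH {'C1': 0.731, 'C2': 0.953, 'C3': 0.731, 'C4': 0.269, 'C5': 0.731}
table: (12, 31, 33, 52)
chi2(1, N=83) = 4.79, p = 0.029, phi = 0.24, 95% CI [0.015, 0.440]
```

Reading the profiles: pure loss avoidance (λ = 1, b = 4) leaves C1/C3/C5
untouched in every game, depresses cooperation in the PD's C2 and C4
(defection avoids the loss there), raises it in Stag Hunt's C4 and
Chicken's C2 (there *cooperation* avoids the loss), and lowers Stag
Hunt's C2 / Chicken's C4. The second block reconstructs the unique
integer 2×2 table behind a published pair of one-shot cooperation
percentages (38.7 % vs 63.5 %, N = 83) and recomputes the Pearson
chi-squared (no continuity correction) and φ = √(χ²/N) from it.

The command line mirrors the library:

```sh
lossavoid simulate-predictions --out profiles.csv
lossavoid generate --seed 11 --design one_shot --b 4 --out trials.csv
lossavoid analyze  --input trials.csv --design one_shot --seed 1 --out contrasts.csv
lossavoid reproduce --input deposited.csv --adapter adapter.yaml --seed 1 --out-dir report/
```

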