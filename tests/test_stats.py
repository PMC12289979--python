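"""Contrast battery: rates, paired t, chi-squared, ANOVA, regressions."""

import numpy as np
import pandas as pd
import pytest

from lossavoid.games import GameType
from lossavoid.choice_model import LOSS_AVOIDANT_VF, ValueFunction
from lossavoid.stats import (
    AmbiguousReconstructionError,
    InfeasibleReconstructionError,
    SeparationError,
    chi2_2x2,
    code_predictors,
    d_av_from_summary,
    logistic_glm,
    mixed_logistic_nested,
    paired_t,
    participant_category_rates,
    reconstruct_counts,
    results_frame,
    rm_anova_stake,
    run_contrast_battery,
)
from lossavoid.synthetic_data import AgentParams, simulate_iterated_group, simulate_one_shot


def _mini_records(rows):
    df = pd.DataFrame(rows)
    if "valid" not in df:
        df["valid"] = True
    df["valid"] = [True if pd.isna(v) else bool(v) for v in df["valid"]]
    if "expectation" not in df:
        df["expectation"] = pd.NA
    if "game" not in df:
        df["game"] = "PD"
    return df


# --------------------------------------------------------------------------
# per-participant rates

def test_participant_category_rates_arithmetic_and_missing():
    rows = []
    # p1: all cooperate everywhere
    for cat in ("C1", "C2", "C3", "C4", "C5"):
        rows += [dict(participant_id="p1", category=cat, choice="C")] * 2
    # p2: 3 C of 5 valid in C2, plus one invalid C that must not count
    rows += [dict(participant_id="p2", category="C2", choice="C")] * 3
    rows += [dict(participant_id="p2", category="C2", choice="D")] * 2
    rows += [dict(participant_id="p2", category="C2", choice="C", valid=False)]
    df = _mini_records(rows)
    rates = participant_category_rates(df)
    assert (rates.loc["p1"] == 1.0).all()
    assert rates.loc["p2", "C2"] == pytest.approx(0.6)
    assert np.isnan(rates.loc["p2", "C1"])  # empty cell surfaces as missing


# --------------------------------------------------------------------------
# paired t and the d_av convention

def test_paired_t_identical_sides_give_zero():
    r = paired_t([0.4, 0.6, 0.5], [0.4, 0.6, 0.5])
    assert r.statistic == 0.0
    assert r.effect_size == 0.0
    assert r.df == 2


def test_paired_t_shift_invariance_and_errors():
    rng = np.random.default_rng(0)
    x, y = rng.random(20), rng.random(20)
    r0 = paired_t(x, y)
    r1 = paired_t(x + 0.3, y + 0.3)
    assert r1.statistic == pytest.approx(r0.statistic, abs=1e-9)
    with pytest.raises(ValueError, match="equal length"):
        paired_t([1, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="pairs"):
        paired_t([np.nan, 1.0], [0.5, np.nan])


@pytest.mark.parametrize(
    "ma, sda, mb, sdb, printed",
    [
        (47.2, 24.7, 50.3, 24.3, 0.126),  # loss-avoidance pair, iterated pilot
        (47.3, 24.7, 54.2, 24.1, 0.284),  # loss-aversion pair (C1 vs C5)
    ],
)
def test_d_av_convention_reproduces_published_effect_sizes(ma, sda, mb, sdb, printed):
    """Mean diff over the average condition SD matches the published d values."""
    assert d_av_from_summary(ma, sda, mb, sdb) == pytest.approx(printed, abs=0.002)


def test_paired_t_uses_d_av_standardizer():
    rng = np.random.default_rng(3)
    x = rng.normal(0.5, 0.1, 40)
    y = rng.normal(0.45, 0.2, 40)
    r = paired_t(x, y)
    expected = (x - y).mean() / (0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1)))
    assert r.effect_size == pytest.approx(expected)


# --------------------------------------------------------------------------
# chi-squared and phi

def test_chi2_equal_proportions_is_zero():
    r = chi2_2x2(10, 20, 10, 20, n_boot=100)
    assert r.statistic == 0.0


def test_chi2_matches_textbook_pearson_formula():
    """Cell-by-cell (O-E)^2/E with no continuity correction, on the lab table."""
    a_coop, a_n, b_coop, b_n = 12, 31, 33, 52
    table = np.array([[12, 19], [33, 19]], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    chi2_manual = ((table - expected) ** 2 / expected).sum()
    r = chi2_2x2(a_coop, a_n, b_coop, b_n, n_boot=100)
    assert r.statistic == pytest.approx(chi2_manual, abs=1e-12)
    assert round(r.statistic, 2) == 4.79
    assert r.df == 1


@pytest.mark.parametrize(
    "chi2, n, phi", [(4.79, 83, 0.24), (30.12, 255, 0.34)]
)
def test_phi_is_root_chi2_over_n(chi2, n, phi):
    assert round(np.sqrt(chi2 / n), 2) == phi


def test_chi2_phi_identity_and_side_swap():
    r = chi2_2x2(12, 31, 33, 52, n_boot=100)
    assert r.effect_size == pytest.approx(np.sqrt(r.statistic / r.n), abs=1e-12)
    swapped = chi2_2x2(33, 52, 12, 31, n_boot=100)
    assert swapped.statistic == pytest.approx(r.statistic, abs=1e-12)


def test_chi2_bootstrap_ci_is_seeded_and_brackets_phi():
    r1 = chi2_2x2(12, 31, 33, 52, seed=5, n_boot=2000)
    r2 = chi2_2x2(12, 31, 33, 52, seed=5, n_boot=2000)
    assert r1.effect_size_ci == r2.effect_size_ci
    lo, hi = r1.effect_size_ci
    assert lo < r1.effect_size < hi


def test_chi2_rejects_zero_margins_and_bad_counts():
    with pytest.raises(ValueError, match="zero margin"):
        chi2_2x2(0, 10, 0, 12)
    with pytest.raises(ValueError):
        chi2_2x2(11, 10, 3, 12)


# --------------------------------------------------------------------------
# table reconstruction from printed rates

def test_reconstruct_unique_lab_table():
    assert reconstruct_counts(38.7, 63.5, 83) == (12, 31, 33, 52)


def test_reconstruct_signals_ambiguity_and_infeasibility():
    with pytest.raises(AmbiguousReconstructionError) as exc:
        reconstruct_counts(50.0, 50.0, 8, decimals=0)
    assert len(exc.value.candidates) > 1
    with pytest.raises(AmbiguousReconstructionError):
        reconstruct_counts(0.0, 100.0, 10, decimals=0)
    with pytest.raises(InfeasibleReconstructionError):
        reconstruct_counts(33.3, 66.7, 4)


# --------------------------------------------------------------------------
# repeated-measures ANOVA

def _stake_table(seed, side_effect=0.0, stake_effect=0.0, n_subj=44):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        subj_mean = rng.normal(0.5, 0.1)
        for stake in range(4):
            for side, eff in (("c135", side_effect / 2), ("c24", -side_effect / 2)):
                rows.append(
                    dict(
                        participant_id=f"s{s}",
                        stake_level=stake,
                        side=side,
                        rate=np.clip(
                            subj_mean + eff + stake * stake_effect + rng.normal(0, 0.08),
                            0,
                            1,
                        ),
                    )
                )
    return pd.DataFrame(rows)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_rm_anova_zero_variance_means_zero_effect_sums_of_squares():
    df = _stake_table(1)
    df["rate"] = 0.5
    aov = rm_anova_stake(df)
    assert np.allclose(aov["SS"], 0.0)


def test_rm_anova_detects_avoidance_not_stake():
    """Avoidance main effect present, stake absent, at the lab sample size."""
    hits_side, hits_stake = 0, 0
    for seed in range(10):
        aov = rm_anova_stake(_stake_table(seed, side_effect=0.06)).set_index("Source")
        if aov.loc["side", "p_unc"] < 0.05:
            hits_side += 1
        if aov.loc["stake_level", "p_unc"] < 0.05:
            hits_stake += 1
    assert hits_side >= 8
    assert hits_stake <= 3


def test_rm_anova_requires_full_crossing():
    df = _stake_table(2).iloc[:-1]
    with pytest.raises(ValueError, match="crossed"):
        rm_anova_stake(df)


# --------------------------------------------------------------------------
# predictor codings

def test_avoidance_codings_by_game():
    rows = [dict(participant_id=f"p{i}", category=f"C{i+1}", choice="C") for i in range(5)]
    df = _mini_records(rows)
    pd_coded = code_predictors(df, GameType.PD).set_index("category")
    assert pd_coded.loc["C3", "avoidance"] == pd_coded.loc["C1", "avoidance"]
    assert pd_coded.loc["C2", "avoidance"] == pd_coded.loc["C4", "avoidance"]
    sh = code_predictors(df, GameType.SH).set_index("category")
    ch = code_predictors(df, GameType.CH).set_index("category")
    # C4 is the avoid-loss-by-cooperating cell in SH but the opposite in PD/CH
    assert sh.loc["C4", "avoidance"] == 1.0
    assert ch.loc["C4", "avoidance"] == -1.0
    assert pd_coded.loc["C4", "avoidance"] > 0  # defect-favoring side in PD
    # aversion is the centered linear trend
    assert list(sh["aversion"]) == [-2.0, -1.0, 0.0, 1.0, 2.0]
    with pytest.raises(ValueError, match="unknown categories"):
        code_predictors(_mini_records([dict(participant_id="p", category="C9", choice="C")]), GameType.PD)


def test_pd_codings_orthogonal_over_balanced_design():
    rows = [
        dict(participant_id=f"p{i}_{c}", category=f"C{c}", choice="C")
        for c in range(1, 6)
        for i in range(4)
    ]
    coded = code_predictors(_mini_records(rows), GameType.PD)
    assert np.dot(coded["avoidance"], coded["aversion"]) == pytest.approx(0.0, abs=1e-12)


def test_partner_prev_coding_missing_on_round_one(iterated_pd):
    coded = code_predictors(iterated_pd, GameType.PD)
    first = coded[coded["round"] == 1]
    assert first["partner_prev_c"].isna().all()
    later = coded[coded["round"] > 1]
    assert set(later["partner_prev_c"].unique()) <= {0.5, -0.5}


# --------------------------------------------------------------------------
# logistic regression

def test_logistic_glm_recovers_avoidance_direction(avoidant_agents):
    hits = 0
    for seed in range(20):
        df = simulate_one_shot(120, [GameType.PD], avoidant_agents, seed=1000 + seed)
        fit = logistic_glm(df, GameType.PD)
        if fit.pvalue("avoidance") < 0.05 and fit.coef("avoidance") < 0:
            hits += 1
    assert hits >= 16


def test_logistic_glm_null_coverage(null_agents):
    covered = 0
    for seed in range(40):
        df = simulate_one_shot(120, [GameType.PD], null_agents, seed=3000 + seed)
        fit = logistic_glm(df, GameType.PD)
        row = fit.params.set_index("term").loc["avoidance"]
        if row["ci_low"] <= 0 <= row["ci_high"]:
            covered += 1
    assert covered >= 33  # ~95% nominal; binomial slack at 40 replicates


def test_logistic_glm_raises_on_constant_outcome(null_agents):
    df = simulate_one_shot(5, [GameType.PD], null_agents, seed=1)
    df["choice"] = "C"
    with pytest.raises(SeparationError):
        logistic_glm(df, GameType.PD)


# --------------------------------------------------------------------------
# nested mixed logistic (lme4 backend)

def test_mixed_logistic_collapses_without_heterogeneity(avoidant_agents):
    """No clustering in the generator: variances ~0, fixed effects match GLM."""
    agents = AgentParams(vf=avoidant_agents.vf, w=0.0)
    df = simulate_iterated_group(4, (12, 5), agents, seed=21)
    mixed = mixed_logistic_nested(df, terms=("avoidance", "aversion"))
    glm = logistic_glm(df, GameType.PD)
    assert all(sd < 0.15 for sd in mixed.variance_components.values())
    assert mixed.coef("avoidance") == pytest.approx(glm.coef("avoidance"), abs=0.05)
    assert mixed.coef("avoidance") < 0
    assert mixed.pvalue("avoidance") < 0.001


def test_mixed_logistic_recovers_participant_intercept_sd(avoidant_agents):
    agents = AgentParams(vf=avoidant_agents.vf, w=0.0, intercept_sd=1.0)
    df = simulate_iterated_group(8, (12, 5), agents, seed=31)
    mixed = mixed_logistic_nested(df, terms=("avoidance", "aversion"))
    sd = mixed.variance_components["f_part"]
    assert 0.7 <= sd <= 1.3


def test_mixed_logistic_partner_prev_dominates_but_avoidance_stable(avoidant_agents):
    agents = AgentParams(vf=avoidant_agents.vf, w=0.6)
    df = simulate_iterated_group(6, (12, 5), agents, seed=41)
    with_hist = mixed_logistic_nested(df)
    without = mixed_logistic_nested(df, terms=("avoidance", "aversion"))
    assert with_hist.coef("partner_prev_c") > 1.0
    assert with_hist.pvalue("partner_prev_c") < 1e-6
    assert np.sign(with_hist.coef("avoidance")) == np.sign(without.coef("avoidance")) == -1


# --------------------------------------------------------------------------
# the battery

def test_battery_orderings_for_sh_and_ch(avoidant_agents):
    for game, top, bottom in (
        (GameType.SH, "sh_c4_vs_c135", "sh_c135_vs_c2"),
        (GameType.CH, "ch_c2_vs_c135", "ch_c135_vs_c4"),
    ):
        df = simulate_one_shot(250, [game], avoidant_agents, seed=17)
        results = {r.name: r for r in run_contrast_battery(df, game, "one_shot", n_boot=200)}
        assert results[top].rate_a > results[top].rate_b
        assert results[bottom].rate_a > results[bottom].rate_b


def test_battery_uses_paired_t_for_iterated(iterated_pd):
    results = run_contrast_battery(iterated_pd, GameType.PD, "iterated")
    names = [r.name for r in results]
    assert names == ["pd_c24_vs_c135", "pd_c1_vs_c5"]
    assert all(r.effect_size_name == "d_av" for r in results)
    frame = results_frame(results)
    assert list(frame["contrast"]) == names
    with pytest.raises(ValueError):
        run_contrast_battery(iterated_pd, GameType.PD, "weekly")
    with pytest.raises(ValueError, match="no records"):
        run_contrast_battery(iterated_pd, GameType.SH, "iterated")
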