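"""Contrast battery and regression models for cooperation-rate inference.

Implements the full analysis battery used for gain/loss-shifted social
dilemmas:

* per-participant cooperation rates by category (iterated designs),
* paired t tests with the ``d_av`` effect size (mean difference divided by
  the average of the two condition SDs),
* Pearson chi-squared tests on 2x2 tables *without* continuity correction,
  with the phi coefficient ``sqrt(chi2 / N)`` and a seeded bias-corrected
  bootstrap CI,
* integer reconstruction of 2x2 tables from printed percentages,
* two-way repeated-measures ANOVA (stake size x loss-avoidance side),
* fixed-effect logistic regression with loss-avoidance / loss-aversion
  contrast codings, and
* nested mixed-effects logistic regression (participant within group
  within experiment) fitted by Laplace-approximated maximum likelihood
  via lme4::glmer.

Predictor codings: loss avoidance is a game-specific category contrast
(for the Prisoner's Dilemma the C2/C4-vs-C1/C3/C5 split, zero-sum over a
balanced design and orthogonal to the linear trend; for Stag Hunt and
Chicken a +1/0/-1 coding of the category predicted up vs. down).  Loss
aversion is the centered linear trend over C1..C5.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps

from .games import Category, GameType

__all__ = [
    "ContrastResult",
    "RegressionResult",
    "SeparationError",
    "AmbiguousReconstructionError",
    "InfeasibleReconstructionError",
    "CONTRAST_BATTERY",
    "choice01",
    "participant_category_rates",
    "paired_t",
    "chi2_2x2",
    "reconstruct_counts",
    "rm_anova_stake",
    "code_predictors",
    "logistic_glm",
    "mixed_logistic_nested",
    "run_contrast_battery",
    "results_frame",
]


# --------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class ContrastResult:
    """One contrast: statistic, df, p, effect size with CI, observed rates."""

    name: str
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_size_name: str
    effect_size_ci: tuple[float, float]
    n: int
    rate_a: float
    rate_b: float
    mean_diff_ci: tuple[float, float] = (float("nan"), float("nan"))


@dataclass(frozen=True)
class RegressionResult:
    """Coefficient table plus model-level diagnostics."""

    params: pd.DataFrame  # term, coef, se, z, p, ci_low, ci_high
    llf: float
    n_obs: int
    method: str
    variance_components: dict = dc_field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    messages: tuple[str, ...] = ()

    def coef(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "p"])


class SeparationError(RuntimeError):
    """The logistic likelihood is degenerate (perfect or constant outcome)."""


class AmbiguousReconstructionError(ValueError):
    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            f"{len(candidates)} integer tables match the printed rates; "
            "cannot pick one silently"
        )


class InfeasibleReconstructionError(ValueError):
    pass


# --------------------------------------------------------------------------
# rates and simple contrasts

def choice01(records: pd.DataFrame) -> pd.Series:
    """Numeric choice: 1 for cooperate, 0 for defect."""
    return (records["choice"] == "C").astype(int)


def participant_category_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant cooperation rate in each category (valid trials only).

    Returns a participant x category table; a cell with zero valid trials
    is left missing (NaN) rather than imputed.
    """
    valid = records[records["valid"].astype(bool)].copy()
    if valid.empty:
        raise ValueError("no valid trials")
    valid["coop"] = choice01(valid)
    table = valid.pivot_table(
        index="participant_id", columns="category", values="coop", aggfunc="mean"
    )
    return table.reindex(columns=[c.name for c in Category])


def d_av_from_summary(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """d_av from condition summaries: |mean difference| / mean of the SDs."""
    return abs(mean_a - mean_b) / (0.5 * (sd_a + sd_b))


def paired_t(x, y, name: str = "paired_t") -> ContrastResult:
    """Two-sided paired t test with the d_av effect-size convention.

    ``d_av = mean(x - y) / ((SD(x) + SD(y)) / 2)`` -- the standardizer is
    the average of the two condition SDs, not the SD of the differences.
    The CI is a 95% interval on the mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two complete pairs")
    d = x - y
    t, p = sps.ttest_rel(x, y)
    sd_x, sd_y = np.std(x, ddof=1), np.std(y, ddof=1)
    denom = 0.5 * (sd_x + sd_y)
    d_av = float(d.mean() / denom) if denom > 0 else 0.0
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
    return ContrastResult(
        name=name,
        statistic=float(t) if np.isfinite(t) else 0.0,
        df=n - 1,
        p_value=float(p) if np.isfinite(p) else 1.0,
        effect_size=d_av,
        effect_size_name="d_av",
        effect_size_ci=(float("nan"), float("nan")),
        n=n,
        rate_a=float(x.mean()),
        rate_b=float(y.mean()),
        mean_diff_ci=ci,
    )


def _signed_phi(a_coop, a_non, b_coop, b_non):
    """Correlation-style phi of a 2x2 table (sign = direction of association)."""
    a_coop = np.asarray(a_coop, dtype=float)
    num = a_coop * b_non - a_non * b_coop
    r1 = a_coop + a_non
    r2 = b_coop + b_non
    c1 = a_coop + b_coop
    c2 = a_non + b_non
    denom = np.sqrt(r1 * r2 * c1 * c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, num / denom, 0.0)
    return out


def chi2_2x2(
    a_coop: int,
    a_n: int,
    b_coop: int,
    b_n: int,
    name: str = "chi2",
    n_boot: int = 10_000,
    seed: int = 0,
) -> ContrastResult:
    """Pearson chi-squared (df=1, no continuity correction) with phi and CI.

    phi is reported as ``sqrt(chi2 / N)``; its CI comes from a seeded
    bias-corrected bootstrap of the signed table correlation, oriented so
    the point estimate is non-negative (the lower bound may be negative).
    """
    for v in (a_coop, a_n, b_coop, b_n):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if a_coop > a_n or b_coop > b_n:
        raise ValueError("cooperation counts cannot exceed group sizes")
    table = np.array([[a_coop, a_n - a_coop], [b_coop, b_n - b_coop]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    n_total = a_n + b_n
    phi = float(np.sqrt(chi2 / n_total))

    rng = np.random.default_rng(seed)
    pa, pb = a_coop / a_n, b_coop / b_n
    ca = rng.binomial(a_n, pa, size=n_boot)
    cb = rng.binomial(b_n, pb, size=n_boot)
    sign = np.sign(_signed_phi(a_coop, a_n - a_coop, b_coop, b_n - b_coop)) or 1.0
    boot = sign * _signed_phi(ca, a_n - ca, cb, b_n - cb)
    # bias-corrected percentile interval
    prop_below = np.clip((boot < phi).mean(), 1e-9, 1 - 1e-9)
    z0 = sps.norm.ppf(prop_below)
    zcrit = sps.norm.ppf(0.975)
    lo_q = sps.norm.cdf(2 * z0 - zcrit)
    hi_q = sps.norm.cdf(2 * z0 + zcrit)
    ci = (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))
    return ContrastResult(
        name=name,
        statistic=float(chi2),
        df=float(dof),
        p_value=float(p),
        effect_size=phi,
        effect_size_name="phi",
        effect_size_ci=ci,
        n=int(n_total),
        rate_a=pa,
        rate_b=pb,
    )


def reconstruct_counts(
    rate_a: float, rate_b: float, n_total: int, decimals: int = 1
) -> tuple[int, int, int, int]:
    """Recover the integer 2x2 table behind two printed percentages.

    Exhaustively searches all splits ``n_a + n_b = n_total`` and all
    cooperation counts whose percentage rounds (at ``decimals`` places) to
    the printed rates.  Returns the unique ``(a_coop, a_n, b_coop, b_n)``;
    raises explicitly on ambiguity (listing all candidates) or
    infeasibility -- it never silently picks one.
    """
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    tol = 0.5 * 10.0 ** (-decimals) + 1e-9
    candidates = []
    for n_a in range(1, n_total):
        n_b = n_total - n_a
        ca = np.arange(n_a + 1)
        ok_a = ca[np.abs(100.0 * ca / n_a - rate_a) <= tol]
        if len(ok_a) == 0:
            continue
        cb = np.arange(n_b + 1)
        ok_b = cb[np.abs(100.0 * cb / n_b - rate_b) <= tol]
        for a in ok_a:
            for b in ok_b:
                candidates.append((int(a), n_a, int(b), n_b))
    if not candidates:
        raise InfeasibleReconstructionError(
            f"no integer table matches ({rate_a}%, {rate_b}%) at N={n_total}"
        )
    if len(candidates) > 1:
        raise AmbiguousReconstructionError(candidates)
    return candidates[0]


# --------------------------------------------------------------------------
# repeated-measures ANOVA

def rm_anova_stake(
    data: pd.DataFrame,
    dv: str = "rate",
    subject: str = "participant_id",
    within: tuple[str, str] = ("stake_level", "side"),
) -> pd.DataFrame:
    """Two-way within-subject ANOVA: stake size x loss-avoidance side.

    Expects a fully crossed long table (every subject observed in every
    stake x side cell).  Returns the ANOVA table with F, df, p and the
    Greenhouse-Geisser sphericity correction as reported by pingouin.
    """
    import pingouin as pg

    cells = data.groupby([subject, *within], observed=True)[dv].count()
    expected = data[subject].nunique() * data[within[0]].nunique() * data[within[1]].nunique()
    if len(cells) != expected or (cells == 0).any():
        raise ValueError("design is not fully crossed: missing subject x cell entries")
    aov = pg.rm_anova(
        data=data, dv=dv, within=list(within), subject=subject, detailed=True
    )
    return aov


# --------------------------------------------------------------------------
# predictor codings and regressions

# Loss-avoidance codings per game.  PD: zero-sum two-sided split (C2/C4
# high); SH/CH: +1 for the category predicted up, -1 for the one predicted
# down, 0 elsewhere.
_AVOIDANCE_CODES = {
    GameType.PD: {"C1": -0.4, "C2": 0.6, "C3": -0.4, "C4": 0.6, "C5": -0.4},
    GameType.SH: {"C1": 0.0, "C2": -1.0, "C3": 0.0, "C4": 1.0, "C5": 0.0},
    GameType.CH: {"C1": 0.0, "C2": 1.0, "C3": 0.0, "C4": -1.0, "C5": 0.0},
}
_AVERSION_CODE = {"C1": -2.0, "C2": -1.0, "C3": 0.0, "C4": 1.0, "C5": 2.0}


def code_predictors(records: pd.DataFrame, game: GameType) -> pd.DataFrame:
    """Attach model predictors: avoidance, aversion, expectation, reciprocity.

    * ``avoidance``: game-specific category contrast (see module docstring);
    * ``aversion``: centered linear trend over C1..C5 (-2..+2);
    * ``expectation_c``: the 0-100 expectation rating centered at its mean
      (missing where no rating was collected);
    * ``partner_prev_c``: partner's previous move as +-0.5 (iterated only;
      missing on round 1).
    """
    out = records.copy()
    codes = _AVOIDANCE_CODES[game]
    unknown = set(out["category"].unique()) - set(codes)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    out["choice01"] = choice01(out)
    out["avoidance"] = out["category"].map(codes).astype(float)
    out["aversion"] = out["category"].map(_AVERSION_CODE).astype(float)
    exp = pd.to_numeric(out["expectation"], errors="coerce")
    out["expectation_c"] = exp - exp.mean() if exp.notna().any() else np.nan
    if "partner_prev" in out.columns:
        out["partner_prev_c"] = out["partner_prev"].map({"C": 0.5, "D": -0.5})
        out["partner_prev_c"] = pd.to_numeric(out["partner_prev_c"], errors="coerce")
    else:
        out["partner_prev_c"] = np.nan
    return out


def logistic_glm(
    records: pd.DataFrame,
    game: GameType,
    terms: tuple[str, ...] = ("avoidance", "aversion"),
) -> RegressionResult:
    """Fixed-effect logistic regression of choice on the coded predictors.

    Maximum-likelihood fit with Wald z tests and 95% intervals.  Complete
    separation (including a constant outcome) raises
    :class:`SeparationError` instead of being silently regularized.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    coded = code_predictors(records[records["valid"].astype(bool)], game)
    cols = ["choice01", *terms]
    coded = coded.dropna(subset=cols)
    y = coded["choice01"].to_numpy()
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is constant; logistic fit is degenerate")
    X = sm.add_constant(coded[list(terms)].astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=False)
    except PerfectSeparationError as e:  # pragma: no cover - depends on data
        raise SeparationError(str(e)) from e
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
        raise SeparationError("separation detected: unbounded coefficient estimates")
    conf = fit.conf_int()
    params = pd.DataFrame(
        {
            "term": X.columns,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_low": conf[0].to_numpy(),
            "ci_high": conf[1].to_numpy(),
        }
    )
    return RegressionResult(
        params=params, llf=float(fit.llf), n_obs=int(fit.nobs), method="logit_ml"
    )


_GLMER_SCRIPT = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1])
rhs <- args[3]
fit <- glmer(as.formula(paste("choice01 ~", rhs)), data = dat, family = binomial,
             control = glmerControl(calc.derivs = FALSE))
sm <- summary(fit)
co <- sm$coefficients
ci <- tryCatch(confint(fit, parm = "beta_", method = "Wald"),
               error = function(e) matrix(NA, nrow(co), 2))
vc <- as.data.frame(VarCorr(fit))
out <- list(
  term = rownames(co), coef = unname(co[, 1]), se = unname(co[, 2]),
  z = unname(co[, 3]), p = unname(co[, 4]),
  ci_low = unname(ci[, 1]), ci_high = unname(ci[, 2]),
  llf = as.numeric(logLik(fit)),
  n_obs = nrow(dat),
  vc_group = vc$grp, vc_sd = vc$sdcor,
  singular = isSingular(fit),
  messages = unlist(fit@optinfo$conv$lme4$messages),
  converged = is.null(fit@optinfo$conv$lme4$code)
)
writeLines(toJSON(out, digits = 12, na = "null"), args[2])
"""


def mixed_logistic_nested(
    records: pd.DataFrame,
    terms: tuple[str, ...] = ("avoidance", "aversion", "partner_prev_c"),
    game: GameType = GameType.PD,
    timeout: float = 900.0,
) -> RegressionResult:
    """Nested random-intercept logistic model (participant in group in experiment).

    Fitted by Laplace-approximated maximum likelihood with lme4::glmer.
    Grouping factors are built as explicit nested labels
    (experiment, experiment:group, experiment:group:participant); a factor
    with fewer than two levels is dropped from the random-effects part.
    Non-convergence and singular variance components are reported on the
    result, never swallowed.
    """
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found on PATH; required for glmer fits")
    coded = code_predictors(records[records["valid"].astype(bool)], game)
    cols = ["choice01", *terms]
    coded = coded.dropna(subset=cols).copy()
    coded["f_exp"] = coded["experiment_id"].astype(str)
    coded["f_grp"] = coded["f_exp"] + ":" + coded["group_id"].astype(str)
    coded["f_part"] = coded["f_grp"] + ":" + coded["participant_id"].astype(str)
    re_terms = [
        f"(1|{f})"
        for f in ("f_exp", "f_grp", "f_part")
        if coded[f].nunique() >= 2
    ]
    if not re_terms:
        raise ValueError("no grouping factor with >= 2 levels; use logistic_glm")
    rhs = " + ".join([*terms, *re_terms])
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.csv"
        out_path = tmp / "fit.json"
        script_path = tmp / "fit.R"
        coded[cols + ["f_exp", "f_grp", "f_part"]].to_csv(data_path, index=False)
        script_path.write_text(_GLMER_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(data_path), str(out_path), rhs],
            capture_output=True,
            text=True,
            timeout=timeout,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(f"glmer fit failed:\n{proc.stderr[-2000:]}")
        res = json.loads(out_path.read_text())

    def _arr(key):
        v = res.get(key, [])
        return np.atleast_1d(np.array(v, dtype=float))

    terms_out = ["const" if t == "(Intercept)" else t for t in np.atleast_1d(res["term"])]
    params = pd.DataFrame(
        {
            "term": terms_out,
            "coef": _arr("coef"),
            "se": _arr("se"),
            "z": _arr("z"),
            "p": _arr("p"),
            "ci_low": _arr("ci_low"),
            "ci_high": _arr("ci_high"),
        }
    )
    vc_groups = [str(g) for g in np.atleast_1d(res.get("vc_group", []))]
    vc_sds = _arr("vc_sd")
    vcs = dict(zip(vc_groups, [float(s) for s in vc_sds]))
    msgs = tuple(str(m) for m in np.atleast_1d(res.get("messages", [])) if m)
    return RegressionResult(
        params=params,
        llf=float(np.atleast_1d(res["llf"])[0]),
        n_obs=int(np.atleast_1d(res["n_obs"])[0]),
        method="glmer_laplace",
        variance_components=vcs,
        converged=bool(np.atleast_1d(res.get("converged", [True]))[0]),
        singular=bool(np.atleast_1d(res.get("singular", [False]))[0]),
        messages=msgs,
    )


# --------------------------------------------------------------------------
# the contrast battery

def _cats(*labels: int) -> frozenset:
    return frozenset(Category(i) for i in labels)


#: The contrast set per game: (name, side A, side B).
CONTRAST_BATTERY: dict[GameType, list[tuple[str, frozenset, frozenset]]] = {
    GameType.PD: [
        ("pd_c24_vs_c135", _cats(2, 4), _cats(1, 3, 5)),
        ("pd_c1_vs_c5", _cats(1), _cats(5)),
    ],
    GameType.SH: [
        ("sh_c4_vs_c2", _cats(4), _cats(2)),
        ("sh_c4_vs_c135", _cats(4), _cats(1, 3, 5)),
        ("sh_c135_vs_c2", _cats(1, 3, 5), _cats(2)),
        ("c3_vs_c15", _cats(3), _cats(1, 5)),
    ],
    GameType.CH: [
        ("ch_c2_vs_c4", _cats(2), _cats(4)),
        ("ch_c2_vs_c135", _cats(2), _cats(1, 3, 5)),
        ("ch_c135_vs_c4", _cats(1, 3, 5), _cats(4)),
        ("c3_vs_c15", _cats(3), _cats(1, 5)),
    ],
}


def _side_rates(records: pd.DataFrame, side: frozenset) -> pd.Series:
    """Per-participant pooled cooperation rate over the side's categories."""
    labels = {c.name for c in side}
    sub = records[records["category"].isin(labels) & records["valid"].astype(bool)]
    return sub.groupby("participant_id")["choice"].apply(lambda s: (s == "C").mean())


def _side_counts(records: pd.DataFrame, side: frozenset) -> tuple[int, int]:
    labels = {c.name for c in side}
    sub = records[records["category"].isin(labels) & records["valid"].astype(bool)]
    return int((sub["choice"] == "C").sum()), int(len(sub))


def run_contrast_battery(
    records: pd.DataFrame,
    game: GameType,
    design: str,
    seed: int = 0,
    n_boot: int = 10_000,
) -> list[ContrastResult]:
    """Run the game's full contrast set on one experiment's records.

    ``design='iterated'`` uses paired t tests on per-participant rates;
    ``design='one_shot'`` uses chi-squared tests on pooled counts.  Only
    records of the given game enter the tests.
    """
    if design not in ("iterated", "one_shot"):
        raise ValueError("design must be 'iterated' or 'one_shot'")
    recs = records[records["game"] == game.value]
    if recs.empty:
        raise ValueError(f"no records for game {game.value}")
    results = []
    for name, side_a, side_b in CONTRAST_BATTERY[game]:
        if design == "iterated":
            ra = _side_rates(recs, side_a)
            rb = _side_rates(recs, side_b)
            joined = pd.concat([ra, rb], axis=1, keys=["a", "b"])
            results.append(paired_t(joined["a"], joined["b"], name=name))
        else:
            a_coop, a_n = _side_counts(recs, side_a)
            b_coop, b_n = _side_counts(recs, side_b)
            if a_n == 0 or b_n == 0:
                raise ValueError(f"empty category cell in contrast {name}")
            results.append(
                chi2_2x2(a_coop, a_n, b_coop, b_n, name=name, seed=seed, n_boot=n_boot)
            )
    return results


def results_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast export."""
    return pd.DataFrame(
        [
            {
                "contrast": r.name,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "effect_size": r.effect_size,
                "effect_size_name": r.effect_size_name,
                "es_ci_low": r.effect_size_ci[0],
                "es_ci_high": r.effect_size_ci[1],
                "n": r.n,
                "rate_a": r.rate_a,
                "rate_b": r.rate_b,
            }
            for r in results
        ]
    )
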