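"""Canonical trial I/O, exclusion preprocessing, and reproduction driver.

The canonical on-disk format is a long-format CSV, one row per decision,
with the columns in :data:`lossavoid.synthetic_data.TRIAL_COLUMNS`.
External datasets are mapped onto it by a declarative
:class:`SchemaAdapter` (column renames and value recodes, with gain/loss
categories re-derived from payoff columns when absent), so the analysis
code never sees a foreign schema.

``reproduce`` runs the full preprocessing + contrast battery over a
canonical trial table and lines the computed statistics up against the
published values stored in :data:`PRINTED_RESULTS`, one row per contrast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .games import GameType, PayoffMatrix, classify_category
from .choice_model import ChoiceModel, ValueFunction, default_choice_model, predict_profile, profile_frame
from .games import canonical_series
from .stats import (
    mixed_logistic_nested,
    results_frame,
    run_contrast_battery,
)
from .synthetic_data import TRIAL_COLUMNS, match_previous_rate

__all__ = [
    "RunConfig",
    "SchemaAdapter",
    "SchemaError",
    "PRINTED_RESULTS",
    "apply_exclusions",
    "load_trials",
    "write_trials",
    "reproduce",
    "simulate_predictions",
    "write_manifest",
]


# --------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-serializable)."""

    mode: str = "simulate_predictions"  # generate | analyze | reproduce | simulate_predictions
    games: tuple[str, ...] = ("PD", "SH", "CH")
    lambdas: tuple[float, ...] = (1.0, 2.0)
    bs: tuple[float, ...] = (0.0, 4.0)
    beta: float = 1.0
    p: float = 0.5
    design: tuple[int, int] = (12, 5)
    n_groups: int = 4
    n_per_category: int = 120
    seed: int | None = None
    input_path: str | None = None
    output_dir: str | None = None
    invalid_threshold: float = 0.10
    adapter_path: str | None = None

    def __post_init__(self) -> None:
        stochastic = self.mode in ("generate", "analyze", "reproduce")
        if stochastic and self.seed is None:
            raise ValueError(f"mode {self.mode!r} is stochastic: a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# --------------------------------------------------------------------------
# exclusions

def apply_exclusions(
    records: pd.DataFrame,
    design: str,
    invalid_threshold: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's participant exclusion rules.

    Iterated designs: a participant is excluded outright when *more than*
    ``invalid_threshold`` (10%) of their trials are invalid (exactly 10%
    is kept); the remaining invalid trials of kept participants are then
    dropped.  One-shot designs: a participant is excluded by a single
    comprehension-test error (``test_errors >= 1``).

    Returns ``(kept, log)`` where the log lists every exclusion with its
    reason and row count; kept rows + logged dropped rows = input rows.
    """
    if design not in ("iterated", "one_shot"):
        raise ValueError("design must be 'iterated' or 'one_shot'")
    log_rows = []
    if design == "iterated":
        invalid_frac = (
            records.assign(inv=~records["valid"].astype(bool))
            .groupby("participant_id")["inv"]
            .mean()
        )
        excluded = set(invalid_frac[invalid_frac > invalid_threshold].index)
        kept = records[~records["participant_id"].isin(excluded)]
        for pid in sorted(excluded):
            n = int((records["participant_id"] == pid).sum())
            log_rows.append(
                {
                    "participant_id": pid,
                    "reason": f"invalid trials > {invalid_threshold:.0%}",
                    "n_rows_dropped": n,
                }
            )
        bad = ~kept["valid"].astype(bool)
        for pid, n in kept.loc[bad].groupby("participant_id").size().items():
            log_rows.append(
                {
                    "participant_id": pid,
                    "reason": "invalid trials dropped (participant kept)",
                    "n_rows_dropped": int(n),
                }
            )
        kept = kept[kept["valid"].astype(bool)]
    else:
        errors = pd.to_numeric(records["test_errors"], errors="coerce").fillna(0)
        excluded = set(records.loc[errors >= 1, "participant_id"].unique())
        kept = records[~records["participant_id"].isin(excluded)]
        for pid in sorted(excluded):
            n = int((records["participant_id"] == pid).sum())
            log_rows.append(
                {
                    "participant_id": pid,
                    "reason": "comprehension-test error",
                    "n_rows_dropped": n,
                }
            )
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason", "n_rows_dropped"])
    if kept.empty:
        log = pd.concat(
            [log, pd.DataFrame([{"participant_id": "<all>", "reason": "no survivors", "n_rows_dropped": 0}])],
            ignore_index=True,
        )
    return kept.copy(), log


# --------------------------------------------------------------------------
# schema adaptation and I/O

class SchemaError(ValueError):
    """A source file cannot be mapped onto the canonical trial schema."""


@dataclass
class SchemaAdapter:
    """Declarative mapping from a source CSV onto the canonical schema.

    ``column_map`` renames source columns to canonical names;
    ``value_maps`` recodes values within a canonical column (e.g.
    ``{"choice": {"1": "C", "0": "D"}}``); ``payoff_columns`` names the
    four role columns used to derive categories when the source carries
    payoffs but no category labels.
    """

    column_map: dict = field(default_factory=dict)
    value_maps: dict = field(default_factory=dict)
    payoff_columns: tuple[str, str, str, str] = ("T", "R", "P", "S")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaAdapter":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            column_map=raw.get("column_map", {}),
            value_maps=raw.get("value_maps", {}),
            payoff_columns=tuple(raw.get("payoff_columns", ("T", "R", "P", "S"))),
        )


_REQUIRED = ("participant_id", "game", "choice")


def load_trials(path: str | Path, adapter: SchemaAdapter | None = None) -> pd.DataFrame:
    """Read a trial CSV, mapping it onto the canonical schema.

    Raises :class:`SchemaError` naming the offending column (and row, for
    value errors).  Categories are derived from payoff columns when absent
    and checked against the sign-pattern classifier.
    """
    df = pd.read_csv(path)
    adapter = adapter or SchemaAdapter()
    df = df.rename(columns=adapter.column_map)
    for col, mapping in adapter.value_maps.items():
        if col in df.columns:
            df[col] = df[col].astype(str).map(lambda v, m=mapping: m.get(v, v))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {missing}; available: {sorted(df.columns)}"
        )
    if "category" not in df.columns or df["category"].isna().all():
        pcols = list(adapter.payoff_columns)
        if not all(c in df.columns for c in pcols):
            raise SchemaError(
                "no category column and no payoff columns "
                f"{pcols} to derive it from"
            )
        cats = []
        for i, row in df[pcols].iterrows():
            m = PayoffMatrix(*[float(row[c]) for c in pcols])
            cats.append(classify_category(m).name)
        df["category"] = cats
    bad_choice = ~df["choice"].isin(["C", "D"]) & df["choice"].notna()
    if bad_choice.any():
        i = int(np.flatnonzero(bad_choice)[0])
        raise SchemaError(
            f"row {i}: column 'choice' has value {df['choice'].iloc[i]!r}, "
            "expected 'C' or 'D'"
        )
    if "expectation" in df.columns:
        exp = pd.to_numeric(df["expectation"], errors="coerce")
        out_of_range = exp.notna() & ((exp < 0) | (exp > 100))
        if out_of_range.any():
            i = int(np.flatnonzero(out_of_range)[0])
            raise SchemaError(f"row {i}: column 'expectation' outside [0, 100]")
    known_games = {g.value for g in GameType}
    bad_game = ~df["game"].isin(known_games)
    if bad_game.any():
        i = int(np.flatnonzero(bad_game)[0])
        raise SchemaError(
            f"row {i}: column 'game' has value {df['game'].iloc[i]!r}, "
            f"expected one of {sorted(known_games)}"
        )
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            df[col] = True if col == "valid" else (0 if col == "test_errors" else pd.NA)
    df["valid"] = df["valid"].fillna(True).astype(bool)
    return df[TRIAL_COLUMNS]


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical trial table (UTF-8 CSV, header row)."""
    records[TRIAL_COLUMNS].to_csv(path, index=False)


# --------------------------------------------------------------------------
# published reference values (for side-by-side reporting only; never used
# in computation)

#: Published statistics keyed by (experiment_id, game, contrast name).
#: t/chi2 is the test statistic, phi/d the printed effect size, rates in %.
PRINTED_RESULTS: dict[tuple[str, str, str], dict] = {
    ("exp1", "PD", "pd_c24_vs_c135"): dict(stat=2.1, df=23, p=0.045, effect=0.126, rate_a=47.2, rate_b=50.3),
    ("exp1", "PD", "pd_c1_vs_c5"): dict(stat=-2.6, df=23, p=0.016, effect=0.284, rate_a=47.3, rate_b=54.2),
    ("exp2", "PD", "pd_c24_vs_c135"): dict(stat=-0.4, df=45, p=0.687, effect=0.012, rate_a=46.0, rate_b=46.0),
    ("exp2", "PD", "pd_c1_vs_c5"): dict(stat=0.2, df=45, p=0.883, effect=0.007, rate_a=45.9, rate_b=45.7),
    ("exp3", "PD", "pd_c1_vs_c5"): dict(stat=0.9, df=44, p=0.362, effect=None, rate_a=50.0, rate_b=48.8),
    ("exp4", "PD", "pd_c24_vs_c135"): dict(stat=4.79, n=83, p=0.029, effect=0.24, rate_a=38.7, rate_b=63.5),
    ("exp5", "PD", "pd_c24_vs_c135"): dict(stat=8.45, n=447, p=0.004, effect=0.14, rate_a=36, rate_b=49),
    ("exp5", "PD", "pd_c1_vs_c5"): dict(stat=1.00, n=175, p=0.328, effect=0.08, rate_a=51, rate_b=43),
    ("exp6", "PD", "pd_c24_vs_c135"): dict(stat=42.25, n=603, p=0.001, effect=0.27, rate_a=39, rate_b=66),
    ("exp6", "PD", "pd_c1_vs_c5"): dict(stat=4.70, n=231, p=0.030, effect=0.14, rate_a=68, rate_b=54),
    ("exp6", "SH", "sh_c4_vs_c2"): dict(stat=30.12, n=255, p=0.001, effect=0.34, rate_a=99, rate_b=77),
    ("exp6", "SH", "sh_c4_vs_c135"): dict(stat=17.75, n=474, p=0.001, effect=0.19, rate_a=99, rate_b=86),
    ("exp6", "SH", "sh_c135_vs_c2"): dict(stat=5.33, n=477, p=0.021, effect=0.11, rate_a=86, rate_b=77),
    ("exp6", "SH", "c3_vs_c15"): dict(stat=6.38, n=348, p=0.012, effect=0.14, rate_a=92, rate_b=82),
    ("exp7", "PD", "pd_c24_vs_c135"): dict(stat=15.03, n=603, p=0.001, effect=0.16, rate_a=47, rate_b=63),
    ("exp7", "PD", "pd_c1_vs_c5"): dict(stat=4.73, n=239, p=0.030, effect=0.14, rate_a=66, rate_b=52),
    ("exp7", "SH", "sh_c4_vs_c2"): dict(stat=6.44, n=249, p=0.011, effect=0.16, rate_a=87, rate_b=74),
    ("exp7", "SH", "sh_c4_vs_c135"): dict(stat=1.63, n=483, p=0.202, effect=0.06, rate_a=87, rate_b=82),
    ("exp7", "SH", "sh_c135_vs_c2"): dict(stat=3.36, n=474, p=0.067, effect=0.08, rate_a=82, rate_b=74),
    ("exp7", "SH", "c3_vs_c15"): dict(stat=8.34, n=354, p=0.004, effect=0.15, rate_a=90, rate_b=78),
    ("exp7", "CH", "ch_c2_vs_c4"): dict(stat=51.33, n=249, p=0.001, effect=0.45, rate_a=91, rate_b=49),
    ("exp7", "CH", "ch_c2_vs_c135"): dict(stat=12.23, n=474, p=0.001, effect=0.16, rate_a=91, rate_b=76),
    ("exp7", "CH", "ch_c135_vs_c4"): dict(stat=32.44, n=483, p=0.001, effect=0.26, rate_a=76, rate_b=49),
    ("exp7", "CH", "c3_vs_c15"): dict(stat=1.50, n=354, p=0.220, effect=0.07, rate_a=80, rate_b=74),
}

#: Pooled iterated-experiment regularities (Experiments 1-3).
PRINTED_POOLED = dict(
    match_previous_rate=0.79,
    avoidance_beta=-0.151,
    aversion_beta=0.038,
    partner_prev_beta=2.495,
)

_ITERATED_EXPERIMENTS = ("exp1", "exp2", "exp3")


def _infer_design(records: pd.DataFrame) -> str:
    return "iterated" if records["group_id"].notna().any() else "one_shot"


def reproduce(
    records: pd.DataFrame,
    seed: int,
    invalid_threshold: float = 0.10,
    n_boot: int = 10_000,
    fit_mixed: bool = True,
) -> dict:
    """Run exclusions + contrast battery per experiment; compare to print.

    Returns a dict with ``contrasts`` (side-by-side table of computed vs.
    published statistics), ``pooled`` (Tit-for-Tat match share and, when
    the iterated experiments are present and ``fit_mixed`` is set, the
    nested mixed-logistic coefficients), ``exclusions`` and ``notices``
    (experiments referenced in the published tables but absent here).
    """
    rows = []
    exclusion_logs = []
    notices = []
    present = set(records["experiment_id"].dropna().unique())
    for exp_id in sorted(present):
        recs = records[records["experiment_id"] == exp_id]
        design = _infer_design(recs)
        kept, log = apply_exclusions(recs, design, invalid_threshold)
        log = log.assign(experiment_id=exp_id)
        exclusion_logs.append(log)
        for game_label in sorted(kept["game"].dropna().unique()):
            game = GameType(game_label)
            results = run_contrast_battery(kept, game, design, seed=seed, n_boot=n_boot)
            for r in results:
                printed = PRINTED_RESULTS.get((exp_id, game_label, r.name), {})
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "game": game_label,
                        "contrast": r.name,
                        "design": design,
                        "computed_statistic": r.statistic,
                        "computed_p": r.p_value,
                        "computed_effect": r.effect_size,
                        "computed_rate_a": 100 * r.rate_a,
                        "computed_rate_b": 100 * r.rate_b,
                        "printed_statistic": printed.get("stat"),
                        "printed_effect": printed.get("effect"),
                        "printed_rate_a": printed.get("rate_a"),
                        "printed_rate_b": printed.get("rate_b"),
                    }
                )
    referenced = {k[0] for k in PRINTED_RESULTS}
    for exp_id in sorted(referenced - present):
        notices.append(f"experiment {exp_id} not in data; its contrasts were skipped")

    pooled: dict = {}
    iterated = records[records["experiment_id"].isin(_ITERATED_EXPERIMENTS)]
    if not iterated.empty:
        kept, _ = apply_exclusions(iterated, "iterated", invalid_threshold)
        if kept["partner_prev"].notna().any():
            pooled["match_previous_rate"] = match_previous_rate(kept)
            pooled["printed_match_previous_rate"] = PRINTED_POOLED["match_previous_rate"]
        if fit_mixed:
            fit = mixed_logistic_nested(
                kept, terms=("avoidance", "aversion", "partner_prev_c")
            )
            pooled["mixed_model"] = fit
    exclusions = (
        pd.concat(exclusion_logs, ignore_index=True)
        if exclusion_logs
        else pd.DataFrame()
    )
    return {
        "contrasts": pd.DataFrame(rows),
        "pooled": pooled,
        "exclusions": exclusions,
        "notices": notices,
    }


# --------------------------------------------------------------------------
# prediction export

def simulate_predictions(
    games: tuple[str, ...] = ("PD", "SH", "CH"),
    lambdas: tuple[float, ...] = (1.0, 2.0),
    bs: tuple[float, ...] = (0.0, 4.0),
    beta: float = 1.0,
    p: float = 0.5,
) -> pd.DataFrame:
    """Category prediction profiles for every game x (lambda, b) combination."""
    cm = default_choice_model(p=p, beta=beta)
    profiles = []
    for g in games:
        game = GameType(g)
        series = canonical_series(game)
        for lam in lambdas:
            for b in bs:
                profiles.append(predict_profile(series, ValueFunction(lam, b), cm))
    return profile_frame(profiles)


def write_manifest(out_dir: str | Path, config: RunConfig | None, seed: int | None) -> Path:
    """Record run provenance (config, seed, package version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "lossavoid",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
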