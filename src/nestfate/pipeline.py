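"""End-to-end analysis runs: config, staging, manifest, reproducibility.

A run chains the full analysis — read or simulate the nest data, screen
collinear covariates, select among candidate survival models, bootstrap the
cumulative incubation survival per region x method group, and test the
fate composition — writing CSV/JSON outputs plus a manifest of checksums so
identical config + seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import fates as fates_mod
from . import records as rec
from . import simulate as sim
from .dsr import CATEGORICAL_TERMS, INTERACTION_TERMS, DSRModel, ModelSpec
from .period import bootstrap_period_survival
from .selection import screen_collinearity, select

log = logging.getLogger("nestfate")

NUMERIC_TERMS = (
    "rain", "irradiance", "soil_temp_mean", "wind_mean",
    "soil_temp_mean_lag1", "wind_mean_lag1", "day_of_season",
)

#: Reduced global model used by the bundled demo scenario: the superset of
#: terms the weather-driven truth actually uses, which keeps the candidate
#: space small enough to fit in minutes.
DEMO_GLOBAL = (
    "region", "method", "wind_mean", "wind_mean_lag1",
    "region:method", "wind_mean:wind_mean_lag1",
)


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    seed: int = 0
    out_dir: str = "nestfate-run"
    global_terms: tuple[str, ...] = DEMO_GLOBAL
    scenario: dict | None = None          # simulation scenario, or None
    nests_path: str | None = None         # CSV inputs when not simulating
    covariates_path: str | None = None
    season_origin: str | None = None
    collinearity_threshold: float = 0.65
    ci_level: float = 0.95
    balance_alpha: float = 0.05
    min_group: int = 5
    incubation_days: int = 27
    n_reps: int = 1000

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0 < self.balance_alpha < 1:
            raise ValueError("balance_alpha must lie in (0, 1)")
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity_threshold must lie in (0, 1]")
        if self.min_group < 0 or self.incubation_days < 1 or self.n_reps < 1:
            raise ValueError("min_group, incubation_days and n_reps must be positive")
        ModelSpec(tuple(self.global_terms))  # hierarchy check
        if self.scenario is None and (self.nests_path is None or self.covariates_path is None):
            raise ValueError("config needs either a simulation scenario or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = raw.pop("thresholds", {})
        inputs = raw.pop("inputs", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "nestfate-run")),
            global_terms=tuple(raw.get("global_terms", DEMO_GLOBAL)),
            scenario=raw.get("scenario"),
            nests_path=inputs.get("nests"),
            covariates_path=inputs.get("covariates"),
            season_origin=inputs.get("season_origin"),
            collinearity_threshold=float(thresholds.get("collinearity", 0.65)),
            ci_level=float(thresholds.get("ci_level", 0.95)),
            balance_alpha=float(thresholds.get("balance_alpha", 0.05)),
            min_group=int(thresholds.get("min_group", 5)),
            incubation_days=int(thresholds.get("incubation", 27)),
            n_reps=int(thresholds.get("n_reps", 1000)),
        )


def demo_config(seed: int = 0, out_dir: str = "nestfate-demo", n_reps: int = 1000) -> RunConfig:
    """Bundled demo scenario: ~200 simulated nests over a 120-day season."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        n_reps=n_reps,
        scenario={
            "n_days": 120,
            "n_nests": {
                "Alsace/camera": 30,
                "Alsace/visits": 25,
                "HautsDeFrance/camera": 85,
                "HautsDeFrance/visits": 60,
            },
        },
    )


def _scenario_nests(scenario: Mapping) -> dict:
    out = {}
    for key, n in scenario["n_nests"].items():
        if "/" in str(key):
            region, method = str(key).split("/", 1)
            out[(region, method)] = int(n)
        else:
            out[str(key)] = int(n)
    return out


def simulate_scenario(config: RunConfig):
    """Generate (records, covariates, truth, weather) for a scenario config."""
    scenario = config.scenario or {}
    n_days = int(scenario.get("n_days", 120))
    weather = {
        region: sim.simulate_weather(params, region, n_days, seed=config.seed)
        for region, params in sim.DEFAULT_WEATHER.items()
    }
    truth_model = sim.TrueModel()
    records, covariates, truth = sim.simulate_nests(
        truth_model, weather, _scenario_nests(scenario), seed=config.seed
    )
    return records, covariates, truth, weather


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _prune_global(terms, retained_numeric) -> tuple[str, ...]:
    """Drop screened-out numeric terms and orphaned interactions."""
    dropped = {t for t in terms if t in NUMERIC_TERMS and t not in retained_numeric}
    kept = []
    for t in terms:
        if t in dropped:
            continue
        if t in INTERACTION_TERMS:
            a, b = INTERACTION_TERMS[t]
            if a in dropped or b in dropped:
                continue
        kept.append(t)
    return tuple(kept)


def _group_weather(day_table: pd.DataFrame, region: str) -> pd.DataFrame:
    """Unique observed days of a region's seasons, in (year, day) order."""
    rows = day_table[day_table["region"] == region]
    return (
        rows.drop_duplicates(subset=["year", "day"])
        .sort_values(["year", "day"], kind="mergesort")
        .reset_index(drop=True)
    )


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (selection table, bootstrap
    results, fate tests, manifest).  Any stage failure aborts the run,
    removes partial outputs, and re-raises tagged with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: list[tuple[str, float]] = []
    stage = "setup"

    def _write_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def _write_text(text: str, name: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    try:
        t0 = time.perf_counter()
        stage = "data"
        if config.scenario is not None:
            records, covariates, truth, _ = simulate_scenario(config)
            _write_csv(rec.records_to_frame(records), "nests.csv")
            _write_csv(covariates, "covariates.csv")
            _write_csv(truth, "truth.csv")
        else:
            records = rec.read_nest_table(config.nests_path, config.season_origin)
            covariates = rec.read_covariate_table(config.covariates_path)
        nests_df = rec.records_to_frame([r for r in records if r.included])
        day_table = rec.join_covariates(records, covariates)
        timings.append((stage, time.perf_counter() - t0))

        t0 = time.perf_counter()
        stage = "collinearity"
        numeric = [t for t in config.global_terms if t in NUMERIC_TERMS]
        if len(numeric) >= 2:
            retained, colin_report = screen_collinearity(
                day_table, numeric, threshold=config.collinearity_threshold
            )
            _write_csv(colin_report, "collinearity.csv")
        else:
            retained = numeric
        global_terms = _prune_global(config.global_terms, set(retained))
        timings.append((stage, time.perf_counter() - t0))

        t0 = time.perf_counter()
        stage = "model-selection"
        sel = select(
            ModelSpec(global_terms),
            nests_df,
            day_table,
            alpha=config.balance_alpha,
            min_group=config.min_group,
            ci_level=config.ci_level,
        )
        _write_csv(sel.table, "selection.csv")
        best = sel.best.results
        _write_text(best.to_json(), "best_model.json")
        timings.append((stage, time.perf_counter() - t0))

        t0 = time.perf_counter()
        stage = "period-survival"
        boot_results = []
        groups = (
            nests_df.groupby(["region", "method"], observed=True).size().index.tolist()
        )
        cat_in_spec = [t for t in best.spec.terms if t in CATEGORICAL_TERMS]
        for g_idx, (region, method) in enumerate(sorted(groups)):
            weather_g = _group_weather(day_table, region)
            if len(weather_g) < config.incubation_days:
                log.warning("group %s/%s: season shorter than the incubation window",
                            region, method)
                continue
            group = {"region": region, "method": method}
            grp_rows = day_table[
                (day_table["region"] == region) & (day_table["method"] == method)
            ]
            for term in cat_in_spec:
                if term not in ("region", "method") and len(grp_rows):
                    group[term] = grp_rows[term].mode().iloc[0]
            boot_results.append(
                bootstrap_period_survival(
                    best,
                    weather_g,
                    group,
                    n_reps=config.n_reps,
                    seed=int(np.random.default_rng([config.seed, 7000 + g_idx]).integers(2**31)),
                    length=config.incubation_days,
                )
            )
        _write_csv(pd.DataFrame([b.summary_row() for b in boot_results]),
                   "period_survival.csv")
        timings.append((stage, time.perf_counter() - t0))

        t0 = time.perf_counter()
        stage = "fate-tests"
        fate_out = {}
        for factor in ("region", "method"):
            table = fates_mod.fate_table(nests_df, factor)
            overall = fates_mod.fisher_exact(table.counts.to_numpy())
            rowwise = fates_mod.rowwise_fate_tests(table)
            _write_csv(rowwise, f"fates_{factor}.csv")
            fate_out[factor] = {"table": table, "overall_p": overall.pvalue,
                                "rowwise": rowwise}
        timings.append((stage, time.perf_counter() - t0))

        stage = "report"
        summary = _summary_text(config, sel, best, boot_results, fate_out, timings)
        _write_text(summary, "summary.txt")
        manifest = {
            "seed": config.seed,
            "config": {k: v for k, v in vars(config).items()},
            "outputs": {p.name: _sha256(p) for p in written},
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1, default=str))
        written.append(mp)
        return {
            "selection": sel,
            "best": best,
            "period_survival": boot_results,
            "fates": fate_out,
            "manifest": manifest,
            "out_dir": str(out),
        }
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err


def _summary_text(config, sel, best, boots, fate_out, timings) -> str:
    lines = [
        "nestfate run summary",
        "====================",
        f"seed: {config.seed}",
        "",
        best.summary(config.ci_level),
        "",
        "Cumulative incubation survival (corrected bootstrap):",
    ]
    for b in boots:
        g = ", ".join(f"{k}={v}" for k, v in b.group.items())
        lines.append(
            f"  {g}: {b.estimate:.3f} (SE {b.se:.3f}, "
            f"95% CI {b.ci_lower:.3f}-{b.ci_upper:.3f})"
        )
    lines.append("")
    for factor, res in fate_out.items():
        lines.append(f"Fate composition by {factor}: Fisher exact p = {res['overall_p']:.3g}")
    lines.append("")
    lines.append("Stage timings (s): " + ", ".join(f"{s}={t:.1f}" for s, t in timings))
    return "\n".join(lines) + "\n"


def reproduce_study(
    data_dir,
    global_terms: tuple[str, ...] = DEMO_GLOBAL,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Re-run the headline analysis on a deposited data directory.

    Expects ``nests.csv`` and ``covariates.csv`` in the canonical schema
    under ``data_dir``.  Returns the null-model fit, the selection table
    over ``global_terms``, median predicted DSR per region x method group,
    and the bootstrap incubation survival per group.
    """
    data_dir = Path(data_dir)
    records = rec.read_nest_table(data_dir / "nests.csv")
    covariates = rec.read_covariate_table(data_dir / "covariates.csv")
    nests_df = rec.records_to_frame([r for r in records if r.included])
    day_table = rec.join_covariates(records, covariates)

    null = DSRModel(day_table, ModelSpec(())).fit()
    sel = select(ModelSpec(tuple(global_terms)), nests_df, day_table)
    best = sel.best.results

    median_dsr = {}
    boots = {}
    for g_idx, ((region, method), grp) in enumerate(
        sorted(day_table.groupby(["region", "method"], observed=True))
    ):
        median_dsr[(region, method)] = float(np.median(best.predict(grp)))
        weather_g = _group_weather(day_table, region)
        boots[(region, method)] = bootstrap_period_survival(
            best, weather_g, {"region": region, "method": method},
            n_reps=n_reps, seed=int(np.random.default_rng([seed, g_idx]).integers(2**31)),
        )
    return {
        "null_loglik": null.llf,
        "null_aicc": null.aicc,
        "selection": sel,
        "best": best,
        "median_dsr": median_dsr,
        "bootstrap": boots,
    }
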