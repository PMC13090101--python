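"""Synthetic weather and nest-observation generator.

Emulates the data-generating process the survival analysis assumes: two
regions with contrasting weather (an AR(1) daily series per variable with a
linear seasonal trend), a logit-linear true daily survival rate driven by
those covariates and by grouping factors, and a field observation process —
nest initiation, discovery with a lag, and a roughly weekly visit schedule —
that censors each nest's history into the (i, j, k) triple: day found, last
day known active, day fate confirmed.

The generator returns the latent truth (true failure day, true window
survival) alongside the censored records, so estimator tests can compare
recovered quantities against what actually happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dsr import INTERACTION_TERMS, ModelSpec, build_design
from .records import FAILURE_FATES, NestRecord

__all__ = [
    "WeatherParams",
    "TrueModel",
    "DEFAULT_WEATHER",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_FATE_MIXTURE",
    "simulate_weather",
    "simulate_nests",
]


@dataclass(frozen=True)
class WeatherParams:
    """Daily-weather model for one region.

    Gaussian AR(1) series (stationary marginal SD as given) for soil
    temperature, wind speed and irradiance around a linear seasonal trend;
    rainfall is Bernoulli wet days with exponential wet-day amounts.  Wind
    and irradiance are floored at 0.
    """

    soil_temp_mean: float
    soil_temp_sd: float
    wind_mean: float
    wind_sd: float
    irradiance_mean: float
    irradiance_sd: float
    rain_wet_prob: float
    rain_wet_mean: float
    ar1_phi: float = 0.5
    soil_temp_slope: float = 0.0  # units per day around mid-season
    wind_slope: float = 0.0
    irradiance_slope: float = 0.0

    def __post_init__(self):
        for name in ("soil_temp_sd", "wind_sd", "irradiance_sd", "rain_wet_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rain_wet_prob <= 1.0:
            raise ValueError("rain_wet_prob must lie in [0, 1]")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")


# Regional defaults: season-mean soil temperature, wind speed, irradiance
# and rainfall match the study regions' contrasts (Alsace warmer and
# calmer, Hauts-de-France windier); 69% of days are wet, so wet-day means
# are overall means / 0.69.  Daily SDs and seasonal trends are generator
# choices documented in the methods note.
DEFAULT_WEATHER: Mapping[str, WeatherParams] = {
    "Alsace": WeatherParams(
        soil_temp_mean=17.2, soil_temp_sd=4.0, soil_temp_slope=0.08,
        wind_mean=0.3, wind_sd=0.15,
        irradiance_mean=217.0, irradiance_sd=60.0, irradiance_slope=1.0,
        rain_wet_prob=0.69, rain_wet_mean=2.6 / 0.69,
    ),
    "HautsDeFrance": WeatherParams(
        soil_temp_mean=15.5, soil_temp_sd=4.0, soil_temp_slope=0.08,
        wind_mean=0.6, wind_sd=0.20,
        irradiance_mean=223.0, irradiance_sd=60.0, irradiance_slope=1.0,
        rain_wet_prob=0.69, rain_wet_mean=2.2 / 0.69,
    ),
}

#: True logit-scale coefficients: the fitted top model of the study system
#: (region x method + wind x lagged wind).
DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "intercept": -1.013,
    "region": 1.700,
    "method": 1.931,
    "wind_mean": 1.905,
    "wind_mean_lag1": 7.732,
    "region:method": -1.708,
    "wind_mean:wind_mean_lag1": -5.741,
}

#: Failure-cause mixture per region, conditional on failure
#: (agriculture, abandoned, flooded, depredated, unknown_failure).
DEFAULT_FATE_MIXTURE: Mapping[str, Mapping[str, float]] = {
    "Alsace": {"agriculture": 11 / 24, "abandoned": 5 / 24, "flooded": 1 / 24,
               "depredated": 6 / 24, "unknown_failure": 1 / 24},
    "HautsDeFrance": {"agriculture": 5 / 26, "abandoned": 7 / 26, "flooded": 1 / 26,
                      "depredated": 5 / 26, "unknown_failure": 8 / 26},
}

#: Days between visits: median 7, IQR 6-7.
DEFAULT_VISIT_PMF: Mapping[int, float] = {5: 0.05, 6: 0.30, 7: 0.50, 8: 0.15}


@dataclass(frozen=True)
class TrueModel:
    """Ground truth for the generator.

    ``coefficients`` maps linear-predictor terms (a hierarchical subset of
    the global model, plus ``"intercept"``) to logit-scale values.  Fate
    causes are labels drawn from a region-specific mixture conditional on
    failure; they do not feed back into the (single) hazard.
    """

    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    fate_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {r: dict(m) for r, m in DEFAULT_FATE_MIXTURE.items()}
    )
    visit_interval_pmf: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VISIT_PMF)
    )
    discovery_lag_max: int = 6  # uniform on 0..max (weekly search cadence)
    camera_prob: Mapping[str, float] = field(
        default_factory=lambda: {"Alsace": 20 / 37, "HautsDeFrance": 72 / 108}
    )
    incubation_days: int = 27
    crop_prob: float = 0.9
    clutch_eq4_prob: float = 0.7
    year_probs: Mapping[int, float] = field(
        default_factory=lambda: {2021: 40 / 145, 2022: 105 / 145}
    )

    def __post_init__(self):
        for region, mix in self.fate_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fate mixture for {region} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError("fate mixture probabilities must be >= 0")
        if any(k < 1 for k in self.visit_interval_pmf):
            raise ValueError("visit intervals must be >= 1 day")
        if abs(sum(self.visit_interval_pmf.values()) - 1.0) > 1e-9:
            raise ValueError("visit interval pmf must sum to 1")

    @property
    def spec(self) -> ModelSpec:
        terms = [t for t in self.coefficients if t != "intercept"]
        # order: mains first, then interactions (hierarchy-safe)
        mains = [t for t in terms if t not in INTERACTION_TERMS]
        inters = [t for t in terms if t in INTERACTION_TERMS]
        return ModelSpec(tuple(mains + inters))

    def beta(self) -> np.ndarray:
        spec = self.spec
        return np.array(
            [self.coefficients.get("intercept", 0.0)]
            + [self.coefficients[t] for t in spec.terms]
        )


def simulate_weather(
    params: WeatherParams, region: str, n_days: int, seed: int, start_day: int = 1
) -> pd.DataFrame:
    """One daily weather series for a region (a covariate-series template).

    Returns one row per day in [start_day, start_day + n_days) with the
    unlagged variables, their one-day lags (derived from the series itself,
    via one burn-in day before the window), rainfall and ``day_of_season``.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _region_code(region)]))
    m = n_days + 1  # one lead-in day so lags exist for the first emitted day
    days = np.arange(start_day - 1, start_day + n_days)
    mid = days.mean()

    def ar1(sd: float) -> np.ndarray:
        phi = params.ar1_phi
        z = np.empty(m)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(m - 1)
        for t in range(1, m):
            z[t] = phi * z[t - 1] + np.sqrt(1.0 - phi * phi) * eps[t - 1]
        return sd * z

    soil = params.soil_temp_mean + params.soil_temp_slope * (days - mid) + ar1(params.soil_temp_sd)
    wind = params.wind_mean + params.wind_slope * (days - mid) + ar1(params.wind_sd)
    irr = params.irradiance_mean + params.irradiance_slope * (days - mid) + ar1(params.irradiance_sd)
    wind = np.maximum(wind, 0.0)
    irr = np.maximum(irr, 0.0)
    wet = rng.random(m) < params.rain_wet_prob
    rain = np.where(wet, rng.exponential(params.rain_wet_mean or 1.0, m), 0.0)
    if params.rain_wet_mean == 0:
        rain = np.zeros(m)

    df = pd.DataFrame(
        {
            "day": days[1:],
            "soil_temp_mean": soil[1:],
            "wind_mean": wind[1:],
            "soil_temp_mean_lag1": soil[:-1],
            "wind_mean_lag1": wind[:-1],
            "rain": rain[1:],
            "irradiance": irr[1:],
            "day_of_season": days[1:].astype(float),
            "region": region,
        }
    )
    return df


def _region_code(region: str) -> int:
    return {"Alsace": 0, "HautsDeFrance": 1}.get(region, 2)


def _group_plan(
    n_nests: Mapping, camera_prob: Mapping[str, float]
) -> list[tuple[str, str | None, int]]:
    """Normalise the requested counts to (region, method-or-None, n)."""
    plan = []
    for key, n in n_nests.items():
        if isinstance(key, tuple):
            region, method = key
            plan.append((region, method, int(n)))
        else:
            plan.append((key, None, int(n)))
    return plan


def _true_dsr(model: TrueModel, day_rows: pd.DataFrame) -> np.ndarray:
    X, _ = build_design(day_rows, model.spec, ref_year=2021)
    eta = X @ model.beta()
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_nests(
    true_model: TrueModel,
    weather: Mapping[str, pd.DataFrame],
    n_nests: Mapping,
    seed: int,
    max_attempts: int = 1000,
) -> tuple[list[NestRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate censored nest histories from a known truth.

    ``weather`` maps region to a daily series (from
    :func:`simulate_weather`); ``n_nests`` maps ``(region, method)`` — or
    just ``region``, in which case the method is drawn per nest from the
    camera-assignment probability — to the number of *observed* nests to
    emit.  Nests that fail before discovery are redrawn (field crews never
    see them), as are initiation days whose incubation window would run
    past the weather series; both are counted in the returned truth table's
    attributes.

    Returns ``(records, covariates, truth)``: validated records, the
    day-level covariate table covering each nest's [i, k) span, and the
    latent truth (true failure day, true window survival) per emitted nest.
    """
    records: list[NestRecord] = []
    cov_spans: list[tuple[str, str, int, int]] = []  # nest_id, region, i, k
    truth_rows = []
    intervals = np.array(sorted(true_model.visit_interval_pmf))
    interval_p = np.array([true_model.visit_interval_pmf[k] for k in intervals])
    fate_names = list(FAILURE_FATES)
    inc = true_model.incubation_days
    # daily true-DSR series per (region, static-factor combination), computed
    # once on the full season so the per-nest loop only slices arrays
    dsr_cache: dict[tuple, np.ndarray] = {}

    def season_dsr(region: str, wx_frame: pd.DataFrame, static: dict) -> np.ndarray:
        key = (region, *sorted(static.items()))
        if key not in dsr_cache:
            rows = wx_frame.copy()
            for col, val in static.items():
                rows[col] = val
            dsr_cache[key] = _true_dsr(true_model, rows)
        return dsr_cache[key]

    for g_idx, (region, method_fixed, count) in enumerate(
        _group_plan(n_nests, true_model.camera_prob)
    ):
        wx_frame = weather[region].sort_values("day").reset_index(drop=True)
        days = wx_frame["day"].to_numpy()
        n_days = int(days.max())
        first_day = int(days.min())
        # leave room for incubation plus the post-failure confirmation visit
        init_lo = first_day + 1
        init_hi = n_days - inc - int(intervals.max())
        if init_hi < init_lo:
            raise ValueError(
                f"weather series for {region} too short for a {inc}-day incubation"
            )
        for nest_idx in range(count):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), g_idx, nest_idx])
            )
            method = method_fixed or (
                "camera" if rng.random() < true_model.camera_prob[region] else "visits"
            )
            year = int(
                rng.choice(list(true_model.year_probs), p=list(true_model.year_probs.values()))
            )
            habitat = "crop" if rng.random() < true_model.crop_prob else "other"
            clutch = "eq4" if rng.random() < true_model.clutch_eq4_prob else "lt4"
            static = {"region": region, "method": method, "year": year,
                      "habitat": habitat, "clutch_class": clutch}
            s_season = season_dsr(region, wx_frame, static)

            for attempt in range(max_attempts):
                t0 = int(rng.integers(init_lo, init_hi + 1))
                idx0 = t0 - first_day
                s = s_season[idx0:idx0 + inc]
                died = rng.random(inc) > s
                # first day the nest is no longer active: it survived days
                # t0 .. fail_day-2 and died during day fail_day-1
                fail_day = int(t0 + np.argmax(died)) + 1 if died.any() else None
                true_s27 = float(np.exp(np.log(s).sum()))

                lag = int(rng.integers(0, true_model.discovery_lag_max + 1))
                d0 = t0 + lag
                if fail_day is not None and fail_day <= d0:
                    continue  # failed before discovery: never observed
                if fail_day is None and d0 > t0 + inc - 1:
                    continue  # hatched before discovery
                i = d0
                if fail_day is None:
                    j = k = t0 + inc  # hatch completion is dateable to the day
                    fate = "hatched"
                else:
                    visits = [i]
                    while visits[-1] < fail_day:
                        visits.append(visits[-1] + int(rng.choice(intervals, p=interval_p)))
                    j = max(v for v in visits if v < fail_day)
                    k = min(v for v in visits if v >= fail_day)
                    mix = true_model.fate_mixture[region]
                    fate = str(rng.choice(fate_names, p=[mix[f] for f in fate_names]))
                break
            else:
                raise RuntimeError(
                    f"could not generate an observed nest in {region} after "
                    f"{max_attempts} attempts"
                )

            nest_id = f"{region[:2]}-{g_idx}-{nest_idx:04d}"
            records.append(
                NestRecord(
                    nest_id=nest_id, region=region, year=year, method=method,
                    habitat=habitat, clutch_class=clutch, fate=fate,
                    day_found=i, day_last_active=j, day_fate_confirmed=k,
                )
            )
            cov_spans.append((nest_id, region, i, k))
            truth_rows.append(
                {
                    "nest_id": nest_id, "region": region, "method": method,
                    "year": year, "initiation_day": t0,
                    "true_fail_day": np.nan if fail_day is None else fail_day,
                    "fate": fate, "true_window_survival": true_s27,
                    "day_found": i, "day_last_active": j, "day_fate_confirmed": k,
                    "attempts": attempt + 1,
                }
            )

    cov_cols = ["day", "soil_temp_mean", "wind_mean", "soil_temp_mean_lag1",
                "wind_mean_lag1", "rain", "irradiance", "day_of_season"]
    if cov_spans:
        indexed = {
            region: weather[region].sort_values("day").set_index("day")[cov_cols[1:]]
            for region in {r for _, r, _, _ in cov_spans}
        }
        parts = []
        for nest_id, region, i, k in cov_spans:
            block = indexed[region].loc[i:k - 1].reset_index()
            block.insert(0, "nest_id", nest_id)
            parts.append(block)
        covariates = pd.concat(parts, ignore_index=True)[["nest_id"] + cov_cols]
    else:
        covariates = pd.DataFrame(columns=["nest_id"] + cov_cols)
    truth = pd.DataFrame(truth_rows)
    return records, covariates, truth
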