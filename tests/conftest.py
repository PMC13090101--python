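from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nestfate.dsr import DSRModel, DSRResults, ModelSpec
from nestfate.records import NestRecord, join_covariates, records_to_frame
from nestfate.simulate import (
    DEFAULT_WEATHER,
    TrueModel,
    simulate_nests,
    simulate_weather,
)


def constant_covariates(
    records, soil: float = 15.0, wind: float = 0.5, rain: float = 1.0, irr: float = 200.0
) -> pd.DataFrame:
    """Covariate rows covering each record's [i, k) span with constant weather."""
    rows = []
    for r in records:
        for day in range(r.day_found, r.day_fate_confirmed):
            rows.append(
                {
                    "nest_id": r.nest_id,
                    "day": day,
                    "soil_temp_mean": soil,
                    "wind_mean": wind,
                    "soil_temp_mean_lag1": soil,
                    "wind_mean_lag1": wind,
                    "rain": rain,
                    "irradiance": irr,
                    "day_of_season": float(day),
                }
            )
    return pd.DataFrame(rows)


def make_nest(
    nest_id="n1", region="Alsace", year=2022, method="visits", habitat="crop",
    clutch_class="eq4", fate="hatched", i=1, j=10, k=10,
) -> NestRecord:
    return NestRecord(
        nest_id=nest_id, region=region, year=year, method=method, habitat=habitat,
        clutch_class=clutch_class, fate=fate, day_found=i, day_last_active=j,
        day_fate_confirmed=k,
    )


def results_with(params: dict, bse: dict | None = None) -> DSRResults:
    """A DSRResults carrying prescribed coefficients (for prediction/CI tests).

    Backed by a real fitted model on a minimal dataset so the object is
    fully formed; the coefficient vector and covariance are then replaced.
    """
    terms = tuple(t for t in params if t != "intercept")
    spec = ModelSpec(terms)
    recs = [
        make_nest("a", region="Alsace", method="visits", fate="hatched", i=1, j=5, k=5),
        make_nest("b", region="HautsDeFrance", method="camera", fate="depredated",
                  i=1, j=4, k=6),
        make_nest("c", region="Alsace", method="camera", fate="hatched", i=1, j=6, k=6),
        make_nest("d", region="HautsDeFrance", method="visits", fate="abandoned",
                  i=2, j=5, k=7, year=2021),
    ]
    cov = constant_covariates(recs)
    # perturb weather so numeric terms are not collinear with the intercept
    rng = np.random.default_rng(0)
    for col in ("soil_temp_mean", "wind_mean", "soil_temp_mean_lag1",
                "wind_mean_lag1", "rain", "irradiance"):
        cov[col] = cov[col] + rng.uniform(0, 0.5, len(cov))
    res = DSRModel(join_covariates(recs, cov), spec).fit()
    beta = pd.Series(
        [params.get("intercept", 0.0)] + [params[t] for t in terms],
        index=res.params.index,
    )
    res.params = beta
    if bse is not None:
        se = np.array([bse.get("intercept", 0.0)] + [bse.get(t, 0.0) for t in terms])
        res.vcov = pd.DataFrame(
            np.diag(se**2), index=beta.index, columns=beta.index
        )
    res.converged = True
    res.diagnostic = ""
    return res


@pytest.fixture(scope="session")
def season_weather():
    return {
        region: simulate_weather(params, region, 130, seed=11)
        for region, params in DEFAULT_WEATHER.items()
    }


@pytest.fixture(scope="session")
def demo_dataset(season_weather):
    truth_model = TrueModel()
    records, covariates, truth = simulate_nests(
        truth_model,
        season_weather,
        {
            ("Alsace", "camera"): 30,
            ("Alsace", "visits"): 25,
            ("HautsDeFrance", "camera"): 85,
            ("HautsDeFrance", "visits"): 60,
        },
        seed=7,
    )
    return truth_model, records, covariates, truth


@pytest.fixture(scope="session")
def demo_day_table(demo_dataset):
    _, records, covariates, _ = demo_dataset
    return join_covariates(records, covariates)


@pytest.fixture(scope="session")
def demo_fit(demo_dataset, demo_day_table):
    truth_model, _, _, _ = demo_dataset
    return DSRModel(demo_day_table, truth_model.spec).fit()
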