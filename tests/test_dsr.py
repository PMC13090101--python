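import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import _oracles
from conftest import constant_covariates, make_nest, results_with
from nestfate.dsr import DSRModel, ModelSpec, SpecError, nest_log_likelihood
from nestfate.records import join_covariates


def intercept_day_table(records, **cov_kwargs):
    return join_covariates(records, constant_covariates(records, **cov_kwargs))


class TestModelSpec:
    def test_interaction_needs_both_parents(self):
        with pytest.raises(SpecError):
            ModelSpec(("region", "region:method"))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(SpecError):
            ModelSpec(("region", "region"))

    def test_k_counts_intercept(self):
        assert ModelSpec(()).k_params == 1
        assert ModelSpec(("region", "method", "region:method")).k_params == 4


class TestLikelihood:
    def test_hatched_nest_is_survival_product(self):
        r = make_nest("n", fate="hatched", i=1, j=3, k=3)
        ll = nest_log_likelihood([logit(0.9)], ModelSpec(()), intercept_day_table([r]))
        assert ll == pytest.approx(2 * math.log(0.9), abs=1e-10)

    def test_failed_nest_adds_window_term(self):
        # survive days 1-2, then fail somewhere in days 3-4:
        # P = 0.9^2 * (1 - 0.9^2)
        r = make_nest("n", fate="depredated", i=1, j=3, k=5)
        ll = nest_log_likelihood([logit(0.9)], ModelSpec(()), intercept_day_table([r]))
        assert ll == pytest.approx(2 * math.log(0.9) + math.log(1 - 0.81), abs=1e-10)

    def test_zero_beta_gives_half(self):
        r = make_nest("n", fate="hatched", i=1, j=2, k=2)
        ll = nest_log_likelihood([0.0], ModelSpec(()), intercept_day_table([r]))
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_failed_nest_with_empty_window_rejected(self):
        r = make_nest("n", fate="hatched", i=1, j=3, k=3)
        day = intercept_day_table([r])
        day.loc[day.index[-1], "status"] = "failure_window"
        with pytest.raises(ValueError):
            nest_log_likelihood([0.0], ModelSpec(()), day)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        beta0=st.floats(-3, 3),
        beta_wind=st.floats(-2, 2),
        j_off=st.integers(1, 3),
        extra=st.integers(0, 2),
        failed=st.booleans(),
        wind=st.lists(st.floats(0.0, 2.0), min_size=3, max_size=3),
    )
    def test_matches_exhaustive_path_enumeration(
        self, beta0, beta_wind, j_off, extra, failed, wind
    ):
        """Short-nest likelihood equals brute-force outcome-path enumeration."""
        if failed:
            span = min(j_off + max(extra, 1), 3)
            j_off = min(j_off, span - 1)
            r = make_nest("n", fate="depredated", i=1, j=1 + j_off, k=1 + span)
        else:
            span = j_off
            r = make_nest("n", fate="hatched", i=1, j=1 + span, k=1 + span)
        cov = constant_covariates([r])
        cov["wind_mean"] = [wind[d % 3] for d in range(len(cov))]
        day = join_covariates([r], cov)
        spec = ModelSpec(("wind_mean",))
        ll = nest_log_likelihood([beta0, beta_wind], spec, day)
        s_days = list(expit(beta0 + beta_wind * day["wind_mean"].to_numpy()))
        expected = _oracles.path_enumeration_loglik(
            s_days, r.day_last_active - r.day_found, failed
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_nest_and_day_permutation(self, demo_day_table, demo_dataset):
        truth_model = demo_dataset[0]
        beta = truth_model.beta()
        base = nest_log_likelihood(beta, truth_model.spec, demo_day_table)
        shuffled = demo_day_table.sample(frac=1.0, random_state=5)
        assert nest_log_likelihood(beta, truth_model.spec, shuffled) == pytest.approx(
            base, rel=1e-12
        )


class TestFit:
    def test_mayfield_closed_form_for_exact_failure_days(self):
        # 5 hatched nests with 15 alive days each, 5 failed with 4 alive days
        # and an exactly-known failure day: D = 95, F = 5 -> S = 0.95
        recs = [
            make_nest(f"h{n}", fate="hatched", i=1, j=16, k=16) for n in range(5)
        ] + [
            make_nest(f"f{n}", fate="depredated", i=1, j=5, k=6) for n in range(5)
        ]
        res = DSRModel(intercept_day_table(recs), ModelSpec(())).fit()
        s_hat = expit(res.params["intercept"])
        assert s_hat == pytest.approx(_oracles.mayfield_closed_form(95, 5), abs=1e-6)
        assert res.params["intercept"] == pytest.approx(logit(0.95), abs=1e-4)
        assert res.converged

    def test_all_hatched_flags_complete_survival(self):
        recs = [make_nest(f"h{n}", fate="hatched", i=1, j=10, k=10) for n in range(4)]
        res = DSRModel(intercept_day_table(recs), ModelSpec(())).fit()
        assert not res.converged
        assert "complete survival" in res.diagnostic

    def test_rank_deficient_design_names_aliased_terms(self):
        recs = [
            make_nest("a", fate="hatched", i=1, j=8, k=8),
            make_nest("b", fate="depredated", i=1, j=4, k=7),
        ]
        cov = constant_covariates(recs)
        cov["wind_mean"] = cov["soil_temp_mean"]  # perfectly collinear
        day = join_covariates(recs, cov)
        with pytest.raises(np.linalg.LinAlgError, match="wind_mean|soil_temp_mean"):
            DSRModel(day, ModelSpec(("soil_temp_mean", "wind_mean")))

    def test_recovers_generating_coefficients(self, demo_fit, demo_dataset):
        """A single 200-nest replicate: estimates near truth, CIs sane."""
        truth_model = demo_dataset[0]
        assert demo_fit.converged
        ci = demo_fit.conf_int()
        truth = truth_model.beta()
        inside = [
            ci.iloc[t]["lower"] <= truth[t] <= ci.iloc[t]["upper"]
            for t in range(len(truth))
        ]
        assert sum(inside) >= len(truth) - 1  # allow one marginal miss


class TestPredict:
    def test_zero_beta_predicts_half(self):
        res = results_with({"intercept": 0.0, "wind_mean": 0.0})
        rows = pd.DataFrame({"wind_mean": [0.1, 2.0, 5.0]})
        assert np.allclose(res.predict(rows), 0.5)

    def test_null_intercept_matches_closed_form(self):
        res = results_with({"intercept": 3.678})
        (s,) = res.predict(pd.DataFrame(index=[0]))
        assert s == pytest.approx(1 / (1 + math.exp(-3.678)), abs=1e-12)
        assert s == pytest.approx(0.97535, abs=1e-5)

    def test_top_model_scalar_oracle(self):
        """Hand evaluation of the fitted top model at Alsace/visits, wind 0.3."""
        res = results_with(
            {
                "intercept": -1.013, "region": 1.700, "method": 1.931,
                "wind_mean": 1.905, "wind_mean_lag1": 7.732,
                "region:method": -1.708, "wind_mean:wind_mean_lag1": -5.741,
            }
        )
        row = pd.DataFrame(
            {
                "region": ["Alsace"], "method": ["visits"],
                "wind_mean": [0.3], "wind_mean_lag1": [0.3],
            }
        )
        eta = -1.013 + 1.905 * 0.3 + 7.732 * 0.3 - 5.741 * 0.09
        assert res.predict(row)[0] == pytest.approx(1 / (1 + math.exp(-eta)), abs=1e-12)

    def test_missing_term_column_raises(self):
        res = results_with({"intercept": 0.0, "wind_mean": 1.0})
        with pytest.raises(KeyError, match="wind_mean"):
            res.predict(pd.DataFrame({"rain": [1.0]}))

    def test_prediction_monotone_in_intercept(self, demo_fit, demo_day_table):
        rows = demo_day_table.head(50)
        lower = demo_fit.predict(rows)
        bumped = results_with(
            {**{t: demo_fit.params[t] for t in demo_fit.params.index if t != "intercept"},
             "intercept": demo_fit.params["intercept"] + 1.0}
        )
        # same spec terms, larger intercept -> strictly larger survival
        assert np.all(bumped.predict(rows) > lower)


class TestWaldCI:
    def test_published_interval_reproduced_within_rounding(self):
        res = results_with({"intercept": -1.013, "region": 1.700},
                           bse={"intercept": 0.915, "region": 0.565})
        ci = res.conf_int()
        assert ci.loc["region", "lower"] == pytest.approx(0.591, abs=0.005)
        assert ci.loc["region", "upper"] == pytest.approx(2.808, abs=0.005)
        assert bool(ci.loc["region", "informative"])

    def test_zero_se_degenerates_to_point(self):
        res = results_with({"intercept": 1.3}, bse={"intercept": 0.0})
        ci = res.conf_int()
        assert ci.loc["intercept", "lower"] == ci.loc["intercept", "upper"] == 1.3

    def test_informative_iff_z_exceeds_critical(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        for est, se in [(1.0, 0.5), (1.0, 0.52), (-0.4, 0.21), (0.4, 0.199)]:
            res = results_with({"intercept": 0.0, "rain": est},
                               bse={"intercept": 1.0, "rain": se})
            flag = bool(res.conf_int().loc["rain", "informative"])
            assert flag == (abs(est) / se > z)

    def test_nonconverged_model_refuses_intervals(self):
        recs = [make_nest(f"h{n}", fate="hatched", i=1, j=10, k=10) for n in range(3)]
        res = DSRModel(intercept_day_table(recs), ModelSpec(())).fit()
        with pytest.raises(ValueError, match="converge"):
            res.conf_int()


def test_serialization_round_trip_fields(demo_fit):
    import json

    blob = json.loads(demo_fit.to_json())
    assert blob["terms"] == list(demo_fit.spec.terms)
    assert blob["K"] == demo_fit.k_params
    assert blob["logLik"] == pytest.approx(demo_fit.llf)
    assert np.allclose(blob["vcov"], demo_fit.vcov.to_numpy())
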