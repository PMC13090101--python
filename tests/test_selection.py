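import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import results_with
from nestfate.dsr import GLOBAL_TERMS, INTERACTION_TERMS, ModelSpec
from nestfate.pipeline import DEMO_GLOBAL
from nestfate.records import join_covariates, records_to_frame
from nestfate.selection import (
    CandidateFit,
    aicc,
    akaike_weights,
    balance_filter,
    enumerate_models,
    informative_screen,
    screen_collinearity,
    select,
)
from nestfate.simulate import TrueModel, simulate_nests


class TestAicc:
    def test_reproduces_null_model_score(self):
        assert aicc(-197.431, 1, 2087) == pytest.approx(396.863, abs=0.01)

    def test_small_sample_formula(self):
        n = 50
        assert aicc(0.0, 1, n) == pytest.approx(2 + 4 / (n - 2))

    def test_correction_vanishes_for_large_n(self):
        assert aicc(-10.0, 3, 1e9) == pytest.approx(20 + 6, abs=1e-6)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_single_model_gets_unit_weight(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_two_model_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_ties_share_equally_and_sum_to_one(self):
        w = akaike_weights([50.0, 50.0, 50.0, 51.0])
        assert w[0] == w[1] == w[2]
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestEnumerate:
    def test_intercept_only_global(self):
        assert enumerate_models(ModelSpec(())) == [ModelSpec(())]

    def test_two_mains_one_interaction(self):
        specs = enumerate_models(ModelSpec(("region", "method", "region:method")))
        got = {frozenset(s.terms) for s in specs}
        assert got == {
            frozenset(), frozenset({"region"}), frozenset({"method"}),
            frozenset({"region", "method"}),
            frozenset({"region", "method", "region:method"}),
        }

    @pytest.mark.parametrize("global_terms", [DEMO_GLOBAL, GLOBAL_TERMS])
    def test_matches_brute_force_hierarchy_filter(self, global_terms):
        specs = enumerate_models(ModelSpec(global_terms))
        got = {frozenset(s.terms) for s in specs}
        expected = _oracles.hierarchical_subsets(
            tuple(global_terms), dict(INTERACTION_TERMS)
        )
        assert len(specs) == len(got)  # no duplicates
        assert got == expected


class TestCollinearity:
    def test_duplicated_column_drops_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=200)})
        df["b"] = df["a"]
        kept, report = screen_collinearity(df, ["a", "b"])
        assert kept == ["a"]
        assert report.loc[0, "dropped"] == "b"

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10_000, 3)), columns=["a", "b", "c"])
        kept, _ = screen_collinearity(df, ["a", "b", "c"])
        assert kept == ["a", "b", "c"]

    def test_threshold_is_strict_inequality(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"] + rng.normal(size=50)
        r = abs(float(np.corrcoef(df["a"], df["b"])[0, 1]))
        kept, _ = screen_collinearity(df, ["a", "b"], threshold=r)
        assert kept == ["a", "b"]  # |r| == threshold is not "greater than"

    def test_zero_variance_dropped_with_report(self):
        df = pd.DataFrame({"a": np.arange(10.0), "z": np.ones(10)})
        kept, report = screen_collinearity(df, ["a", "z"])
        assert kept == ["a"]
        assert (report["reason"] == "zero variance").any()

    def test_priority_list_decides_loser(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        df["b"] = df["a"] + 0.01 * rng.normal(size=100)
        kept, _ = screen_collinearity(df, ["a", "b"], priority=["b", "a"])
        assert kept == ["b"]


def nest_frame(counts: dict) -> pd.DataFrame:
    rows = []
    i = 0
    for (region, method), n in counts.items():
        for _ in range(n):
            rows.append({"nest_id": f"n{i}", "region": region, "method": method,
                         "year": 2022, "habitat": "crop", "clutch_class": "eq4"})
            i += 1
    return pd.DataFrame(rows)


class TestBalanceFilter:
    SPEC = ModelSpec(("region", "method", "region:method"))

    def test_study_design_cells_admissible(self):
        nests = nest_frame({("Alsace", "camera"): 20, ("Alsace", "visits"): 17,
                            ("HautsDeFrance", "camera"): 72,
                            ("HautsDeFrance", "visits"): 36})
        ok, reason = balance_filter(self.SPEC, nests)
        assert ok and reason == ""

    def test_cell_of_five_is_too_small(self):
        nests = nest_frame({("Alsace", "camera"): 5, ("Alsace", "visits"): 17,
                            ("HautsDeFrance", "camera"): 72,
                            ("HautsDeFrance", "visits"): 36})
        ok, reason = balance_filter(self.SPEC, nests)
        assert not ok and reason == "small-group"

    def test_perfectly_balanced_table_admissible(self):
        nests = nest_frame({("Alsace", "camera"): 50, ("Alsace", "visits"): 50,
                            ("HautsDeFrance", "camera"): 50,
                            ("HautsDeFrance", "visits"): 50})
        assert balance_filter(self.SPEC, nests) == (True, "")

    def test_strong_association_is_unbalanced(self):
        nests = nest_frame({("Alsace", "camera"): 40, ("Alsace", "visits"): 8,
                            ("HautsDeFrance", "camera"): 8,
                            ("HautsDeFrance", "visits"): 40})
        ok, reason = balance_filter(self.SPEC, nests)
        assert not ok and reason == "unbalanced"

    def test_single_factor_skips_chi_square(self):
        nests = nest_frame({("Alsace", "camera"): 90, ("HautsDeFrance", "camera"): 8})
        ok, _ = balance_filter(ModelSpec(("region",)), nests)
        assert ok


class TestInformativeScreen:
    def test_all_overlapping_cis_excluded(self):
        res = results_with({"intercept": 0.0, "rain": 0.05},
                           bse={"intercept": 1.0, "rain": 0.1})
        cand = CandidateFit(res.spec, res)
        informative_screen([cand])
        assert cand.excluded and cand.reason == "all-uninformative"

    def test_one_informative_predictor_retains_model(self):
        res = results_with({"intercept": 0.0, "rain": 0.3, "wind_mean": 0.0},
                           bse={"intercept": 1.0, "rain": 0.1, "wind_mean": 1.0})
        cand = CandidateFit(res.spec, res)
        informative_screen([cand])
        assert not cand.excluded

    def test_null_model_never_screened(self):
        res = results_with({"intercept": 0.5}, bse={"intercept": 5.0})
        cand = CandidateFit(res.spec, res)
        informative_screen([cand])
        assert not cand.excluded

    def test_exclusion_rate_matches_nominal_level(self, season_weather):
        """With a truly null covariate, ~95% of single-covariate models are
        screened out (their 95% CI covers 0 at the nominal rate)."""
        truth = TrueModel(coefficients={"intercept": 3.2})
        spec = ModelSpec(("wind_mean",))
        excluded = 0
        n_seeds = 400
        for seed in range(n_seeds):
            recs, cov, _ = simulate_nests(
                truth, season_weather, {("HautsDeFrance", "camera"): 100},
                seed=10_000 + seed,
            )
            res = None
            day = join_covariates(recs, cov)
            try:
                from nestfate.dsr import DSRModel

                res = DSRModel(day, spec).fit()
            except Exception:
                continue
            cand = CandidateFit(spec, res)
            informative_screen([cand])
            excluded += cand.excluded
        assert excluded / n_seeds == pytest.approx(0.95, abs=0.03)


class TestSelect:
    def test_recovers_generating_model(self, demo_dataset, demo_day_table):
        truth_model, records, _, _ = demo_dataset
        nests = records_to_frame([r for r in records if r.included])
        table = select(ModelSpec(DEMO_GLOBAL), nests, demo_day_table)
        kept = table.table[~table.table["excluded"]]
        assert kept["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert kept.iloc[0]["delta_AICc"] == 0.0
        truth_terms = set(truth_model.spec.terms)
        truth_row = kept[kept["model"] == truth_model.spec.label()]
        top_terms = set(
            t.strip() for t in kept.iloc[0]["model"].split("+") if t.strip() != "1"
        )
        assert (len(truth_row) and truth_row.iloc[0]["delta_AICc"] <= 2.0) or (
            top_terms >= truth_terms
        )

    def test_null_truth_keeps_null_competitive(self, season_weather):
        truth = TrueModel(coefficients={"intercept": 3.2})
        recs, cov, _ = simulate_nests(
            truth, season_weather,
            {("Alsace", "camera"): 60, ("Alsace", "visits"): 60,
             ("HautsDeFrance", "camera"): 60, ("HautsDeFrance", "visits"): 60},
            seed=42,
        )
        nests = records_to_frame(recs)
        table = select(ModelSpec(DEMO_GLOBAL), nests, join_covariates(recs, cov))
        kept = table.table[~table.table["excluded"]]
        null_delta = float(kept.loc[kept["model"] == "1", "delta_AICc"].iloc[0])
        assert null_delta <= 2.0

    def test_invariant_to_nest_row_permutation(self, demo_dataset, demo_day_table):
        _, records, _, _ = demo_dataset
        nests = records_to_frame([r for r in records if r.included])
        t1 = select(ModelSpec(("region", "method")), nests, demo_day_table).table
        t2 = select(
            ModelSpec(("region", "method")),
            nests.sample(frac=1.0, random_state=9).reset_index(drop=True),
            demo_day_table.sample(frac=1.0, random_state=9),
        ).table
        pd.testing.assert_frame_equal(t1, t2)
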