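"""Logit-linear daily nest survival with interval-censored failures.

The daily survival rate (DSR) of nest *n* on day *t* is

    S_nt = 1 / (1 + exp(-x_nt' beta))

with a design vector built from grouping factors (region, monitoring
method, habitat, year, clutch-size class), daily weather covariates and
their one-day lags, day of season, and a small set of two-way interactions.

Each nest contributes a known-fate, interval-censored likelihood term.
Writing i, j, k for the day found, the last day known active, and the day
the fate was confirmed:

    log L_n = sum_{t=i}^{j-1} log S_nt
              + [failed] * log(1 - prod_{t=j}^{k-1} S_nt)

A hatched nest (j = k) contributes only the survival product; a failed nest
additionally contributes the probability that it died somewhere inside the
bracketing window (j, k].  This is the classical known-fate nest-survival
likelihood with daily resolution; failures are never located sub-day.

Fitting follows the statsmodels convention: :class:`DSRModel` holds the
data and term specification, ``fit()`` returns a :class:`DSRResults` with
the coefficient vector on the logit scale, its covariance from the inverse
observed information, Wald intervals and prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from . import records as rec

__all__ = [
    "MAIN_TERMS",
    "INTERACTION_TERMS",
    "GLOBAL_TERMS",
    "ModelSpec",
    "DSRModel",
    "DSRResults",
    "nest_log_likelihood",
    "fit_dsr",
    "predict_dsr",
    "wald_ci",
]

# Main-effect terms of the global model.  Categorical factors use reference
# coding with indicators named for the non-reference level: Hauts-de-France
# vs Alsace, camera vs visits, crop vs other, eq4 vs lt4, and an indicator
# for the later of the two study years.
MAIN_TERMS = (
    "habitat",
    "year",
    "clutch_class",
    "rain",
    "irradiance",
    "soil_temp_mean",
    "wind_mean",
    "soil_temp_mean_lag1",
    "wind_mean_lag1",
    "region",
    "method",
    "day_of_season",
)

#: interaction -> its two parent main effects (model hierarchy)
INTERACTION_TERMS: Mapping[str, tuple[str, str]] = {
    "soil_temp_mean:wind_mean": ("soil_temp_mean", "wind_mean"),
    "region:wind_mean": ("region", "wind_mean"),
    "soil_temp_mean:soil_temp_mean_lag1": ("soil_temp_mean", "soil_temp_mean_lag1"),
    "wind_mean:wind_mean_lag1": ("wind_mean", "wind_mean_lag1"),
    "region:method": ("region", "method"),
}

#: The full global model: every main effect plus the five interactions.
GLOBAL_TERMS = tuple(MAIN_TERMS) + tuple(INTERACTION_TERMS)

CATEGORICAL_TERMS = frozenset({"habitat", "year", "clutch_class", "region", "method"})


class SpecError(ValueError):
    """A term list violates the model hierarchy or names an unknown term."""


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of model terms; the intercept is always implicit."""

    terms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        seen = set()
        for t in self.terms:
            if t not in MAIN_TERMS and t not in INTERACTION_TERMS:
                raise SpecError(f"unknown model term {t!r}")
            if t in seen:
                raise SpecError(f"duplicate model term {t!r}")
            seen.add(t)
        for t in self.terms:
            if t in INTERACTION_TERMS:
                a, b = INTERACTION_TERMS[t]
                if a not in seen or b not in seen:
                    raise SpecError(
                        f"interaction {t!r} requires both main effects {a!r} and {b!r}"
                    )

    @property
    def k_params(self) -> int:
        return 1 + len(self.terms)

    @property
    def categorical_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t in CATEGORICAL_TERMS)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "1"


def _main_column(term: str, df: pd.DataFrame, ref_year: int | None) -> np.ndarray:
    if term == "region":
        return (df["region"].to_numpy() == "HautsDeFrance").astype(float)
    if term == "method":
        return (df["method"].to_numpy() == "camera").astype(float)
    if term == "habitat":
        return (df["habitat"].to_numpy() == "crop").astype(float)
    if term == "clutch_class":
        return (df["clutch_class"].to_numpy() == "eq4").astype(float)
    if term == "year":
        years = df["year"].to_numpy().astype(int)
        ref = ref_year if ref_year is not None else years.min()
        return (years != ref).astype(float)
    return df[term].to_numpy(dtype=float)


def build_design(
    df: pd.DataFrame, spec: ModelSpec, ref_year: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with leading intercept column) for a day-level table."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    cache: dict[str, np.ndarray] = {}
    for term in spec.terms:
        if term in INTERACTION_TERMS:
            a, b = INTERACTION_TERMS[term]
            col = cache[a] * cache[b]
        else:
            if term not in df.columns:
                raise KeyError(f"day table lacks column for term {term!r}")
            col = _main_column(term, df, ref_year)
            cache[term] = col
        if not np.all(np.isfinite(col)):
            raise ValueError(f"non-finite covariate values in term {term!r}")
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the aliased columns if X is rank deficient."""
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify columns whose removal restores full rank relative to the rest
        aliased = []
        for idx in range(X.shape[1] - 1, -1, -1):
            keep = [c for c in range(X.shape[1]) if c != idx and names[c] not in aliased]
            if np.linalg.matrix_rank(X[:, keep]) == r:
                aliased.append(names[idx])
                if len(aliased) >= X.shape[1] - r:
                    break
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; aliased term(s): {sorted(aliased)}"
        )


@dataclass
class _LikelihoodData:
    """Flattened per-row arrays for fast likelihood evaluation."""

    X: np.ndarray                 # (n_rows, K)
    alive: np.ndarray             # bool, row is a confirmed-alive day
    window_group: np.ndarray      # int, failed-nest index per failure-window row (-1 otherwise)
    n_failed: int
    names: list[str]
    n_rows: int


def _prepare(day_table: pd.DataFrame, spec: ModelSpec, ref_year=None) -> _LikelihoodData:
    if len(day_table) == 0:
        raise ValueError("empty day table: no exposure days")
    required = {"nest_id", "status", "failed"}
    missing = required - set(day_table.columns)
    if missing:
        raise KeyError(f"day table lacks column(s) {sorted(missing)}")
    X, names = build_design(day_table, spec, ref_year)
    status = day_table["status"].to_numpy()
    alive = status == "alive"
    window = ~alive
    # map failure-window rows to a dense failed-nest index
    wg = np.full(len(day_table), -1, dtype=int)
    if window.any():
        ids = day_table["nest_id"].to_numpy()[window]
        uniq, inv = np.unique(ids, return_inverse=True)
        wg[window] = inv
        n_failed = len(uniq)
        # a failed nest must have k > j, i.e. at least one window row
        bad = day_table.loc[window & ~day_table["failed"].to_numpy(), "nest_id"]
        if len(bad):
            raise ValueError(
                f"failure-window rows for non-failed nest(s): {sorted(set(bad))[:5]}"
            )
    else:
        n_failed = 0
    failed_ids = set(day_table.loc[day_table["failed"], "nest_id"])
    windowed_ids = set(day_table.loc[window, "nest_id"])
    no_window = failed_ids - windowed_ids
    if no_window:
        raise ValueError(
            "failed nest(s) with an empty failure window (k = j): "
            f"{sorted(no_window)[:5]}"
        )
    return _LikelihoodData(X, alive, wg, n_failed, names, len(day_table))


def _loglik_grad(beta: np.ndarray, data: _LikelihoodData) -> tuple[float, np.ndarray]:
    eta = data.X @ beta
    log_s = -np.logaddexp(0.0, -eta)          # log sigmoid, stable
    s = np.exp(log_s)
    ll = float(log_s[data.alive].sum())
    grad = data.X[data.alive].T @ (1.0 - s[data.alive])
    if data.n_failed:
        w = ~data.alive
        # log of the window survival product per failed nest
        log_pw = np.bincount(
            data.window_group[w], weights=log_s[w], minlength=data.n_failed
        )
        log_pw = np.minimum(log_pw, -1e-12)   # guard exact 0 at extreme beta
        log_1m = np.log(-np.expm1(log_pw))
        ll += float(log_1m.sum())
        # d/dbeta log(1 - Pw) = -(Pw / (1 - Pw)) * sum_window (1 - S_t) x_t
        ratio = np.exp(log_pw - log_1m)       # Pw / (1 - Pw)
        row_w = -ratio[data.window_group[w]] * (1.0 - s[w])
        grad += data.X[w].T @ row_w
    return ll, grad


def nest_log_likelihood(
    beta: Sequence[float], spec: ModelSpec, day_table: pd.DataFrame
) -> float:
    """Known-fate interval-censored log likelihood at ``beta``.

    ``day_table`` comes from :func:`nestfate.records.join_covariates`; beta
    is ordered (intercept, *spec.terms*).
    """
    data = _prepare(day_table, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.X.shape[1],):
        raise ValueError(
            f"beta has length {beta.shape[0]}, spec needs {data.X.shape[1]}"
        )
    return _loglik_grad(beta, data)[0]


class DSRModel:
    """Daily-survival-rate model for known-fate nest data.

    Parameters
    ----------
    day_table : DataFrame
        Day-level analysis table from :func:`records.join_covariates`
        (one row per nest per at-risk day).
    spec : ModelSpec
        Terms entering the linear predictor (intercept implicit).
    ref_year : int, optional
        Reference level for the ``year`` indicator; defaults to the earliest
        year in the table.
    """

    def __init__(self, day_table: pd.DataFrame, spec: ModelSpec, ref_year: int | None = None):
        self.day_table = day_table
        self.spec = spec
        self.ref_year = ref_year
        self._data = _prepare(day_table, spec, ref_year)
        check_full_rank(self._data.X, self._data.names)
        self.exog_names = list(self._data.names)
        #: effective sample size for AICc: total exposure days sum(k - i)
        self.n_effective = self._data.n_rows

    @classmethod
    def from_records(
        cls,
        nests: Iterable[rec.NestRecord],
        covariates: pd.DataFrame,
        spec: ModelSpec,
        ref_year: int | None = None,
    ) -> "DSRModel":
        return cls(rec.join_covariates(nests, covariates), spec, ref_year)

    # -- likelihood ----------------------------------------------------
    def loglike(self, beta: np.ndarray) -> float:
        return _loglik_grad(np.asarray(beta, float), self._data)[0]

    def score(self, beta: np.ndarray) -> np.ndarray:
        return _loglik_grad(np.asarray(beta, float), self._data)[1]

    def mayfield(self) -> float:
        """Constant-DSR starting estimate: alive-days / (alive-days + failures).

        Classical Mayfield accounting on the confirmed portion of the data:
        every observed-alive day is a success trial and every failed nest
        one failure event.
        """
        d = int(self._data.alive.sum())
        f = self._data.n_failed
        if d == 0:
            return 0.5
        return d / (d + f) if f else 1.0 - 0.5 / (d + 1)

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        start: Sequence[float] | None = None,
        bound: float = 25.0,
        gtol: float = 1e-8,
        maxiter: int = 500,
    ) -> "DSRResults":
        """Maximise the likelihood by L-BFGS-B from a Mayfield-informed start.

        Coefficients are box-bounded at +/-``bound`` on the logit scale so a
        divergent fit (e.g. no observed failures pushes the intercept to
        +inf) stays finite; an estimate on the bound is flagged as
        non-converged rather than reported silently.
        """
        k = self._data.X.shape[1]
        if start is None:
            start = np.zeros(k)
            s0 = np.clip(self.mayfield(), 1e-6, 1 - 1e-6)
            start[0] = special.logit(s0)
        start = np.asarray(start, dtype=float)

        def negloglik(b):
            ll, g = _loglik_grad(b, self._data)
            return -ll, -g

        res = optimize.minimize(
            negloglik,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-bound, bound)] * k,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        beta = res.x
        at_bound = bool(np.any(np.abs(np.abs(beta) - bound) < 1e-8))
        complete_survival = self._data.n_failed == 0
        converged = bool(res.success) and not at_bound and not complete_survival
        diagnostic = ""
        if complete_survival:
            diagnostic = "complete survival: no failures observed, DSR diverges to 1"
        elif at_bound:
            diagnostic = f"coefficient(s) at the +/-{bound} logit bound"
        elif not res.success:
            diagnostic = f"optimizer did not converge: {res.message}"

        hess = numdiff.approx_hess(beta, lambda b: _loglik_grad(b, self._data)[0])
        try:
            vcov = np.linalg.inv(-hess)
            vcov = 0.5 * (vcov + vcov.T)
        except np.linalg.LinAlgError:
            vcov = np.full((k, k), np.nan)
            if converged:
                converged, diagnostic = False, "singular observed information"
        return DSRResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            vcov=pd.DataFrame(vcov, index=self.exog_names, columns=self.exog_names),
            llf=float(-res.fun),
            converged=converged,
            diagnostic=diagnostic,
            n_iter=int(res.nit),
        )


@dataclass
class DSRResults:
    """Fit results: coefficients on the logit scale with Wald inference."""

    model: DSRModel
    params: pd.Series
    vcov: pd.DataFrame
    llf: float
    converged: bool
    diagnostic: str = ""
    n_iter: int = 0

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def k_params(self) -> int:
        return len(self.params)

    @property
    def n_effective(self) -> int:
        return self.model.n_effective

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    @property
    def aicc(self) -> float:
        from .selection import aicc as _aicc

        return _aicc(self.llf, self.k_params, self.n_effective)

    def cov_params(self) -> pd.DataFrame:
        return self.vcov

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals plus the per-coefficient "informative" flag.

        A coefficient is flagged informative when its interval excludes 0;
        covariates whose interval overlaps 0 are treated as weakly
        predictive in model screening.
        """
        if not self.converged:
            raise ValueError(f"model did not converge ({self.diagnostic})")
        z = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        informative = (lo > 0) | (hi < 0)
        return pd.DataFrame(
            {"lower": lo, "upper": hi, "informative": informative}, index=self.params.index
        )

    def predict(self, covariate_rows: pd.DataFrame) -> np.ndarray:
        """Daily survival probabilities for new covariate rows."""
        X, _ = build_design(covariate_rows, self.spec, self.model.ref_year)
        return special.expit(X @ self.params.to_numpy())

    def summary(self, level: float = 0.95) -> str:
        lines = [
            "Known-fate daily nest survival (logit link)",
            f"  terms: {self.spec.label()}",
            f"  K = {self.k_params}   exposure days = {self.n_effective}",
            f"  logLik = {self.llf:.3f}   AICc = {self.aicc:.3f}"
            f"   converged = {self.converged}",
        ]
        if self.diagnostic:
            lines.append(f"  note: {self.diagnostic}")
        if self.converged:
            ci = self.conf_int(level)
            lines.append(f"  {'term':<34}{'coef':>10}{'SE':>9}{'lower':>9}{'upper':>9}")
            for name in self.params.index:
                star = "*" if ci.loc[name, "informative"] else " "
                lines.append(
                    f"  {name:<34}{self.params[name]:>10.3f}{self.bse[name]:>9.3f}"
                    f"{ci.loc[name, 'lower']:>9.3f}{ci.loc[name, 'upper']:>9.3f}{star}"
                )
            lines.append("  * 95% CI excludes 0")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(self.spec.terms),
                "beta": self.params.to_numpy().tolist(),
                "vcov": self.vcov.to_numpy().tolist(),
                "logLik": self.llf,
                "K": self.k_params,
                "n_effective": self.n_effective,
                "converged": self.converged,
                "diagnostic": self.diagnostic,
            },
            indent=1,
        )


# -- module-level conveniences mirroring the library surface ------------

def fit_dsr(spec: ModelSpec, day_table: pd.DataFrame, **options) -> DSRResults:
    """Fit a DSR model spec to a day-level table (see :class:`DSRModel`)."""
    return DSRModel(day_table, spec, ref_year=options.pop("ref_year", None)).fit(**options)


def predict_dsr(results: DSRResults, covariate_rows: pd.DataFrame) -> np.ndarray:
    return results.predict(covariate_rows)


def wald_ci(results: DSRResults, level: float = 0.95) -> pd.DataFrame:
    return results.conf_int(level)
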