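"""Candidate-model enumeration, screening and AICc ranking.

The selection pipeline mirrors a constrained all-subsets information-
theoretic workflow: every model nested within a global model is generated
(respecting interaction hierarchy), candidates whose grouping factors are
unbalanced or produce tiny groups are excluded before fitting, fitted
candidates in which no covariate is informative (every 95% CI overlaps 0)
are screened out, and the survivors are ranked by small-sample-corrected
AIC with Akaike weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dsr import (
    CATEGORICAL_TERMS,
    INTERACTION_TERMS,
    DSRModel,
    DSRResults,
    ModelSpec,
)

__all__ = [
    "screen_collinearity",
    "enumerate_models",
    "balance_filter",
    "aicc",
    "akaike_weights",
    "informative_screen",
    "select",
    "SelectionTable",
]


def aicc(loglik: float, k: int, n: float) -> float:
    """Small-sample Akaike criterion: -2 logL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def screen_collinearity(
    table: pd.DataFrame,
    covariates: Sequence[str],
    threshold: float = 0.65,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every strongly collinear covariate pair.

    Pairwise Pearson r is computed over all analysis rows; a pair is flagged
    when \\|r\\| strictly exceeds ``threshold``.  Within a flagged pair the
    member lower in ``priority`` (default: the given order, earlier = keep)
    is dropped.  Zero-variance covariates are dropped up front.  Returns the
    retained list and a per-pair report.
    """
    priority = list(priority) if priority is not None else list(covariates)
    rank = {c: priority.index(c) if c in priority else len(priority) for c in covariates}
    retained = []
    rows = []
    for c in covariates:
        if table[c].std(ddof=0) == 0:
            rows.append({"var_a": c, "var_b": "", "r": np.nan, "dropped": c,
                         "reason": "zero variance"})
        else:
            retained.append(c)
    dropped: set[str] = set()
    for a, b in itertools.combinations(retained, 2):
        r = float(np.corrcoef(table[a], table[b])[0, 1])
        flag = abs(r) > threshold
        loser = ""
        if flag:
            loser = a if rank[a] > rank[b] else b
            dropped.add(loser)
        rows.append({"var_a": a, "var_b": b, "r": r, "dropped": loser,
                     "reason": f"|r| > {threshold}" if flag else ""})
    kept = [c for c in retained if c not in dropped]
    return kept, pd.DataFrame(rows, columns=["var_a", "var_b", "r", "dropped", "reason"])


def enumerate_models(global_spec: ModelSpec) -> list[ModelSpec]:
    """All submodels of a global model, closed under interaction hierarchy.

    Every subset of main effects is combined with every subset of the
    interactions whose two parents are present; the intercept-only null is
    always included.  Order is deterministic (mains in global order, then
    lexicographic inclusion masks).
    """
    mains = [t for t in global_spec.terms if t not in INTERACTION_TERMS]
    inters = [t for t in global_spec.terms if t in INTERACTION_TERMS]
    out: list[ModelSpec] = []
    for r in range(len(mains) + 1):
        for main_subset in itertools.combinations(mains, r):
            present = set(main_subset)
            allowed = [
                t for t in inters
                if INTERACTION_TERMS[t][0] in present and INTERACTION_TERMS[t][1] in present
            ]
            for q in range(len(allowed) + 1):
                for int_subset in itertools.combinations(allowed, q):
                    out.append(ModelSpec(tuple(main_subset) + tuple(int_subset)))
    return out


def _crosstab_counts(nests: pd.DataFrame, factors: Sequence[str]) -> np.ndarray:
    tab = nests.groupby(list(factors), observed=True).size()
    shape = [nests[f].nunique() for f in factors]
    counts = np.zeros(shape, dtype=float)
    levels = [sorted(nests[f].unique()) for f in factors]
    index = [{lvl: i for i, lvl in enumerate(levs)} for levs in levels]
    for key, n in tab.items():
        key = key if isinstance(key, tuple) else (key,)
        counts[tuple(ix[k] for ix, k in zip(index, key))] = n
    return counts


def balance_filter(
    spec: ModelSpec,
    nests: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 5,
) -> tuple[bool, str]:
    """Admissibility of a candidate's grouping-factor combination.

    Nests are cross-tabulated over every categorical factor in the spec.
    The candidate is inadmissible if any cell holds ``min_group`` or fewer
    nests, or (with >= 2 factors) a Pearson chi-square test of independence
    rejects at ``alpha``: a significantly unbalanced design.  Specs with at
    most one categorical factor face only the small-cell rule.
    """
    factors = list(dict.fromkeys(spec.categorical_terms))
    if not factors:
        return True, ""
    counts = _crosstab_counts(nests, factors)
    if counts.min() <= min_group:
        return False, "small-group"
    if len(factors) >= 2:
        # mutual-independence chi-square: expected = product of marginals
        total = counts.sum()
        expected = np.ones_like(counts) * total
        for axis in range(counts.ndim):
            marg = counts.sum(axis=tuple(a for a in range(counts.ndim) if a != axis))
            shape = [1] * counts.ndim
            shape[axis] = len(marg)
            expected = expected * (marg / total).reshape(shape)
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        dof = int(np.prod(counts.shape) - 1 - sum(s - 1 for s in counts.shape))
        if dof > 0:
            p = float(stats.chi2.sf(chi2, dof))
            if p < alpha:
                return False, "unbalanced"
    return True, ""


def informative_screen(candidates: Iterable["CandidateFit"], level: float = 0.95) -> None:
    """Flag candidates in which every covariate is uninformative.

    A fitted candidate other than the null is excluded when the ``level``
    confidence interval of each of its non-intercept coefficients overlaps
    0; models with at least one informative predictor are retained.
    Non-converged fits are excluded outright.  Exclusions are recorded on
    the candidate, never deleted.
    """
    for cand in candidates:
        if cand.excluded or cand.results is None:
            continue
        res = cand.results
        if not res.converged:
            cand.excluded, cand.reason = True, "nonconverged"
            continue
        if len(res.spec.terms) == 0:
            continue  # the null model is never screened out
        ci = res.conf_int(level)
        informative = ci["informative"].to_numpy()[1:]  # skip intercept
        if not informative.any():
            cand.excluded, cand.reason = True, "all-uninformative"


@dataclass
class CandidateFit:
    spec: ModelSpec
    results: DSRResults | None = None
    excluded: bool = False
    reason: str = ""


@dataclass
class SelectionTable:
    """Ranked candidate models with AICc, weights and exclusion audit."""

    candidates: list[CandidateFit]
    table: pd.DataFrame

    @property
    def best(self) -> CandidateFit:
        kept = [c for c in self.candidates if not c.excluded and c.results is not None]
        return min(kept, key=lambda c: c.results.aicc)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def select(
    global_spec: ModelSpec,
    nests: pd.DataFrame,
    day_table: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 5,
    ci_level: float = 0.95,
    fit_options: dict | None = None,
) -> SelectionTable:
    """Run the full selection pipeline over a global model.

    enumerate -> balance filter -> fit admissible candidates ->
    informative-parameter screen -> AICc ranking with Akaike weights.
    Deterministic given its inputs; excluded candidates stay in the output
    table with their exclusion reason.  ``nests`` is the record-level frame
    (one row per nest) used for the balance filter; ``day_table`` the
    day-level analysis table.
    """
    fit_options = fit_options or {}
    cands = [CandidateFit(spec) for spec in enumerate_models(global_spec)]
    cache: dict[frozenset, DSRResults] = {}
    for cand in cands:
        ok, reason = balance_filter(cand.spec, nests, alpha=alpha, min_group=min_group)
        if not ok:
            cand.excluded, cand.reason = True, reason
            continue
        key = frozenset(cand.spec.terms)
        if key not in cache:
            try:
                cache[key] = DSRModel(day_table, cand.spec).fit(**fit_options)
            except (np.linalg.LinAlgError, ValueError) as err:
                cand.excluded, cand.reason = True, f"fit-error: {err}"
                continue
        cand.results = cache[key]
    informative_screen(cands, level=ci_level)

    kept = [c for c in cands if not c.excluded and c.results is not None]
    if not kept:
        raise ValueError("no admissible candidate model survived screening")
    aiccs = np.array([c.results.aicc for c in kept])
    weights = akaike_weights(aiccs)
    delta = aiccs - aiccs.min()
    rows = []
    for c, a, d, w in zip(kept, aiccs, delta, weights):
        rows.append(
            {
                "model": c.spec.label(),
                "K": c.results.k_params,
                "logLik": c.results.llf,
                "AICc": a,
                "delta_AICc": d,
                "weight": w,
                "excluded": False,
                "reason": "",
            }
        )
    for c in cands:
        if c.excluded:
            rows.append(
                {
                    "model": c.spec.label(),
                    "K": c.spec.k_params,
                    "logLik": c.results.llf if c.results else np.nan,
                    "AICc": np.nan,
                    "delta_AICc": np.nan,
                    "weight": 0.0,
                    "excluded": True,
                    "reason": c.reason,
                }
            )
    table = pd.DataFrame(rows)
    order = table["AICc"].fillna(np.inf)
    table = table.iloc[np.argsort(order, kind="mergesort")].reset_index(drop=True)
    return SelectionTable(cands, table)
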