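"""Nest-fate contingency analysis.

Cross-tabulates nest fates over a grouping factor (region or monitoring
method), tests the full r x c table with Fisher's exact test, and compares
each fate against all others in 2 x 2 collapses with conditional
maximum-likelihood odds ratios and Holm-Bonferroni-adjusted p-values.

The exact test treats all margins as fixed: the probability of a table is
the multivariate hypergeometric

    P(table) = (prod_i r_i!) (prod_j c_j!) / (N! prod_ij n_ij!)

and the two-sided p-value sums P over all tables with the observed margins
whose probability does not exceed that of the observed table (the classical
definition).  The odds ratio reported for a 2 x 2 table is the value of the
noncentral-hypergeometric odds parameter maximising the conditional
likelihood given the margins — the estimate printed by exact 2 x 2 tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .records import FATES, NestRecord, records_to_frame

__all__ = [
    "FateTable",
    "fate_table",
    "fisher_exact",
    "FisherExactResult",
    "conditional_mle_or",
    "rowwise_fate_tests",
    "holm_adjust",
]

FATE_ORDER = tuple(f for f in FATES if f != "undetermined")

#: Exhaustive enumeration is used while the (loose) bound on the number of
#: tables with the observed margins stays below this; beyond it the p-value
#: is estimated by Monte Carlo with a fixed seed and flagged.
ENUMERATION_LIMIT = 5_000_000
MC_DRAWS = 1_000_000
#: Relative slack when comparing table probabilities, to keep float rounding
#: from flipping the "no more probable than observed" classification.
PROB_SLACK = 1e-7


@dataclass
class FateTable:
    """Counts of nest fates per level of a row factor."""

    row_factor: str
    counts: pd.DataFrame  # rows = factor levels, columns = fate categories

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def percentages(self) -> pd.DataFrame:
        """Row-wise percentages, as displayed alongside the counts."""
        return 100.0 * self.counts.div(self.row_totals, axis=0)


def fate_table(nests, row_factor: str) -> FateTable:
    """Cross-tabulate included nests (fate != undetermined) over a factor."""
    if not isinstance(nests, pd.DataFrame):
        nests = records_to_frame(nests)
    df = nests[nests["fate"] != "undetermined"]
    if len(df) == 0:
        raise ValueError("no nests with determined fates to tabulate")
    counts = pd.crosstab(df[row_factor], df["fate"])
    counts = counts.reindex(columns=list(FATE_ORDER), fill_value=0)
    counts = counts.loc[sorted(counts.index)]
    return FateTable(row_factor, counts.astype(int))


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------------

class FisherExactResult(NamedTuple):
    pvalue: float
    method: str  # "exact" or "monte-carlo"


def _log_table_prob(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        special.gammaln(r + 1).sum()
        + special.gammaln(c + 1).sum()
        - special.gammaln(n + 1)
        - special.gammaln(table + 1).sum()
    )


def _count_bound(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Number of tables with the given margins (exact for 2 rows, else a bound)."""
    if len(row_sums) == 2:
        # exact count of first rows x with sum r1 and 0 <= x_j <= c_j,
        # by polynomial convolution
        r1 = int(row_sums[0])
        poly = np.zeros(r1 + 1)
        poly[0] = 1.0
        for c in col_sums:
            kernel = np.ones(min(int(c), r1) + 1)
            poly = np.convolve(poly, kernel)[: r1 + 1]
        return float(poly[r1])
    bound = 1.0
    for _ in range(len(row_sums) - 1):
        for c in col_sums:
            bound *= c + 1
            if bound > 1e12:
                return bound
    return bound


def _enumerate_two_row(col_sums: np.ndarray, r1: int, log_p_obs: float) -> float:
    """Exact two-sided p for a 2 x c table by vectorised enumeration.

    Enumerates all first rows x with sum r1 and 0 <= x_j <= c_j; the second
    row is then determined.  Partial states carry the accumulated
    log prod_j C(c_j, x_j); P(table) = that product / C(N, r1).
    """
    c = np.asarray(col_sums, dtype=int)
    n = int(c.sum())
    suffix = np.concatenate([np.cumsum(c[::-1])[::-1][1:], [0]])  # capacity after col j
    sums = np.zeros(1, dtype=np.int64)
    logp = np.zeros(1)
    for j, cj in enumerate(c):
        x = np.arange(cj + 1)
        log_choose = (
            special.gammaln(cj + 1)
            - special.gammaln(x + 1)
            - special.gammaln(cj - x + 1)
        )
        new_sums = (sums[:, None] + x[None, :]).ravel()
        new_logp = (logp[:, None] + log_choose[None, :]).ravel()
        keep = (new_sums <= r1) & (new_sums + suffix[j] >= r1)
        sums, logp = new_sums[keep], new_logp[keep]
    logp = logp[sums == r1] - (
        special.gammaln(n + 1) - special.gammaln(r1 + 1) - special.gammaln(n - r1 + 1)
    )
    mask = logp <= log_p_obs + PROB_SLACK
    return float(np.exp(logp[mask]).sum())


def _enumerate_general(row_sums, col_sums, log_p_obs: float) -> float:
    """Recursive exhaustive enumeration for r > 2 rows (small tables)."""
    col_sums = np.asarray(col_sums, dtype=int)
    total_p = 0.0

    def fill_row(rows_left: list[int], cols_rem: np.ndarray, acc_log: float):
        nonlocal total_p
        if len(rows_left) == 1:
            row = cols_rem
            log_row = -special.gammaln(row + 1).sum()
            log_p = acc_log + log_row
            if log_p <= log_p_obs + PROB_SLACK:
                total_p += np.exp(log_p)
            return
        r = rows_left[0]

        def fill_cell(j: int, rem: int, cols: np.ndarray, log_acc: float):
            if j == len(cols) - 1:
                if rem <= cols[j]:
                    new_cols = cols.copy()
                    new_cols[j] -= rem
                    fill_row(
                        rows_left[1:], new_cols,
                        log_acc - special.gammaln(rem + 1),
                    )
                return
            hi = min(rem, cols[j])
            lo = max(0, rem - int(cols[j + 1:].sum()))
            for x in range(lo, hi + 1):
                new_cols = cols.copy()
                new_cols[j] -= x
                fill_cell(j + 1, rem - x, new_cols, log_acc - special.gammaln(x + 1))

        fill_cell(0, r, cols_rem, acc_log)

    n = int(col_sums.sum())
    base = (
        special.gammaln(np.asarray(row_sums) + 1).sum()
        + special.gammaln(col_sums + 1).sum()
        - special.gammaln(n + 1)
    )
    fill_row(list(row_sums), col_sums, float(base))
    return float(total_p)


def fisher_exact(table, seed: int = 0) -> FisherExactResult:
    """Two-sided Fisher's exact test for an r x c contingency table.

    Exhaustive when the margin-based bound on the number of candidate
    tables is below :data:`ENUMERATION_LIMIT`; otherwise Monte Carlo over
    tables drawn with fixed margins (``MC_DRAWS`` draws, seeded), flagged
    in the result's ``method``.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)
    if t.sum() == 0:
        raise ValueError("empty table")
    log_p_obs = _log_table_prob(t)
    if _count_bound(row_sums, col_sums) <= ENUMERATION_LIMIT:
        if t.shape[0] == 2:
            p = _enumerate_two_row(col_sums, int(row_sums[0]), log_p_obs)
        elif t.shape[1] == 2:
            p = _enumerate_two_row(row_sums, int(col_sums[0]), log_p_obs)
        else:
            p = _enumerate_general(row_sums, col_sums, log_p_obs)
        return FisherExactResult(min(p, 1.0), "exact")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_sums, col_sums)
    hits = 0
    block = 100_000
    remaining = MC_DRAWS
    margin_term = float(
        special.gammaln(row_sums + 1).sum()
        + special.gammaln(col_sums + 1).sum()
        - special.gammaln(t.sum() + 1)
    )
    while remaining > 0:
        m = min(block, remaining)
        draws = sampler.rvs(size=m, method="patefield", random_state=rng)
        logp = margin_term - special.gammaln(draws + 1).sum(axis=(1, 2))
        hits += int((logp <= log_p_obs + PROB_SLACK).sum())
        remaining -= m
    # add-one estimate keeps the p-value away from an impossible exact 0
    return FisherExactResult((hits + 1) / (MC_DRAWS + 1), "monte-carlo")


# ---------------------------------------------------------------------------
# Conditional MLE odds ratio for 2 x 2 tables
# ---------------------------------------------------------------------------

def conditional_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio of a 2 x 2 table [[a, b], [c, d]].

    Maximises the Fisher noncentral hypergeometric likelihood of the first
    cell given all margins, i.e. solves E_psi[X] = a for the odds parameter
    psi.  When the observed cell sits on the boundary of its support the
    MLE is the likelihood limit 0 or +inf.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or c + d == 0 or b + d == 0:
        raise ValueError("a table margin is empty; the odds ratio is undefined")
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    if lo == hi:
        raise ValueError("degenerate support: margins determine the table")
    if a == lo:
        return 0.0
    if a == hi:
        return float("inf")

    def mean_minus_a(log_psi: float) -> float:
        return stats.nchypergeom_fisher.mean(n, c1, r1, np.exp(log_psi)) - a

    span = 1.0
    while mean_minus_a(-span) > 0 or mean_minus_a(span) < 0:
        span *= 2.0
        if span > 700:  # pragma: no cover - numerically unreachable for valid input
            raise RuntimeError("failed to bracket the conditional MLE")
    return float(np.exp(optimize.brentq(mean_minus_a, -span, span, xtol=1e-12)))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def rowwise_fate_tests(
    table: FateTable, alpha: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Per-fate 2 x 2 comparisons with Holm-adjusted exact p-values.

    For each fate category the r x c table is collapsed to fate-vs-rest by
    row-factor level (the table must have exactly two levels), tested with
    Fisher's exact test, and summarised by the conditional-MLE odds ratio.
    The family of raw p-values is Holm-Bonferroni adjusted.
    """
    counts = table.counts
    if counts.shape[0] != 2:
        raise ValueError("row-wise fate tests need exactly two row-factor levels")
    fates = [f for f in counts.columns if counts[f].sum() > 0]
    rows = []
    for fate in fates:
        a = int(counts.iloc[0][fate])
        b = int(table.row_totals.iloc[0] - a)
        c = int(counts.iloc[1][fate])
        d = int(table.row_totals.iloc[1] - c)
        res = fisher_exact([[a, b], [c, d]], seed=seed)
        try:
            oratio = conditional_mle_or(a, b, c, d)
        except ValueError:
            oratio = np.nan
        rows.append(
            {
                "fate": fate,
                f"{table.row_factor}_{counts.index[0]}": a,
                f"{table.row_factor}_{counts.index[1]}": c,
                "odds_ratio": oratio,
                "p_raw": res.pvalue,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out
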