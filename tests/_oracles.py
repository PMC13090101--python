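"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own likelihood code paths: the
enumeration below walks every daily outcome path consistent with a censored
record and sums path probabilities directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def path_enumeration_loglik(s_days: list[float], j_offset: int, failed: bool) -> float:
    """Log probability of a censored record by exhaustive path enumeration.

    ``s_days`` holds the true daily survival values for days i..k-1 (length
    k - i); ``j_offset`` = j - i splits them into confirmed-alive days and
    the failure window.  Every binary survive/die assignment over the days
    is enumerated and kept iff consistent with the record: all days before
    j survived; a failed nest dies on exactly one window day (and the path
    ends there); a hatched nest survives everything.
    """
    n = len(s_days)
    # every distinct outcome path: death during day t (having survived all
    # earlier days), or survival of every day
    paths = []  # (death_day or None, probability)
    for t in range(n):
        prob = 1.0
        for u in range(t):
            prob *= s_days[u]
        paths.append((t, prob * (1.0 - s_days[t])))
    prob_all = 1.0
    for u in range(n):
        prob_all *= s_days[u]
    paths.append((None, prob_all))

    total = 0.0
    for death_day, prob in paths:
        if failed:
            consistent = death_day is not None and death_day >= j_offset
        else:
            consistent = death_day is None
        if consistent:
            total += prob
    return math.log(total)


def mayfield_closed_form(alive_days: int, failures: int) -> float:
    """Constant-DSR MLE when every failure day is exactly known."""
    return alive_days / (alive_days + failures)


def hierarchical_subsets(terms: tuple[str, ...], parents: dict) -> set[frozenset]:
    """All subsets of ``terms`` closed under the interaction hierarchy."""
    out = set()
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            s = set(subset)
            if all(
                parents[t][0] in s and parents[t][1] in s
                for t in subset
                if t in parents
            ):
                out.add(frozenset(subset))
    return out


def hypergeom_2x2_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for a 2x2 table by direct hypergeometric sums."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-7))
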