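"""Paired nonparametric testing: Wilcoxon signed-rank with exact p-values.

The twin design yields one (affected, unaffected) count per pair, so the
natural test for a median shift is the Wilcoxon signed-rank test on the
within-pair differences.  Cohorts of ~17 pairs sit squarely in the
small-sample regime, so the null distribution is computed exactly by
enumerating sign assignments whenever feasible.

Conventions: zero differences are dropped (classic Wilcoxon handling;
a Pratt option keeps them in the ranking), ties in |d| receive midranks,
the reported statistic is min(W+, W-), and the exact two-sided p-value
is min(1, 2 * P(W+ <= min(W+, W-))) under the enumeration null.  The
enumeration is evaluated by dynamic programming over doubled midranks
(integerized), which is equivalent to summing over all 2^n sign vectors.
For n above ``exact_limit`` a normal approximation with the tie-robust
variance  Var(W+) = sum(r_i^2)/4  and a 0.5 continuity correction is
used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    p_value: float
    n_effective: int  # nonzero differences used
    w_plus: float
    w_minus: float
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _exact_cdf_leq(ranks2: np.ndarray, w2: int) -> float:
    """P(2*W+ <= w2) where each doubled rank enters W+ with prob 1/2.

    Dynamic programming over the integer distribution of 2*W+; identical
    to enumerating all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * dist + 0.5 * shifted
    w2 = min(w2, total)
    return float(dist[: w2 + 1].sum())


def wilcoxon_signed_rank(
    differences: Sequence[float],
    zero_method: str = "wilcox",
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Parameters
    ----------
    differences
        Within-pair differences (affected - unaffected); at least one.
    zero_method
        ``"wilcox"`` drops zero differences before ranking (default);
        ``"pratt"`` ranks zeros with everything else, then drops their
        rank contribution.
    exact_limit
        Largest number of nonzero differences for which the exact
        enumeration null is used; beyond it, normal approximation.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size < 1:
        raise ValueError("need at least one paired difference")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")

    if zero_method == "wilcox":
        nz = d[d != 0]
        ranks = rankdata(np.abs(nz)) if nz.size else np.array([])
    else:
        nz = d[d != 0]
        all_ranks = rankdata(np.abs(d))
        ranks = all_ranks[d != 0]

    n_eff = int(nz.size)
    if n_eff == 0:
        return WilcoxonResult(0.0, 1.0, 0, 0.0, 0.0, "degenerate")

    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    stat = min(w_plus, w_minus)

    if n_eff <= exact_limit:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        p = min(1.0, 2.0 * _exact_cdf_leq(ranks2, int(round(2 * stat))))
        method = "exact"
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        # continuity-corrected two-sided normal approximation
        z = (stat - mu + 0.5) / sigma
        p = min(1.0, 2.0 * norm.cdf(z))
        method = "normal"
    return WilcoxonResult(stat, float(p), n_eff, w_plus, w_minus, method)
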