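"""Directional rank-based signature correlation (the "running Fisher" test).

A signed query signature (biomarker) is compared against a target bioset
ranked by |fold-change|.  For each of the four (query-sign, target-sign)
pairs, the target ranking is restricted to genes of that sign and scanned:
at every rank cutoff where a query gene occurs the hypergeometric upper
tail of the overlap is evaluated, the minimum tail probability is
Bonferroni-corrected by the number of cutoffs scanned, and the two
concordant (up/up, down/down) and two discordant (up/down, down/up) pair
p-values are compared.  The winning side's two p-values are combined by
Fisher's method (chi-square, 4 df), giving a correlation direction, a
p-value, and a signed score direction x -log10(p).

The exact-test kernel works in log space, so tails of order 1e-300 are
still meaningful; the final p is clamped to the smallest positive double.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .core_io import Biomarker, Bioset, RunningFisherResult

#: Number of genes assayable on the reference mouse platform; used as the
#: hypergeometric population size unless overridden.
DEFAULT_UNIVERSE = 23238

_TINY = 1e-320  # keeps p in (0, 1] after Fisher combination underflow


@dataclass(frozen=True)
class RfParams:
    """Parameters of the running Fisher comparison.

    universe_size
        Population size N of the hypergeometric tests (platform gene count).
    platform_genes
        Optional gene universe of the target platform.  When given, query
        genes absent from it are removed before testing (reducing the
        effective query-set size); otherwise the full query size is used,
        which is conservative.
    """

    universe_size: int = DEFAULT_UNIVERSE
    platform_genes: frozenset[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")


def hypergeom_upper_tail(k: int, K: int, c: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, c), summed in log space.

    N is the population size, K the number of marked items (query-set
    size), c the draw size (rank cutoff), k the observed overlap.
    """
    if not (0 <= k <= min(K, c) and 0 <= K <= N and 0 <= c <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, c={c}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, c) + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(c - i + 1) - gammaln(N - K - (c - i) + 1)
        - (gammaln(N + 1) - gammaln(c + 1) - gammaln(N - c + 1))
    )
    return float(min(1.0, math.exp(logsumexp(logpmf))))


def rank_target(bioset: Bioset) -> list[tuple[str, int]]:
    """Order the target genes by |fold-change| descending, ties broken by
    gene_id ascending; returns (gene_id, sign) pairs."""
    return [
        (e.gene_id, 1 if e.fold_change > 0 else -1)
        for e in sorted(bioset.entries, key=lambda e: (-abs(e.fold_change), e.gene_id))
    ]


def directional_pair_p(
    query_set: frozenset[str] | set[str],
    target_ranked: list[tuple[str, int]],
    target_sign: int,
    params: RfParams,
) -> tuple[float, int]:
    """One (query-sign, target-sign) pair of the running scan.

    The ranked target is restricted to genes of ``target_sign`` (rank order
    preserved) and the hypergeometric upper tail is evaluated at each rank
    where a query gene occurs — the only positions where the tail can
    attain a local minimum — plus the full sub-list length.  The minimum
    tail is Bonferroni-corrected by the number of cutoffs scanned and
    capped at 1.

    Returns (p, overlap at the best cutoff); (1.0, 0) when the overlap is
    empty or the query is empty.
    """
    if not query_set:
        return 1.0, 0
    sub = [g for g, s in target_ranked if s == target_sign]
    positions = [i + 1 for i, g in enumerate(sub) if g in query_set]
    if not positions:
        return 1.0, 0
    cutoffs = sorted(set(positions) | {len(sub)})
    K, N = len(query_set), params.universe_size
    if N < len(sub) or N < K:
        raise ValueError("universe smaller than target or query set")
    best_p, best_k = 1.0, 0
    for c in cutoffs:
        k = bisect_right(positions, c)
        tail = hypergeom_upper_tail(k, K, c, N)
        if tail < best_p:
            best_p, best_k = tail, k
    return min(1.0, best_p * len(cutoffs)), best_k


def _fisher_combine(p1: float, p2: float) -> float:
    stat = -2.0 * (math.log(max(p1, _TINY)) + math.log(max(p2, _TINY)))
    return max(float(chi2.sf(stat, df=4)), _TINY)


def running_fisher(
    query: Biomarker, target: Bioset, params: RfParams | None = None
) -> RunningFisherResult:
    """Compare a biomarker to a bioset; see the module docstring for the
    construction.  Direction is 0 (and the call downstream is no-call)
    when concordant and discordant evidence tie, including the no-overlap
    case where p = 1."""
    params = params or RfParams()
    ranked = rank_target(target)

    q_up: set[str] = set(query.up_genes)
    q_down: set[str] = set(query.down_genes)
    if params.platform_genes is not None:
        q_up &= params.platform_genes
        q_down &= params.platform_genes

    p_uu, k_uu = directional_pair_p(q_up, ranked, +1, params)
    p_dd, k_dd = directional_pair_p(q_down, ranked, -1, params)
    p_ud, k_ud = directional_pair_p(q_up, ranked, -1, params)
    p_du, k_du = directional_pair_p(q_down, ranked, +1, params)

    score_conc = -(math.log10(p_uu) + math.log10(p_dd))
    score_disc = -(math.log10(p_ud) + math.log10(p_du))

    if score_conc > score_disc:
        direction = 1
    elif score_conc < score_disc:
        direction = -1
    else:
        direction = 0

    # On a tie the two sides have equal Fisher statistics, so either pair
    # yields the same combined p; use the concordant side.
    if direction >= 0:
        p_value = _fisher_combine(p_uu, p_dd)
    else:
        p_value = _fisher_combine(p_ud, p_du)

    signed_score = direction * -math.log10(p_value) + 0.0  # avoid -0.0
    return RunningFisherResult(
        direction=direction,
        p_value=p_value,
        signed_score=signed_score,
        overlap_concordant=k_uu + k_dd,
        overlap_discordant=k_ud + k_du,
        per_pair_p={
            ("+", "+"): p_uu,
            ("-", "-"): p_dd,
            ("+", "-"): p_ud,
            ("-", "+"): p_du,
        },
    )
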