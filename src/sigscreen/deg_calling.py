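"""Differential expression: one-way ANOVA with Benjamini-Hochberg FDR and a
fold-change floor, turning an expression matrix into a bioset.

ANOVA is run on log2-transformed intensities; the reported fold-change is
the signed ratio of linear-scale group means (>= 1 up, down-regulation as
-(b/a)).  BH is applied across all genes on the matrix first and the
fold-change floor second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .core_io import Annotation, Bioset, BiosetEntry, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegParams:
    fdr_threshold: float = 0.01
    fc_threshold: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1")


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA over >= 2 groups of >= 2 values each.

    Returns (F, p) with F on (k-1, N-k) degrees of freedom.  When both the
    between- and within-group variances are zero the test is undefined and
    (0, 1) is returned by convention (logged).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise ValueError("insufficient replicates: within-group df < 1")
    if ss_within == 0.0:
        if ss_between == 0.0:
            log.info("degenerate ANOVA input (all values identical): p = 1 by convention")
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(f_dist.sf(F, df_b, df_w))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _two_group_f_vectorised(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row two-group ANOVA F and p for genes x samples blocks a, b."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma[:, None]) ** 2).sum(axis=1) + ((b - mb[:, None]) ** 2).sum(axis=1)
    df_w = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / 1.0) / (ssw / df_w)
    p = f_dist.sf(F, 1, df_w)
    degenerate = (ssw == 0.0) & (ssb == 0.0)
    if degenerate.any():
        log.info("%d genes with zero variance everywhere: p = 1 by convention", degenerate.sum())
        F = np.where(degenerate, 0.0, F)
        p = np.where(degenerate, 1.0, p)
    exact = (ssw == 0.0) & (ssb > 0.0)
    p = np.where(exact, 0.0, p)
    return F, p


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    params: DegParams | None = None,
    bioset_id: str = "degs",
    annotations: Annotation | None = None,
) -> Bioset:
    """Two-group DEG call: per-gene ANOVA on log2 intensities, BH across all
    genes, then keep genes with adjusted p <= fdr_threshold and
    |signed fold-change| >= fc_threshold.  Positive fold-change means the
    group_a mean exceeds the group_b mean.

    Raises ValueError("... no entries") when nothing survives, matching the
    bioset invariant that a statistically filtered list is non-empty.
    """
    params = params or DegParams()
    values = np.asarray(matrix.values, dtype=float)
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    log_v = np.log2(values)
    _, p = _two_group_f_vectorised(log_v[:, cols_a], log_v[:, cols_b])
    adj = benjamini_hochberg(p)

    mean_a = values[:, cols_a].mean(axis=1)
    mean_b = values[:, cols_b].mean(axis=1)
    ratio = mean_a / mean_b
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    keep = (adj <= params.fdr_threshold) & (np.abs(fc) >= params.fc_threshold)
    log.info(
        "call_degs %s vs %s: %d/%d genes pass FDR <= %g and |FC| >= %g",
        group_a, group_b, int(keep.sum()), len(matrix.gene_ids),
        params.fdr_threshold, params.fc_threshold,
    )
    entries = tuple(
        BiosetEntry(matrix.gene_ids[i], float(fc[i]), float(adj[i]))
        for i in np.flatnonzero(keep)
    )
    if not entries:
        raise ValueError(f"bioset {bioset_id!r}: no entries")
    return Bioset(
        bioset_id=bioset_id,
        entries=entries,
        annotations=annotations or Annotation(),
        fc_threshold=params.fc_threshold,
    )
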