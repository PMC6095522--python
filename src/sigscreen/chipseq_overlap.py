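"""Peak-to-gene assignment by summit-to-TSS distance and biomarker
enrichment among peak-proximal genes (Yates-corrected chi-square).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import namedtuple
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .core_io import Biomarker, GeneAnnotation, Peak, PeakSet

log = logging.getLogger(__name__)


def nearest_gene(peaks: PeakSet, genes: GeneAnnotation) -> list[tuple[Peak, str]]:
    """Assign each peak to the gene whose TSS is nearest its summit on the
    same chromosome (unsigned base-pair distance; ties broken by gene_id
    ascending).  Peaks on chromosomes without genes are dropped and the
    count logged."""
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes.genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()

    out: list[tuple[Peak, str]] = []
    dropped = 0
    for p in peaks.peaks:
        lst = by_chrom.get(p.chrom)
        if lst is None:
            dropped += 1
            continue
        positions = [t for t, _ in lst]
        i = bisect_left(positions, p.summit)
        candidates = []
        if i < len(lst):
            candidates.append(lst[i])
        if i > 0:
            candidates.append(lst[i - 1])
        best = min(candidates, key=lambda tg: (abs(tg[0] - p.summit), tg[1]))
        # equidistant TSSs elsewhere in the sorted list can only occur at
        # these two neighbours, but multiple genes may share the same TSS
        best_d = abs(best[0] - p.summit)
        tied = [g for t, g in lst if abs(t - p.summit) == best_d]
        out.append((p, min(tied)))
    if dropped:
        log.info("nearest_gene: dropped %d peaks on chromosomes without genes", dropped)
    return out


def collate_chip_genes(gene_sets: Sequence[Iterable[str]]) -> frozenset[str]:
    """Union of per-study peak-proximal gene sets."""
    if not gene_sets:
        raise ValueError("need at least one gene set")
    out: set[str] = set()
    for s in gene_sets:
        out |= set(s)
    return frozenset(out)


def yates_chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    chi2 = N (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)); the
    correction term is clamped so it never exceeds |ad - bc|.  p is the
    upper tail of chi-square with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    (a, b), (c, d) = t
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin in 2x2 table")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num ** 2 / margins
    return float(stat), float(chi2.sf(stat, df=1))


EnrichmentResult = namedtuple("EnrichmentResult", "n_overlap fraction chi2 p")


def biomarker_chip_enrichment(
    biomarker: Biomarker, chip_genes: frozenset[str] | set[str], universe: frozenset[str] | set[str]
) -> EnrichmentResult:
    """Enrichment of biomarker genes among peak-proximal genes.

    The 2x2 table partitions the universe into biomarker/non-biomarker x
    chip/non-chip; the fraction is the percentage of biomarker genes near
    peaks, to one decimal.
    """
    bm = set(biomarker.genes)
    chip = set(chip_genes)
    uni = set(universe)
    if not bm <= uni:
        raise ValueError("biomarker genes must be a subset of the universe")
    if not chip <= uni:
        raise ValueError("chip genes must be a subset of the universe")
    a = len(bm & chip)
    b = len(bm - chip)
    c = len(chip - bm)
    d = len(uni - bm - chip)
    stat, p = yates_chi_square([[a, b], [c, d]])
    return EnrichmentResult(
        n_overlap=a,
        fraction=round(100.0 * a / len(bm), 1),
        chi2=stat,
        p=p,
    )
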