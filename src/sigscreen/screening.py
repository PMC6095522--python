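"""Compendium screening: run a set of biomarkers against a set of biosets,
call activation/suppression, and evaluate classifier performance.

A bioset is called *activated* for a biomarker when the running Fisher
comparison has direction +1 and p <= alpha (default 1e-4), *suppressed*
for direction -1, and *no-call* otherwise.  Across a compendium an
additional Benjamini-Hochberg stage at alpha = 0.001 is applied to each
biomarker's p-value column, and both the raw-p rule and the BH stage must
agree before a call is made (the BH stage can be disabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import Biomarker, BiomarkerCall, Bioset, RunningFisherResult, ScreenRecord
from .deg_calling import benjamini_hochberg
from .running_fisher import RfParams, running_fisher

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierParams:
    alpha: float = 1e-4
    compendium_fdr_alpha: float = 0.001
    apply_compendium_fdr: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def classify(result: RunningFisherResult, params: ClassifierParams | None = None) -> str:
    """Activation call from a single comparison: activated iff direction +1
    and p <= alpha; suppressed iff direction -1 and p <= alpha; else no-call."""
    params = params or ClassifierParams()
    if result.p_value <= params.alpha:
        if result.direction == 1:
            return "activated"
        if result.direction == -1:
            return "suppressed"
    return "no-call"


def screen_compendium(
    biomarkers: Sequence[Biomarker],
    biosets: Sequence[Bioset],
    params: ClassifierParams | None = None,
    rf_params: RfParams | None = None,
) -> list[ScreenRecord]:
    """One master-table record per bioset with per-biomarker signed score,
    p-value and call.  With ``apply_compendium_fdr`` (the default), calls
    additionally require the biomarker's BH-adjusted p-column to pass
    ``compendium_fdr_alpha``; both stages are logged."""
    params = params or ClassifierParams()
    if not biomarkers or not biosets:
        raise ValueError("need at least one biomarker and one bioset")
    ids = [b.bioset_id for b in biosets]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate bioset_ids in compendium")

    results = {
        bm.name: [running_fisher(bm, bs, rf_params) for bs in biosets] for bm in biomarkers
    }
    calls_per_bm: dict[str, list[BiomarkerCall]] = {}
    for bm in biomarkers:
        res = results[bm.name]
        raw_calls = [classify(r, params) for r in res]
        if params.apply_compendium_fdr:
            adj = benjamini_hochberg([r.p_value for r in res])
            passed = adj <= params.compendium_fdr_alpha
            final = [c if ok else "no-call" for c, ok in zip(raw_calls, passed)]
            demoted = sum(1 for c, f in zip(raw_calls, final) if c != f)
            log.info(
                "screen %s: %d/%d raw calls at p <= %g; %d demoted by compendium BH at %g",
                bm.name, sum(c != "no-call" for c in raw_calls), len(res),
                params.alpha, demoted, params.compendium_fdr_alpha,
            )
        else:
            final = raw_calls
            log.info(
                "screen %s: %d/%d calls at p <= %g (no compendium BH)",
                bm.name, sum(c != "no-call" for c in raw_calls), len(res), params.alpha,
            )
        calls_per_bm[bm.name] = [
            BiomarkerCall(r.signed_score, r.p_value, c) for r, c in zip(res, final)
        ]

    return [
        ScreenRecord(
            bioset_id=bs.bioset_id,
            annotation=bs.annotations,
            calls={bm.name: calls_per_bm[bm.name][i] for bm in biomarkers},
        )
        for i, bs in enumerate(biosets)
    ]


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and rates (percentages) of the activation classifier.

    ``no-call`` and ``suppressed`` predictions both count as negative when
    the truth labels are binary positive/negative activation status.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def rounded(self) -> tuple[int, int, int]:
        """(sensitivity, specificity, balanced accuracy) to the nearest whole percent."""
        return (
            round(self.sensitivity),
            round(self.specificity),
            round(self.balanced_accuracy),
        )


def evaluate(
    calls: Sequence[str],
    truth: Sequence[str],
    positive_call: str = "activated",
) -> PerformanceReport:
    """Score calls against binary truth labels ('positive'/'negative')."""
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    if any(t not in ("positive", "negative") for t in truth):
        raise ValueError("truth labels must be 'positive' or 'negative'")
    tp = fn = tn = fp = 0
    for c, t in zip(calls, truth):
        predicted_positive = c == positive_call
        if t == "positive":
            tp += predicted_positive
            fn += not predicted_positive
        else:
            fp += predicted_positive
            tn += not predicted_positive
    return PerformanceReport(tp=tp, fn=fn, tn=tn, fp=fp)


def count_biomarker_genes_altered(biomarker: Biomarker, bioset: Bioset, sign: int) -> int:
    """Number of biomarker genes of the given sign present in the bioset with
    the same sign of change (the per-bioset biomarker-response count)."""
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    bm_genes = biomarker.up_genes if sign == 1 else biomarker.down_genes
    target = bioset.gene_signs
    return sum(1 for g in bm_genes if target.get(g) == sign)
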