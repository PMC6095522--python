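"""Biomarker derivation from activation and knockout biosets.

A probe enters the biomarker when it is (1) present in at least
``min_support`` of the activation biosets, (2) always with the same sign,
(3) with |average fold-change| over the biosets where present >= 1.5.
Probe-to-gene grouping then removes (4) genes whose surviving probes
disagree in direction, (5) genes that are also altered in the same
direction in the knockout exclusion bioset (a knockout that still shows
the response cannot depend on the factor), and (6) genes claimed by other
factors' biomarkers.  Absence from a list is neutral evidence, never a
contradiction, and the average fold-change is taken over the biosets where
the probe is present.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import Biomarker, BiomarkerEntry, Bioset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuilderParams:
    activation_biosets: tuple[Bioset, ...]
    probe_to_gene: Mapping[str, str]
    exclusion_bioset: Bioset | None = None
    excluded_gene_sets: tuple[frozenset[str], ...] = field(default_factory=tuple)
    min_support: int = 3
    min_avg_fc: float = 1.5

    def __post_init__(self) -> None:
        if len(self.activation_biosets) < 2:
            raise ValueError("need at least 2 activation biosets")
        if not (1 <= self.min_support <= len(self.activation_biosets)):
            raise ValueError("min_support must be between 1 and the number of activation biosets")
        if self.min_avg_fc < 1.0:
            raise ValueError("min_avg_fc must be >= 1")


def _gene_of(entry_id: str, probe_to_gene: Mapping[str, str]) -> str:
    # exclusion biosets may already be keyed by gene symbol
    return probe_to_gene.get(entry_id, entry_id)


def build_biomarker(params: BuilderParams, name: str) -> Biomarker:
    """Apply the six selection criteria; see the module docstring.

    Criteria 1-3 are evaluated per probe, then 4 (within-gene sign
    agreement), 5 (knockout exclusion, gene-level, same direction only)
    and 6 (cross-biomarker exclusion) in that order.
    """
    # precondition: the map covers every probe in the activation biosets
    for bs in params.activation_biosets:
        for e in bs.entries:
            if e.gene_id not in params.probe_to_gene:
                raise ValueError(f"probe {e.gene_id!r} missing from probe_to_gene")

    occurrences: dict[str, list[float]] = {}
    for bs in params.activation_biosets:
        for e in bs.entries:
            occurrences.setdefault(e.gene_id, []).append(e.fold_change)

    survivors: dict[str, float] = {}
    n_c1 = n_c2 = n_c3 = 0
    for probe, fcs in occurrences.items():
        if len(fcs) < params.min_support:  # criterion 1
            n_c1 += 1
            continue
        if not (all(f > 0 for f in fcs) or all(f < 0 for f in fcs)):  # criterion 2
            n_c2 += 1
            continue
        avg = sum(fcs) / len(fcs)
        if abs(avg) < params.min_avg_fc:  # criterion 3
            n_c3 += 1
            continue
        survivors[probe] = avg

    # criterion 4: genes whose probes disagree in sign are removed entirely
    gene_signs: dict[str, set[int]] = {}
    for probe, avg in survivors.items():
        gene_signs.setdefault(params.probe_to_gene[probe], set()).add(1 if avg > 0 else -1)
    conflicted = {g for g, signs in gene_signs.items() if len(signs) > 1}

    # criterion 5: same-direction presence in the knockout bioset excludes
    ko_signs: dict[str, int] = {}
    if params.exclusion_bioset is not None:
        for e in params.exclusion_bioset.entries:
            ko_signs[_gene_of(e.gene_id, params.probe_to_gene)] = 1 if e.fold_change > 0 else -1

    # criterion 6
    foreign = frozenset().union(*params.excluded_gene_sets) if params.excluded_gene_sets else frozenset()

    entries = []
    n_c4 = n_c5 = n_c6 = 0
    for probe in sorted(survivors):
        avg = survivors[probe]
        gene = params.probe_to_gene[probe]
        if gene in conflicted:
            n_c4 += 1
            continue
        if ko_signs.get(gene) == (1 if avg > 0 else -1):
            n_c5 += 1
            continue
        if gene in foreign:
            n_c6 += 1
            continue
        entries.append(BiomarkerEntry(probe, gene, avg))

    log.info(
        "build_biomarker %s: %d candidate probes; removed %d (support), %d (sign "
        "consistency), %d (avg FC), %d (within-gene conflict), %d (knockout), "
        "%d (other biomarkers); %d retained",
        name, len(occurrences), n_c1, n_c2, n_c3, n_c4, n_c5, n_c6, len(entries),
    )
    if not entries:
        raise ValueError("no biomarker probes survive")
    return Biomarker(
        name=name,
        entries=tuple(entries),
        derived_from=tuple(bs.bioset_id for bs in params.activation_biosets),
    )


BiomarkerSummary = namedtuple("BiomarkerSummary", "n_probes n_up n_down n_genes")


def summarize_biomarker(b: Biomarker) -> BiomarkerSummary:
    """Counts of probes by direction and of distinct genes."""
    n_up = sum(1 for e in b.entries if e.avg_fold_change > 0)
    return BiomarkerSummary(
        n_probes=len(b.entries),
        n_up=n_up,
        n_down=len(b.entries) - n_up,
        n_genes=len({e.gene_id for e in b.entries}),
    )
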