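"""Seeded generators for every input the screen consumes.

These emulate the statistical structure the analysis assumes: 4-group
genotype x treatment expression experiments with factor-dependent
responder genes, biosets with tunable sign-concordant biomarker enrichment
near the top of the |fold-change| ranking, compendia whose biosets carry
correlated latent activities for two biomarkers, and peak/TSS files with a
designated fraction of target genes nearest to peaks.  All generators are
pure functions of their arguments and a seed: identical inputs give
bit-identical outputs.

The noise model for expression is log-normal (normal on the log2 scale),
the standard microarray error model.  Bioset |fold-changes| follow a
shifted exponential above the upload floor 1.2; concordant biomarker
genes draw their |fold-change| from the top quartile of the bioset's
distribution so the running scan sees signal near the top of the ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (
    Annotation,
    Biomarker,
    BiomarkerEntry,
    Bioset,
    BiosetEntry,
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    Peak,
    PeakSet,
)

GROUPS = ("WT-ctl", "WT-trt", "KO-ctl", "KO-trt")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    responder_effect is the log2 mean shift of responder genes in treated
    wild-type samples; noise_sd is the log2-scale replicate noise.
    Defaults mirror a 4-replicate, 4-group microarray design with a
    20,000-gene platform.
    """

    seed: int = 0
    n_genes: int = 20000
    n_per_group: int = 4
    responder_effect: float = 1.5
    noise_sd: float = 0.25
    concordance: float = 0.8
    latent_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.concordance <= 1.0):
            raise ValueError("concordance must lie in [0, 1]")
        if not (-1.0 <= self.latent_correlation <= 1.0):
            raise ValueError("latent_correlation must lie in [-1, 1]")


def _sorted_unique(universe: Sequence[str]) -> list[str]:
    """Normalise a gene universe; cheap no-op when already sorted and unique."""
    u = list(universe)
    if all(u[i] < u[i + 1] for i in range(len(u) - 1)):
        return u
    return sorted(set(u))


def gene_universe(n_genes: int, include: Sequence[str] = ()) -> list[str]:
    """A sorted gene universe of size n_genes containing the given genes
    plus synthetic ids (g00001, ...)."""
    extra = [f"g{i:05d}" for i in range(1, n_genes - len(include) + 1)]
    universe = sorted(set(include) | set(extra))
    if len(universe) != n_genes:
        raise ValueError("include list contains duplicates or exceeds n_genes")
    return universe


def simulate_genotype_experiment(
    cfg: SimulationConfig, responders: Sequence[tuple[str, int]]
) -> ExpressionMatrix:
    """A 4-group (wild-type/knockout x control/treated) experiment.

    Responder genes are shifted by sign x responder_effect (log2) in the
    treated wild-type group only; every other gene x group effect is zero,
    so the knockout contrast is null by construction.  Intensities are
    log-normal with per-gene baselines uniform on log2 in [6, 12].
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for g, s in responders:
        if g not in index:
            raise ValueError(f"responder gene {g!r} not in the simulated universe")
        if s not in (1, -1):
            raise ValueError(f"responder sign for {g!r} must be +1 or -1")

    n_samples = cfg.n_per_group * len(GROUPS)
    baseline = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    log2 = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    trt_cols = slice(cfg.n_per_group, 2 * cfg.n_per_group)  # WT-trt block
    for g, s in responders:
        log2[index[g], trt_cols] += s * cfg.responder_effect

    sample_ids = tuple(f"{grp}_{j + 1}" for grp in GROUPS for j in range(cfg.n_per_group))
    groups = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    return ExpressionMatrix(
        gene_ids=tuple(genes),
        sample_ids=sample_ids,
        values=np.exp2(log2),
        groups=groups,
    )


def _structured_bioset(
    rng: np.random.Generator,
    structure: Sequence[tuple[Biomarker, float]],
    n_entries: int,
    universe: Sequence[str],
    bioset_id: str,
    annotations: Annotation | None,
    fc_threshold: float = 1.2,
    fc_scale: float = 0.6,
) -> Bioset:
    """Shared generator: each (biomarker, signed concordance sc) plants
    round(|sc| x biomarker gene count) biomarker genes with sign equal to
    the biomarker sign (times -1 when sc < 0) and |FC| from the top
    quartile; the remaining entries are non-biomarker genes with random
    signs and shifted-exponential |FC|."""
    universe_sorted = _sorted_unique(universe)
    excluded: set[str] = set()
    chosen: list[tuple[str, int]] = []
    for bm, sc in structure:
        excluded |= bm.genes
        genes = sorted(bm.genes)
        n_c = round(abs(sc) * len(genes))
        idx = rng.choice(len(genes), size=n_c, replace=False) if n_c else np.array([], dtype=int)
        flip = 1 if sc >= 0 else -1
        up = bm.up_genes
        chosen.extend(
            (genes[i], (1 if genes[i] in up else -1) * flip) for i in sorted(idx)
        )
    pool = [g for g in universe_sorted if g not in excluded]
    n_fill = n_entries - len(chosen)
    if n_fill < 0:
        raise ValueError("n_entries too small for the requested concordance structure")
    if n_fill > len(pool):
        raise ValueError("universe too small for the requested bioset size")
    fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
    fill = [(pool[i], int(s)) for i, s in zip(fill_idx, rng.choice((-1, 1), size=n_fill))]

    abs_fc = np.sort(fc_threshold + rng.exponential(scale=fc_scale, size=n_entries))[::-1]
    top_q = max(len(chosen), math.ceil(n_entries / 4))
    top_positions = (
        rng.choice(top_q, size=len(chosen), replace=False)
        if chosen
        else np.array([], dtype=int)
    )
    slots: list[tuple[str, int] | None] = [None] * n_entries
    for pos, gene_sign in zip(top_positions, chosen):
        slots[int(pos)] = gene_sign
    it = iter(fill)
    for i in range(n_entries):
        if slots[i] is None:
            slots[i] = next(it)
    entries = tuple(
        BiosetEntry(g, s * float(abs_fc[i])) for i, (g, s) in enumerate(slots)  # type: ignore[misc]
    )
    return Bioset(
        bioset_id=bioset_id,
        entries=entries,
        annotations=annotations or Annotation(),
        fc_threshold=fc_threshold,
    )


def simulate_bioset(
    biomarker: Biomarker,
    concordance: float,
    n_entries: int,
    universe: Sequence[str],
    seed: int,
    bioset_id: str | None = None,
    annotations: Annotation | None = None,
) -> Bioset:
    """A bioset with a tunable fraction of sign-concordant biomarker genes
    near the top of the |FC| ranking; concordance 0 excludes every
    biomarker gene (the fill never draws from the biomarker)."""
    if not (0.0 <= concordance <= 1.0):
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return _structured_bioset(
        rng,
        [(biomarker, concordance)],
        n_entries,
        universe,
        bioset_id or f"sim-{biomarker.name}-c{concordance:g}-s{seed}",
        annotations,
    )


def simulate_null_bioset(
    universe: Sequence[str],
    n_entries: int,
    seed: int,
    bioset_id: str | None = None,
    annotations: Annotation | None = None,
) -> Bioset:
    """A null bioset: genes sampled uniformly from the universe with random
    signs and shifted-exponential |FC|, independent of any biomarker."""
    rng = np.random.default_rng(seed)
    universe_sorted = _sorted_unique(universe)
    if n_entries > len(universe_sorted):
        raise ValueError("n_entries exceeds the universe size")
    idx = rng.choice(len(universe_sorted), size=n_entries, replace=False)
    signs = rng.choice((-1, 1), size=n_entries)
    abs_fc = 1.2 + rng.exponential(scale=0.6, size=n_entries)
    entries = tuple(
        BiosetEntry(universe_sorted[i], int(s) * float(f))
        for i, s, f in zip(idx, signs, abs_fc)
    )
    return Bioset(
        bioset_id=bioset_id or f"null-s{seed}",
        entries=entries,
        annotations=annotations or Annotation(),
    )


def simulate_compendium(
    cfg: SimulationConfig,
    biomarker_a: Biomarker,
    biomarker_b: Biomarker,
    n_biosets: int,
    n_entries: int = 300,
    universe: Sequence[str] | None = None,
) -> list[tuple[Bioset, float, float]]:
    """Biosets whose latent activities for two gene-disjoint biomarkers are
    drawn from a standard bivariate normal with correlation
    cfg.latent_correlation.  Each latent maps monotonically to a signed
    concordance (clip(latent / 2, -1, 1)); negative latents plant the
    biomarker genes with flipped signs.  Returns (bioset, latent_a,
    latent_b) triples so recovery can be tested against the truth."""
    if biomarker_a.genes & biomarker_b.genes:
        raise ValueError("biomarkers must be gene-disjoint")
    if n_biosets < 1:
        raise ValueError("n_biosets must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.latent_correlation
    latents = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_biosets
    )
    if universe is None:
        universe = gene_universe(
            cfg.n_genes, include=sorted(biomarker_a.genes | biomarker_b.genes)
        )
    out = []
    for i, (la, lb) in enumerate(latents):
        sc_a = float(np.clip(la / 2.0, -1.0, 1.0))
        sc_b = float(np.clip(lb / 2.0, -1.0, 1.0))
        bs = _structured_bioset(
            rng,
            [(biomarker_a, sc_a), (biomarker_b, sc_b)],
            n_entries,
            universe,
            f"compendium-{i:04d}",
            None,
        )
        out.append((bs, float(la), float(lb)))
    return out


def simulate_gene_annotation(
    n_genes: int, chroms: Sequence[str] = ("chr1", "chr2"), spacing: int = 10000
) -> GeneAnnotation:
    """Evenly spaced genes with unique TSS positions, alternating strand."""
    genes = []
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        per_chrom[chrom] += 1
        tss = spacing * per_chrom[chrom]
        genes.append(GeneRecord(f"g{i + 1:05d}", chrom, tss, "+" if i % 2 == 0 else "-"))
    return GeneAnnotation(tuple(genes))


def simulate_peaks(
    genes: GeneAnnotation,
    target_genes: Sequence[str],
    frac_near: float,
    seed: int,
    half_width: int = 100,
) -> PeakSet:
    """One peak per target gene: round(frac_near x n_targets) peaks have
    their summit exactly at the target's TSS (hence nearer it than any
    other TSS), and the rest sit at the TSS of a non-target gene."""
    if not (0.0 <= frac_near <= 1.0):
        raise ValueError("frac_near must lie in [0, 1]")
    by_id = {g.gene_id: g for g in genes.genes}
    targets = sorted(target_genes)
    missing = [t for t in targets if t not in by_id]
    if missing:
        raise ValueError(f"target genes not in annotation: {missing}")
    per_chrom: dict[str, set[int]] = {}
    for g in genes.genes:
        tss_set = per_chrom.setdefault(g.chrom, set())
        if g.tss in tss_set:
            raise ValueError("annotation has duplicate TSS positions on one chromosome")
        tss_set.add(g.tss)

    rng = np.random.default_rng(seed)
    n_near = round(frac_near * len(targets))
    near_idx = set(
        int(i) for i in rng.choice(len(targets), size=n_near, replace=False)
    )
    non_targets = sorted(set(by_id) - set(targets))
    n_far = len(targets) - n_near
    if n_far > len(non_targets):
        raise ValueError("not enough non-target genes for the far peaks")
    far_genes = [
        non_targets[int(i)] for i in rng.choice(len(non_targets), size=n_far, replace=False)
    ]
    peaks = []
    far_it = iter(far_genes)
    for i, t in enumerate(targets):
        g = by_id[t] if i in near_idx else by_id[next(far_it)]
        w = min(half_width, g.tss)
        peaks.append(Peak(g.chrom, g.tss - w, g.tss + w))
    return PeakSet(tuple(peaks))


def make_biomarker(
    name: str, n_up: int, n_down: int, seed: int, gene_prefix: str | None = None
) -> Biomarker:
    """A synthetic biomarker with the given up/down composition; average
    fold-changes are 1.5 + exponential draws (negated for the down set)."""
    rng = np.random.default_rng(seed)
    prefix = gene_prefix or name
    entries = []
    for i in range(n_up + n_down):
        fc = 1.5 + float(rng.exponential(scale=1.0))
        if i >= n_up:
            fc = -fc
        gene = f"{prefix}-gene{i + 1:03d}"
        entries.append(BiomarkerEntry(f"{prefix}-probe{i + 1:03d}", gene, fc))
    return Biomarker(name=name, entries=tuple(entries))
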