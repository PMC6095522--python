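# Methods

## The screening model

The pipeline treats a transcription factor's activation signature as a fixed
signed gene set (the biomarker) and every experimental comparison as a
bioset: a statistically filtered gene list with signed fold-changes on the
microarray convention (|FC| ≥ 1 always; down-regulation stored as
−control/treated). The screen asks whether the biomarker genes sit unusually
high in a bioset's |FC| ranking with matching (activation) or opposing
(suppression) signs.

### Running Fisher comparison

For query sign q ∈ {up, down} and target sign t ∈ {+, −}, the target ranking
is restricted to genes of sign t, preserving order. The hypergeometric upper
tail P(X ≥ k | N, K, c) is evaluated at each rank cutoff c where a query
gene occurs — the only positions where the tail can reach a local minimum —
plus the full sub-list length; the minimum is multiplied by the number of
cutoffs scanned (Bonferroni) and capped at 1. K is the query-set size, N the
platform universe. The two concordant pairs and two discordant pairs are
compared by summed −log₁₀ p; the winning side's p-values are combined by
Fisher's method (χ² with 4 df). Direction is the sign of the difference in
side scores, 0 on an exact tie (including the no-overlap case, where p = 1).

This is a deterministic, defensible variant of the commercial rank-based
signature-correlation statistic: the published interface (a correlation
direction plus a p-value per comparison) is reproduced, but the proprietary
engine's exact numerics are not recoverable, and bit-compatibility is a
non-goal. Choices fixed here: the query is an unordered signed set (only the
target is rank-scanned); ties in |FC| break by gene id ascending; query
genes absent from the target platform reduce K only when a platform gene
list is supplied, otherwise the full K is used (conservative). Underflow in
the Fisher combination is clamped at 10⁻³²⁰ so p stays in (0, 1].

The construction is exactly antisymmetric in two senses, both tested: a
global sign flip of the target swaps the concordant and discordant pairs
(direction negates, p unchanged), and likewise a sign flip of the query.

### Classification and screening

A comparison is called activated/suppressed when direction = ±1 and
p ≤ α = 10⁻⁴. Across a compendium, a Benjamini–Hochberg stage at α = 0.001
is additionally applied to each biomarker's p-column and both stages must
agree — the conjunction is the only reading of the published cutoff
("p ≤ 10⁻⁴ after a BH correction of α = 0.001") consistent with per-bioset
p ≤ 10⁻⁴ statements; both are computed and logged, and the BH stage can be
disabled. Performance against binary truth counts no-call and suppressed as
negative predictions; balanced accuracy is the mean of sensitivity and
specificity, reported to the nearest whole percent.

### DEG calling

Per-gene one-way ANOVA on log2 intensities over the two contrasted groups
(classical F on (1, N−2) df; genes with zero variance everywhere get p = 1
by convention, logged), BH across all genes on the matrix, then the
fold-change floor (|signed linear-scale ratio of group means| ≥ 1.2). FDR
first and FC second mirrors the published order of operations. Moderated or
empirical-Bayes tests are out of scope.

### Biomarker derivation

Criteria, applied in order: (1–3) per probe — present in ≥ 3 of 4 activation
contrasts, always with one sign, |mean FC over contrasts where present| ≥
1.5 (absence is neutral evidence; averaging over only the lists where the
probe appears avoids fabricating zeros); (4) genes whose surviving probes
disagree in sign are removed entirely; (5) genes altered in the *same*
direction in the knockout exclusion bioset are removed (a response that
survives knockout cannot depend on the factor; opposite-direction changes do
not exclude); (6) genes claimed by other factors' biomarkers are removed.
The 4→5→6 order resolves an interaction the selection rules leave open.

### Coupling and ChIP enrichment

Coupling between two biomarkers plots each bioset's signed scores and fits
OLS; R² = 1 − SSE/SST and F = (n−2)R²/(1−R²) on (1, n−2) df, the spreadsheet
LINEST convention. No-call biosets are included with their signed scores
(significance thresholds are overlays, not filters). The coincidence rate is
the percentage of biosets carrying call A (e.g. activated) that also carry
call B (e.g. suppressed), with the full 3×3 call table reported.

Peaks (BED, 0-based half-open) are assigned to the gene minimizing
|summit − TSS| on the same chromosome; summit = floor((start+end)/2), TSS =
start on '+' and end − 1 on '−', distance is unsigned, ties break by gene
id. Biomarker enrichment among peak-proximal genes uses the Yates-corrected
χ² on the 2×2 partition of an explicit gene universe (the analysis universe
is a required argument because no canonical background exists); the
continuity term is clamped at |ad − bc| so independent tables give χ² = 0.

## Synthetic data

Generators are pure functions of (parameters, seed); identical calls are
bit-identical.

- **Genotype experiment** — 4 groups (wild-type/knockout × control/treated),
  4 replicates each, log-normal intensities (normal on log2, the standard
  microarray error model) with per-gene baselines uniform on log2 [6, 12]
  and replicate noise σ = 0.25. Responder genes shift by ±effect (log2) in
  treated wild-type only, so the knockout contrast is null by construction.
- **Bioset** — |FC| ~ 1.2 + Exponential(0.6); a concordance c plants
  round(c × biomarker size) biomarker genes with matching signs and |FC|
  drawn from the top quartile of the bioset's distribution, so the running
  scan sees signal near the top of the ranking; the non-biomarker fill never
  draws from the biomarker, so c = 0 biosets share no gene with it. Null
  biosets instead sample uniformly from the whole universe (chance overlap
  with random signs is possible — the harder null).
- **Compendium** — latent activity pairs from a standard bivariate normal
  with correlation ρ; each latent maps monotonically to a signed concordance
  clip(latent/2, −1, 1), negative latents planting flipped signs.
- **Peaks** — one peak per target gene; a designated fraction have their
  summit exactly at the target's TSS, the rest at non-target TSSs; the
  annotation generator spaces TSSs 10 kb apart so assignments are
  unambiguous.

What the generators do **not** emulate: probe-level structure, batch and
platform artifacts, correlated noise between genes, heavy-tailed effect-size
distributions, or annotation errors. Passing tests therefore demonstrate the
pipeline's internal correctness and calibration, not robustness to real
microarray pathology.

## Parameter defaults

| parameter | default | units | note |
|---|---|---|---|
| universe size N | 23,238 | genes | reference mouse platform gene count; simulations use the simulated universe size |
| upload FC floor | 1.2 | signed ratio | bioset import filter |
| DEG FDR | 0.01 | — | BH step-up |
| biomarker min avg FC | 1.5 | signed ratio | criterion 3 |
| biomarker min support | 3 of 4 | contrasts | criterion 1 |
| call threshold α | 10⁻⁴ | p-value | per comparison |
| compendium BH α | 0.001 | — | across biosets per biomarker |
| responder effect | 1.5 | log2 | SimulationConfig default |
| noise σ | 0.25 | log2 | replicate noise |

## Design notes and problem sizes

- **Recovery scenarios use strong activation.** With 4 replicates and a
  classical per-gene F-test, the noncentral-t calculation gives per-contrast
  recovery power ≈ 0.23–0.60 for a 1.5-log2 shift at σ = 0.25 under BH 0.01
  on 3,000–20,000 genes — near-complete recovery of a planted responder set
  is mathematically out of reach there without variance moderation, which is
  deliberately out of scope. Biomarker-recovery tests therefore model strong
  constitutive activation (2.5 log2 ≈ 5.7-fold responders, realistic for
  prototypical oxidative-stress targets under constitutive Keap1 loss),
  where power ≥ 0.97 and ≥ 3-of-4 support is near-certain.
- Test and calibration problem sizes are the package's own choices:
  null-specificity and type-I calibration run 10² and 10⁴ comparisons of
  300-gene biosets against the packaged 48-gene biomarker in a 20,000-gene
  universe; builder recovery uses 4,000-gene platforms with 40 responders
  over 10 seeds; coupling-sign recovery uses 100 compendia of 100 biosets at
  ρ = 0.5 in a 5,000-gene universe.
- The packaged biomarker is synthetic (see `sigscreen/datasets.py`): it
  reproduces the published composition (75 probe sets, 52 up / 23 down, 48
  genes) with plausible mouse liver gene symbols so the screen and demos run
  without downloads; it is not a published supplementary table.
- The discreteness of the hypergeometric tail plus the per-pair Bonferroni
  and the requirement that two pairs agree make the null conservative: the
  measured type-I error at the 10⁻⁴ cutoff is far below nominal, which is
  the desired behavior for a screen whose cost asymmetry favors specificity.

## Known limitations

- The statistic is one variant of a family; published p-values from the
  commercial engine will differ numerically (direction and call behavior are
  the comparable outputs). Reproducing printed compendium R² values would
  require the proprietary compendium and is out of scope.
- Biosets are gene-level; probe-to-gene mapping is the caller's
  responsibility (identity mapping in the synthetic pipeline).
- The conservative null means power at exactly α = 10⁻⁴ is lower than a
  calibrated test would give; concordance ≥ ~0.3 with top-quartile placement
  is detected reliably, weak diffuse signals are not.
- `evaluate` assumes binary truth; graded or unknown activation states must
  be excluded by the caller.
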