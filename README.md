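# wmglia

Cell-state, composition and spatial-proximity analysis of glia in aging
white matter.

Aging murine white matter accumulates distinct glial states: age-related
oligodendrocytes (ARO, marked by *Serpina3n* and *C4b*),
interferon-responsive oligodendrocytes (IRO, marked by *Stat1*,
*Ifi27l2a* and MHC class I genes *B2m*, *H2-K1*, *H2-D1*) and
interferon-responsive microglia (IRM, *Stat1*, *Ifit3*), with CD8⁺ T cells
(*Cd3d*, *Trbc2*) appearing in their vicinity. `wmglia` implements the
computational workflow for studying these states as a tested, reusable
library: per-cell QC filter chains, marker-signature cell-state assignment,
compositional change testing, and radius-based spatial proximity analysis
with a matched random-cell null — plus synthetic-data generators that plant
known ground truth so every stage can be validated end to end.

It is aimed at computational biologists who want the statistical machinery
of this kind of study (or honest calibration/power numbers for it) without
the original imaging and sequencing data.

## What it computes

**QC (`wmglia.qc`).** The plate-based (Smart-seq2) chain keeps a cell iff
all nine per-cell metrics fall inside closed intervals
(reads ∈ [2×10⁴, 4×10⁶], genes ∈ [1000, 6500], mean read length ∈
[180, 200], mismatch rate ∈ [0.15, 0.5], % uniquely mapped ∈ [68, 100],
% multimapped ∈ [2.3, 7.7], % too short ∈ [0, 17], ERCC fraction ≤ 0.011,
mitochondrial fraction ≤ 0.006). The droplet chain removes genes expressed
in < 3 cells, then cells with < 200 detected genes, > 10% mitochondrial
counts, or above optional per-batch UMI/gene caps, and drops the
rRNA-contamination indicator genes *Gm42418* and *AY036118*.

**Cell states (`wmglia.states`).** Counts are normalized as
log(1 + 10⁴·cᵢⱼ/Σⱼcᵢⱼ); a cell's signature score is the mean across-cell
z-score of the signature genes; a cell is labeled with the best-scoring
signature whose score exceeds τ (default 0.5 z-units), else `unassigned`.
Markers between groups are ranked by a two-sided Wilcoxon rank-sum test
(exact permutation enumeration for group sizes ≤ 10, tie- and
continuity-corrected normal approximation otherwise) with
avg_log2FC = log₂((mean expm1 A + ε)/(mean expm1 B + ε)) and
Benjamini–Hochberg control; top-k marker overlaps compare state programs.

**Composition (`wmglia.composition`).** Per-sample state proportions are
tested state-vs-rest with a beta-binomial likelihood-ratio test (group
means μ₀, μ₁ and per-state overdispersion fitted by maximum likelihood;
p from χ²₁), BH-adjusted across states, flagged at a deliberately
permissive default FDR of 0.4 for screening subtle shifts. Tukey boxplot
summaries (linear-interpolation quartiles, 1.5×IQR whiskers) match the
per-sample-dot presentation used for such data.

**Proximity (`wmglia.proximity`).** For subject cells (e.g. IRO) and
neighbor cells (e.g. CD8⁺ T), the statistic is the fraction of subjects
with a neighbor within 20 µm (center-to-center, boundary inclusive). The
null replaces the neighbor set, per section, with an equal number of
randomly sampled DAPI⁺ nuclei (default 100 seeded draws, averaged per
mouse) and the observed vs null per-mouse fractions are compared with a
two-sided paired t-test. A frontal-vs-medial white-matter comparison is
included for subregional localization.

**Synthetic data (`wmglia.simulate`).** Gamma-Poisson count matrices with
planted states, QC tables with planted violations, Dirichlet-multinomial
composition tables, and spatial sections where targets are Gaussian
offspring of reference cells with probability `assoc_prob` — all pure
functions of their seed.

## Worked example

```python
import numpy as np
from wmglia import simulate, states, proximity

# 8 samples, young vs aged white matter, planted glial states
design = simulate.default_design(seed=0)
counts = simulate.generate_counts(design)
norm = states.normalize_log(counts)
scores = states.score_signatures(norm)
assigned = states.assign_states(
    scores, [("IRO", 0.5), ("ARO", 0.5), ("IRM", 0.5), ("T_NK", 0.5)]
)
print(assigned["state"].value_counts().to_string())

# 4 mice x 3 sections with a planted 50% IRO-to-CD8 association
params = simulate.SpatialSimParams(assoc_prob=0.5, displacement_sigma=8.0, seed=0)
sections = simulate.generate_point_pattern(params)
result = proximity.proximity_analysis(
    sections, "IRO", "CD8_T", proximity.ProximityConfig(n_null_draws=100, seed=1)
)
print("observed per mouse:", np.round(result.observed.to_numpy(), 3))
print("null mean per mouse:", np.round(result.null_mean.to_numpy(), 3))
print(f"paired t = {result.test.t:.2f}, p = {result.test.p:.2e}")
```

Output:

```
state
unassigned    2048
ARO            228
T_NK           113
IRM             86
IRO             85

observed per mouse: [0.493 0.522 0.493 0.449]
null mean per mouse: [0.034 0.033 0.03  0.038]
paired t = 28.33, p = 9.66e-05
```

The assignment counts mirror the planted prevalences (ARO, IRO, IRM and
T cells are rare in young and expanded in aged white matter; baseline
oligodendrocytes stay `unassigned`). About half the IRO cells sit within
20 µm of a CD8⁺ T cell, versus ~3% expected for randomly chosen nuclei, and
the paired test across the four mice is decisive.

A full pipeline run (simulate → qc → states → composition → proximity,
with a manifest and byte-reproducible outputs) is one call or one command:

```bash
wmglia all --seed 1 --out results/demo
```

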