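# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## QC filter chains

Two platform-specific chains with deliberately different boundary
semantics.

**Plate-based (Smart-seq2).** A cell is kept iff every one of nine per-cell
metrics lies inside a closed interval (`lo ≤ x ≤ hi`); the defaults are the
interval bounds listed in the README. Both endpoints are inclusive because
the defining criteria are stated as ≥/≤ conditions. Two of the published
bounds look unusual and are applied exactly as configured rather than
"corrected": the mismatch-rate interval has a *lower* bound of 0.15, and
the ERCC and mitochondrial bounds (0.011, 0.006) are interpreted on the 0–1
fraction scale. Both are ordinary configurable intervals
(`QCThresholds.replace(...)`), so users who read these quantities
differently can override them. Missing (NaN) metric values fail the filter,
since the interval condition cannot be verified.

**Droplet.** Order is fixed and tested: genes expressed in fewer than
`min_cells_per_gene` (default 3) cells are removed first, with expression
counted over the input cells; detected-gene numbers for the subsequent cell
filter are then computed on the surviving genes. Cells are removed when
detected genes < 200, mitochondrial fraction > 0.10 (strictly), or total
UMIs / detected genes reach the optional caps (strict upper bounds, so a
cell exactly at the cap is removed). The caps vary per sequencing batch and
are configuration, not code. Mitochondrial genes are recognized by the
`mt-` name prefix. The rRNA-contamination indicator genes *Gm42418* and
*AY036118* are removed by `remove_genes`, which ignores absent names with a
log note.

Invariants tested: kept/removed partition the input; widening any interval
never shrinks the kept set; filtering is idempotent; both chains agree
exactly with brute-force per-cell predicates on random tables, including
all 18 Smart-seq2 interval endpoints.

## Normalization and signature scoring

Counts are normalized as `log(1 + scale · c/libsize)` with
`scale = 10⁴`. This is a deliberately simple, documented normalization: the
variance-stabilizing regression and graph-clustering stack used in
full-scale single-cell analyses is out of scope here, because the cell
states of interest are defined by small, fixed marker sets rather than by
de-novo clusters. A zero-libsize cell raises immediately — it means QC was
skipped.

A signature score is the mean, over signature genes present in the matrix,
of each gene's across-cell z-score (population SD, `ddof = 0`).
Zero-variance genes contribute 0 rather than NaN. Shipped signatures: IRO
{Stat1, Ifi27l2a, B2m, H2-K1, H2-D1}, ARO {Serpina3n, C4b}, IRM {Stat1,
Ifit3}, the shared IFN program {Stat1, Ifit3, Usp18, Ifi27l2a}, and T/NK
{Cd3d, Trbc2}.

Assignment takes an ordered rule list `(signature, τ)`: a cell gets the
highest-scoring signature whose score strictly exceeds its τ, exact ties
resolving to the earlier rule; otherwise `unassigned`. τ = 0.5 z-units by
default. τ is an artifact parameter of this package — cluster-based
workflows have no equivalent threshold — and was fixed a priori as "half a
standard deviation above the population mean", not fitted to data.

## Marker ranking

Per gene, a two-sided Wilcoxon rank-sum test between the two cell groups:

* both groups ≤ 10 cells: the exact permutation distribution of the group-A
  rank sum, computed by dynamic programming over doubled mid-ranks (doubling
  makes tied mid-ranks integral, so the distribution is exact under ties).
  The two-sided p is `P(|W − E[W]| ≥ |w_obs − E[W]|)`. The test suite checks
  this path against literal `itertools.combinations` enumeration.
* otherwise: the normal approximation with tie correction and continuity
  correction. Genes with no variation across the pooled groups get p = 1.

Fold change is `log₂((mean expm1(A) + ε)/(mean expm1(B) + ε))` with
`ε = 10⁻⁹` — the de-logged-mean convention of the standard single-cell
toolchain; ε only guards all-zero groups. BH adjustment runs across all
tested genes *before* any fold-change filtering, so the adjusted values do
not depend on the reporting threshold; when a threshold is set (the
conventional `|avg_log2FC| > 1`), failing rows are dropped afterwards. Rows
sort by p ascending, then |fold change| descending (stable sort).
`top_k_overlap` intersects the top-k genes of two such tables and is
symmetric in its arguments.

## Compositional testing

Cluster abundances are compositional and overdispersed across replicate
samples. Each state is tested state-vs-rest: with yᵢ cells of the state out
of nᵢ in sample i, the model is beta-binomial with mean μ (parameterized
as a, b = μs, (1−μ)s) and concentration s. The null fits a shared μ, the
alternative one μ per group, both with one shared s per state, all by
maximum likelihood (Nelder-Mead on (logit μ, log s), two starting
concentrations, moment-based initial means; the alternative is guarded to
never score below the null). p comes from χ² with 1 df on the likelihood
ratio; BH runs across states; the `significant` flag uses FDR ≤ 0.4 by
default — a deliberately permissive screening threshold for subtle
compositional shifts, configurable for confirmatory use. The reported
effect is the log-odds difference logit(μ₁) − logit(μ₀).

Degenerate states are skipped with a log note: absent from every sample, or
occupying 100% of every sample (no "rest" to compare against). Each group
must contribute ≥ 2 samples.

This test deliberately avoids a reference-cell-type anchor (which some
compositional frameworks require but which is an additional modeling choice
with no canonical value); state-vs-rest framing sidesteps it at the cost of
mild dependence between the per-state tests, which BH tolerates.
Simulation at 10 samples/group × 1,000 cells/sample puts the empirical
type-I error near 0.065 at α = 0.05 — slightly above nominal, as expected
for a 1-df LRT with an estimated nuisance overdispersion at this sample
size, and within the 1.5× bound the acceptance suite enforces.

Boxplot summaries use linear-interpolation quartiles (the `numpy`
`method="linear"` convention, fixed because boxplot conventions differ) and
Tukey 1.5×IQR whiskers/outliers.

## Spatial proximity

All distances are Euclidean, center-to-center, in µm. The observed
statistic is the fraction of subject-category cells whose nearest
neighbor-category cell lies within radius r (default 20 µm). The boundary
is **inclusive** (a neighbor at exactly r counts): the measurement is
defined by a circle of radius r drawn around the cell center, so the
closed disc is the natural region; an exclusive option exists. Neighbor
queries use a k-d tree and are tested to agree exactly with all-pairs
distances.

The random-cell null: per draw and per section, sample without replacement
a set of DAPI⁺ nuclei equal in size to the section's neighbor-category
count, excluding the neighbor category itself (and by default also the
subject category — whether subjects should be eligible is genuinely
ambiguous, so it is an option), then recompute the fraction with the
sampled set as neighbors. The default 100 seeded draws are averaged per
mouse: a strictly more stable estimator of the same null as a single
manual random selection, which `n_null_draws = 1` reproduces.

Per-mouse fractions pool cells across the mouse's sections by default
(matching reporting of pooled per-mouse totals); per-section averaging is
available (`aggregation="section_mean"`). Observed vs mean-null per-mouse
fractions are compared with a classical two-sided paired t-test
(df = mice − 1). If all paired differences are identical the t statistic
is defined as 0 (p = 1) for zero difference and ±∞ (p = 0) otherwise.
No edge correction is applied anywhere; the calibration experiments use
windows ≫ r so the bias is negligible (see below).

The subregional comparison takes per-section values with a two-level
region label (frontal vs medial white matter), averages sections per mouse
and region, and applies the same paired t-test across mice; every mouse
must contribute both regions.

## Synthetic-data generators

All generators are pure functions of their arguments including the seed
(bit-identical reruns are tested).

**QC tables.** Passing cells draw each metric uniformly from the central
80% of its interval; violating cells are pushed outside on a feasible side
(respecting hard domains such as percentages ≤ 100), disjointly across
metrics, with ground truth in `passes_qc`.

**Counts.** Gamma-Poisson: baseline per-gene means from Gamma(0.4, 10)
(long right tail, many weakly expressed genes, ≈ 6,500 counts/cell at the
default 1,500 genes), lognormal library-size factors with unit mean
(σ = 0.35), counts Poisson(lib × mean × fold) where the fold multiplier
(default 8) elevates the marker genes of the cell's planted state. Marker
genes draw baseline means uniformly from 30–80 counts per cell rather than
from the gamma tail: the defining markers of real glial states are
reliably detected transcripts, and a "marker" with a baseline mean of 0.01
counts would be undetectable at any fold — the planted effect must act on
genes a real analysis could see. The default design is 8 samples (4 young,
4 aged, white matter, one mouse each, 320 cells per sample ≈ 2,500 cells),
with state prevalences expanding from ~1% (IRO, IRM, T cells) and 2% (ARO)
in young to 6%/15% in aged white matter. Matrices carry the 13
mitochondrial genes, both contaminant indicator genes, and (plate-based
samples only) 20 ERCC spike-in features.

**Sections.** Background DAPI⁺ nuclei are a homogeneous Poisson process
(default intensity 10⁻³ µm⁻² → ≈ 360 nuclei per 600 × 600 µm window);
reference cells are uniform (default 11/section); each target cell is,
with probability `assoc_prob`, displaced from a uniformly chosen reference
parent by an isotropic Gaussian (default σ = 8 µm), resampled until inside
the window — resampling rather than clamping avoids edge pile-up that
would bias proximity fractions — otherwise uniform (default 23
targets/section, 3 sections × 4 mice). The per-section reference and
target counts are scaled from study totals of 134 reference and 272 target
cells over 4 mice × 3 sections; the imaging field of view is not reported
anywhere, so the window size is an explicit choice and everything is
configurable. All cells, typed or background, carry the DAPI⁺ flag the
null draws from.

**Composition tables.** Per sample, proportions ~ Dirichlet(c·p) with
concentration c = 50 (moderate replicate-to-replicate scatter), counts
multinomial; the treated group multiplies selected states by a fold and
renormalizes, and the planted effect map rides along in `info`.

What the generators do **not** emulate: batch effects, ambient RNA,
doublets, gene-gene correlation beyond the planted state structure,
segmentation errors, or anisotropic tissue architecture. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated models — not robustness to those artifacts.

## Calibration and power experiments

`wmglia.experiments` runs many independent simulated studies per setting;
the sizes below are the package's chosen experiment scales (also used by
the acceptance suite):

* **Proximity null (CSR)**: 200 studies at `assoc_prob = 0`; the paired
  test's rejection rate at α = 0.05 falls inside the 95% binomial interval
  around 0.05, and the pooled subject-with-neighbor fraction matches the
  Poisson closed form 1 − exp(−λπr²) within 3 SE over 100 studies (the
  residual edge-effect deficit at the default window is ≈ 0.001, inside
  that tolerance).
* **Proximity power**: 100 studies at `assoc_prob = 0.5`, σ = 8 µm; the
  paired test rejects in ≥ 90% of studies (empirically ~100%) and the
  observed-minus-null difference is positive in ≥ 99%.
* **Composition**: 500 null simulations (type-I ≤ 1.5 × 0.05, empirically
  ≈ 0.065) and 100 replicates with a planted 3-fold IRO shift at
  10 samples/group × 1,000 cells (flagged in ≥ 80%, empirically ~100%).
* **State recovery**: ≥ 95% of planted labels recovered at fold 8
  (empirically ≈ 0.98), degrading monotonically as the fold approaches 1
  (≈ 0.92 at 4, ≈ 0.79 at 2). Cells planted in states without a dedicated
  signature count as correct when `unassigned`.

## Pipeline and reproducibility

`run_all` executes simulate → qc → states → composition → proximity from a
schema-validated YAML config (unknown keys rejected). One global seed
spawns per-stage seeds via `numpy.random.SeedSequence(seed).spawn`, all
below 2³¹ and recorded in the manifest together with library versions and
a config hash, so any stage can be rerun in isolation. Outputs are
versioned plain text (CSV/JSON/MatrixMarket) and byte-identical across
reruns with the same config and seed.

## Known limitations

* The beta-binomial LRT is mildly anticonservative at small sample sizes
  (type-I ≈ 0.065 at nominal 0.05 with 10 samples/group); a Bartlett-type
  correction is not applied. At the default screening FDR of 0.4 this is
  immaterial; for confirmatory use, tighten the FDR and prefer more
  samples.
* Signature scores are z-scores relative to the analyzed cell population,
  so a score (and τ) is only comparable within one dataset composition.
* The exact Wilcoxon path is quadratic in group size times total rank sum;
  it is restricted to groups ≤ 10 by design.
* Proximity analysis is strictly 2-D and uncorrected for section edges;
  with radii comparable to the window size the CSR expectation would need
  edge terms the package does not implement.
* The droplet chain takes the `mt-` prefix convention for mitochondrial
  genes; non-mouse naming schemes need the prefix parameter.
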