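"""Synthetic data with planted ground truth for every pipeline stage.

Three kinds of inputs are emulated, each matching the statistical structure
the downstream stages assume rather than the raw instrument output:

* **QC metric tables** -- per-cell sequencing metrics where a requested
  number of cells violate chosen filters and everything else sits safely
  inside the bounds, with a ground-truth pass flag per cell.
* **Count matrices** -- a gamma-Poisson (negative binomial) model: per-gene
  baseline means from a long-tailed gamma, lognormal library-size factors,
  and Poisson sampling of ``libsize x gene_mean x fold``, where the fold
  multiplier elevates the marker genes of the cell's planted state. Marker
  genes get moderate baseline means (real marker genes are reliably
  detected); matrices carry mitochondrial genes, the rRNA-contamination
  indicator genes, and -- for plate-based samples -- ERCC spike-in features.
* **Spatial point patterns** -- per section, DAPI+ background nuclei as a
  homogeneous Poisson process, reference cells (CD8 T) uniform, and each
  target cell (IRO/IRM) placed, with probability ``assoc_prob``, at an
  isotropic Gaussian displacement from a uniformly chosen reference parent
  (resampled until inside the window, avoiding edge pile-up), otherwise
  uniform. Default per-section counts (11 reference, 23 target, ~360
  background in a 600 x 600 um window) are scaled from the study totals of
  134 CD8+ and 272 IRO cells over 4 mice x 3 sections; the imaging
  field-of-view is not reported anywhere, so the window is an explicit,
  configurable choice.

Composition tables are Dirichlet-multinomial with a group-specific fold
effect on selected states. Every generator is a pure function of its
arguments including the seed.
"""
from __future__ import annotations

import dataclasses

import anndata as ad
import numpy as np
import pandas as pd

from .composition import CompositionTable
from .proximity import PointPattern
from .qc import SMARTSEQ_METRICS, QCThresholds

AGES = (3, 12, 18, 24)
GENOTYPES = ("WT", "RAG1KO", "CD8KO", "TREM2KO")
TISSUES = ("GM", "WM")
PLATFORMS = ("smartseq2", "droplet")

#: the 13 protein-coding mouse mitochondrial genes
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)
CONTAMINANT_GENES = ("Gm42418", "AY036118")

#: hard domain of each QC metric (used to pick a feasible violation side)
_METRIC_DOMAIN: dict[str, tuple[float, float]] = {
    "reads": (0.0, np.inf),
    "genes": (0.0, np.inf),
    "mean_read_length": (0.0, np.inf),
    "mismatch_rate": (0.0, 1.0),
    "pct_unique_mapped": (0.0, 100.0),
    "pct_multimapped": (0.0, 100.0),
    "pct_too_short": (0.0, 100.0),
    "frac_ercc": (0.0, 1.0),
    "frac_mito": (0.0, 1.0),
}


# ---------------------------------------------------------------------------
# design / profile types


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    """One biological sample in a simulated design."""

    sample_id: str
    mouse_id: str
    age_months: int
    genotype: str
    tissue: str
    platform: str
    n_cells: int

    def __post_init__(self) -> None:
        if self.age_months not in AGES:
            raise ValueError(f"age_months must be one of {AGES}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def condition(self) -> tuple[int, str, str]:
        return (self.age_months, self.genotype, self.tissue)


@dataclasses.dataclass(frozen=True)
class SimDesign:
    samples: tuple[SampleSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")


@dataclasses.dataclass(frozen=True)
class StateProfile:
    """One cell state: its marker genes, marker elevation and prevalence.

    ``baseline_proportion`` is either one fraction used for every condition
    or a dict keyed by (age_months, genotype, tissue).
    """

    state: str
    baseline_proportion: float | dict[tuple[int, str, str], float]
    markers: tuple[str, ...]
    fold: float = 1.0

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker list must be non-empty")
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")

    def proportion_for(self, condition: tuple[int, str, str]) -> float:
        if isinstance(self.baseline_proportion, dict):
            if condition not in self.baseline_proportion:
                raise KeyError(f"profile {self.state!r} lacks condition {condition}")
            return self.baseline_proportion[condition]
        return float(self.baseline_proportion)


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Count-model noise settings.

    Baseline gene means follow a Gamma(shape, scale) (long right tail, many
    lowly expressed genes); marker genes instead draw uniform baseline means
    from ``[marker_mean_low, marker_mean_high]`` counts per cell so that
    planted effects act on detectable genes. Library-size factors are
    lognormal with unit mean.
    """

    gene_mean_shape: float = 0.4
    gene_mean_scale: float = 10.0
    marker_mean_low: float = 30.0
    marker_mean_high: float = 80.0
    libsize_sigma: float = 0.35
    ercc_mean: float = 0.5
    n_ercc: int = 20


YOUNG_WM = (3, "WT", "WM")
AGED_WM = (24, "WT", "WM")


def default_profiles(fold: float = 8.0) -> list[StateProfile]:
    """Seven-state profile set for a young-vs-aged white-matter design.

    Prevalences emulate the study-scale structure: the interferon-responsive
    and age-related states are rare in young white matter and expand with
    age, while the two baseline oligodendrocyte states shrink. The marker
    fold elevation defaults to 8, a strong but realistic marker contrast.
    """
    props = {
        "Oligo1": {YOUNG_WM: 0.52, AGED_WM: 0.34},
        "Oligo2": {YOUNG_WM: 0.30, AGED_WM: 0.24},
        "ARO": {YOUNG_WM: 0.02, AGED_WM: 0.15},
        "IRO": {YOUNG_WM: 0.01, AGED_WM: 0.06},
        "IRM": {YOUNG_WM: 0.01, AGED_WM: 0.06},
        "CD8_T": {YOUNG_WM: 0.01, AGED_WM: 0.04},
        "other": {YOUNG_WM: 0.13, AGED_WM: 0.11},
    }
    markers = {
        "Oligo1": ("Plp1", "Mal"),
        "Oligo2": ("Mbp", "Mog"),
        "ARO": ("Serpina3n", "C4b"),
        "IRO": ("Stat1", "Ifi27l2a", "B2m", "H2-K1", "H2-D1"),
        "IRM": ("Stat1", "Ifit3"),
        "CD8_T": ("Cd3d", "Trbc2"),
        "other": ("Cldn5",),
    }
    folds = {"ARO": fold, "IRO": fold, "IRM": fold, "CD8_T": fold}
    return [
        StateProfile(s, props[s], markers[s], folds.get(s, 1.0)) for s in props
    ]


def default_design(
    n_per_group: int = 4,
    cells_per_sample: int = 320,
    platform: str = "smartseq2",
    seed: int = 0,
) -> SimDesign:
    """Young (3 mo) vs aged (24 mo) wild-type white matter, one mouse per
    sample; the default scale (~2,500 cells over 8 mice) mirrors a
    plate-based study of this size."""
    samples = []
    for group, age in (("young", 3), ("aged", 24)):
        for i in range(n_per_group):
            samples.append(
                SampleSpec(
                    sample_id=f"{group}_{i + 1}",
                    mouse_id=f"m_{group}_{i + 1}",
                    age_months=age,
                    genotype="WT",
                    tissue="WM",
                    platform=platform,
                    n_cells=cells_per_sample,
                )
            )
    return SimDesign(samples=tuple(samples), seed=seed)


# ---------------------------------------------------------------------------
# QC tables


def generate_qc_table(
    n_cells: int,
    violation_spec: dict[str, int] | None = None,
    seed: int = 0,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics with exactly the requested filter violations.

    Non-violating cells draw every metric uniformly from the central 80% of
    its interval (strictly inside the bounds); each metric named in
    ``violation_spec`` gets the stated number of cells pushed outside its
    interval on a feasible side (violating cells are disjoint across
    metrics). The ground-truth flag is stored in ``passes_qc``.
    """
    violation_spec = violation_spec or {}
    thresholds = thresholds or QCThresholds()
    bounds = thresholds.bounds()
    unknown = set(violation_spec) - set(SMARTSEQ_METRICS)
    if unknown:
        raise ValueError(f"unknown QC metric(s): {sorted(unknown)}")
    if any(c < 0 for c in violation_spec.values()):
        raise ValueError("violation counts must be non-negative")
    if sum(violation_spec.values()) > n_cells:
        raise ValueError("violation counts exceed n_cells")

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(index=[f"cell_{i:05d}" for i in range(n_cells)])
    table.index.name = "cell_id"
    for metric, (lo, hi) in bounds.items():
        span = hi - lo
        table[metric] = rng.uniform(lo + 0.1 * span, hi - 0.1 * span, size=n_cells)

    order = rng.permutation(n_cells)
    start = 0
    passes = np.ones(n_cells, dtype=bool)
    for metric, count in violation_spec.items():
        rows = order[start : start + count]
        start += count
        lo, hi = bounds[metric]
        dom_lo, dom_hi = _METRIC_DOMAIN[metric]
        span = max(hi - lo, 1e-6)
        below_ok, above_ok = lo > dom_lo, hi < dom_hi
        if not (below_ok or above_ok):
            raise ValueError(f"metric {metric!r} interval covers its whole domain")
        for row in rows:
            if below_ok and (not above_ok or rng.random() < 0.5):
                low_edge = max(dom_lo, lo - 0.5 * span)
                value = lo - rng.uniform(0.05, 1.0) * (lo - low_edge)
            else:
                high_edge = hi + 0.5 * span if not np.isfinite(dom_hi) else min(
                    dom_hi, hi + 0.5 * span
                )
                value = hi + rng.uniform(0.05, 1.0) * (high_edge - hi)
            table.iloc[row, table.columns.get_loc(metric)] = value
        passes[rows] = False
    table["passes_qc"] = passes
    return table


# ---------------------------------------------------------------------------
# count matrices


def _gene_universe(
    profiles: list[StateProfile], n_genes: int, any_smartseq: bool, noise: NoiseParams
) -> tuple[list[str], list[str]]:
    markers: list[str] = []
    for prof in profiles:
        for g in prof.markers:
            if g not in markers:
                markers.append(g)
    named = markers + list(MITO_GENES) + list(CONTAMINANT_GENES)
    ercc = [f"ERCC-{i + 1:05d}" for i in range(noise.n_ercc)] if any_smartseq else []
    n_named = len(named) + len(ercc)
    if n_genes < n_named:
        raise ValueError(f"n_genes={n_genes} < {n_named} named genes")
    fillers = [f"Gene{i + 1:05d}" for i in range(n_genes - n_named)]
    return named + fillers + ercc, markers


def generate_counts(
    design: SimDesign,
    profiles: list[StateProfile] | None = None,
    n_genes: int = 1500,
    noise: NoiseParams | None = None,
) -> ad.AnnData:
    """Gamma-Poisson count matrix with planted cell states.

    Returns cells x genes counts (``AnnData``) with per-cell metadata and
    the ground-truth state in ``obs['true_state']``. The same design (seed
    included) always yields the identical matrix.
    """
    profiles = profiles if profiles is not None else default_profiles()
    noise = noise or NoiseParams()
    state_names = [p.state for p in profiles]
    conditions = {s.condition for s in design.samples}
    for cond in sorted(conditions):
        total = sum(p.proportion_for(cond) for p in profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions for condition {cond} sum to {total}")

    any_ss2 = any(s.platform == "smartseq2" for s in design.samples)
    genes, marker_list = _gene_universe(profiles, n_genes, any_ss2, noise)
    gene_index = {g: j for j, g in enumerate(genes)}
    rng = np.random.default_rng(design.seed)

    base_mean = rng.gamma(noise.gene_mean_shape, noise.gene_mean_scale, size=len(genes))
    for g in marker_list:
        base_mean[gene_index[g]] = rng.uniform(
            noise.marker_mean_low, noise.marker_mean_high
        )
    ercc_cols = np.array([g.startswith("ERCC-") for g in genes])
    base_mean[ercc_cols] = noise.ercc_mean

    # per-state fold multiplier over genes
    fold_rows = {}
    for prof in profiles:
        row = np.ones(len(genes))
        for g in prof.markers:
            if g not in gene_index:
                raise ValueError(f"marker {g!r} absent from gene universe")
            row[gene_index[g]] *= prof.fold
        fold_rows[prof.state] = row

    blocks, obs_rows = [], []
    sigma = noise.libsize_sigma
    for sample in design.samples:
        props = np.array([p.proportion_for(sample.condition) for p in profiles])
        states = rng.choice(state_names, size=sample.n_cells, p=props)
        lib = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=sample.n_cells)
        rate = lib[:, None] * base_mean[None, :]
        rate = rate * np.vstack([fold_rows[s] for s in states])
        if sample.platform == "droplet":
            rate[:, ercc_cols] = 0.0
        blocks.append(rng.poisson(rate).astype(np.int32))
        for i, state in enumerate(states):
            obs_rows.append(
                {
                    "cell_id": f"{sample.sample_id}_c{i + 1:04d}",
                    "sample_id": sample.sample_id,
                    "mouse_id": sample.mouse_id,
                    "age_months": sample.age_months,
                    "genotype": sample.genotype,
                    "tissue": sample.tissue,
                    "platform": sample.platform,
                    "true_state": state,
                }
            )
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(
        X=np.vstack(blocks),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["ground_truth"] = {
        "profiles": {
            p.state: {"markers": list(p.markers), "fold": p.fold} for p in profiles
        },
        "seed": design.seed,
    }
    return adata


# ---------------------------------------------------------------------------
# spatial point patterns


@dataclasses.dataclass(frozen=True)
class SpatialSimParams:
    """Settings for simulated imaged sections; lengths in um."""

    window_width: float = 600.0
    window_height: float = 600.0
    dapi_intensity: float = 0.001
    n_ref: int = 11
    n_target: int = 23
    assoc_prob: float = 0.5
    displacement_sigma: float = 8.0
    n_sections_per_mouse: int = 3
    n_mice: int = 4
    seed: int = 0
    ref_category: str = "CD8_T"
    target_category: str = "IRO"

    def __post_init__(self) -> None:
        if self.window_width <= 0 or self.window_height <= 0:
            raise ValueError("window dimensions must be positive")
        if not 0.0 <= self.assoc_prob <= 1.0:
            raise ValueError("assoc_prob must be in [0, 1]")
        if self.displacement_sigma <= 0:
            raise ValueError("displacement_sigma must be positive")
        expected = self.dapi_intensity * self.window_width * self.window_height
        if expected > 1e6:
            raise ValueError("expected background count exceeds 1e6 cells")


def _uniform_points(rng, n, w, h):
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def generate_point_pattern(params: SpatialSimParams) -> list[PointPattern]:
    """Simulate sections with a planted reference-target association.

    Returns one ``PointPattern`` per (mouse, section); the planted
    ``assoc_prob`` and parameters are recorded in each pattern's ``info``.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.window_width, params.window_height
    area = w * h
    patterns = []
    for m in range(params.n_mice):
        mouse_id = f"mouse_{m + 1}"
        for s in range(params.n_sections_per_mouse):
            section_id = f"{mouse_id}_sec{s + 1}"
            n_bg = rng.poisson(params.dapi_intensity * area)
            bg = _uniform_points(rng, n_bg, w, h)
            refs = _uniform_points(rng, params.n_ref, w, h)
            targets = np.empty((params.n_target, 2))
            for i in range(params.n_target):
                if params.n_ref > 0 and rng.random() < params.assoc_prob:
                    parent = refs[rng.integers(params.n_ref)]
                    while True:  # resample until inside; no edge clamping
                        pos = parent + rng.normal(0, params.displacement_sigma, 2)
                        if 0 <= pos[0] <= w and 0 <= pos[1] <= h:
                            break
                    targets[i] = pos
                else:
                    targets[i] = _uniform_points(rng, 1, w, h)[0]
            coords = np.vstack([bg, refs, targets])
            categories = (
                ["DAPI_other"] * n_bg
                + [params.ref_category] * params.n_ref
                + [params.target_category] * params.n_target
            )
            cells = pd.DataFrame(
                {
                    "cell_id": [f"{section_id}_c{i + 1:05d}" for i in range(len(coords))],
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                    "category": categories,
                    "dapi": True,
                    "section_id": section_id,
                    "mouse_id": mouse_id,
                }
            )
            patterns.append(
                PointPattern(
                    cells=cells,
                    window=(w, h),
                    info={"assoc_prob": params.assoc_prob, "params": dataclasses.asdict(params)},
                )
            )
    return patterns


# ---------------------------------------------------------------------------
# composition tables


def generate_composition_counts(
    base_props: np.ndarray | list[float],
    effects: dict[str, float] | None = None,
    n_samples_per_group: int = 10,
    cells_per_sample: int = 1000,
    overdispersion: float = 50.0,
    seed: int = 0,
    states: list[str] | None = None,
    group_names: tuple[str, str] = ("control", "treated"),
) -> CompositionTable:
    """Dirichlet-multinomial sample x state counts with a planted group effect.

    The second group's expected proportions are the base proportions with
    each state in ``effects`` multiplied by its fold, renormalized.
    ``overdispersion`` is the Dirichlet concentration (smaller = noisier
    replicate samples; 50 gives the moderate between-replicate scatter seen
    in per-sample cluster proportions).
    """
    base = np.asarray(base_props, dtype=float)
    if abs(base.sum() - 1.0) > 1e-9:
        raise ValueError("base proportions must sum to 1")
    if overdispersion <= 0:
        raise ValueError("degenerate concentration: overdispersion must be > 0")
    if n_samples_per_group < 1:
        raise ValueError("each group needs at least one sample")
    effects = effects or {}
    states = states or [f"state_{i + 1}" for i in range(len(base))]
    if len(states) != len(base):
        raise ValueError("states and base_props length mismatch")
    bad = set(effects) - set(states)
    if bad:
        raise ValueError(f"effects reference unknown states: {sorted(bad)}")
    if any(f <= 0 for f in effects.values()):
        raise ValueError("effect folds must be positive")

    fold = np.array([effects.get(s, 1.0) for s in states])
    treated = base * fold
    treated = treated / treated.sum()

    rng = np.random.default_rng(seed)
    rows, meta = [], []
    for group, props in zip(group_names, (base, treated)):
        for i in range(n_samples_per_group):
            p = rng.dirichlet(props * overdispersion)
            counts = rng.multinomial(cells_per_sample, p)
            rows.append(counts)
            meta.append({"sample_id": f"{group}_{i + 1}", "group": group})
    metadata = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(rows, index=metadata.index, columns=states)
    return CompositionTable(
        counts=counts,
        metadata=metadata,
        info={"effects": dict(effects), "base_props": base.tolist(), "seed": seed},
    )
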