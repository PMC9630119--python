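"""Simulation experiments: calibration, power and parameter recovery.

These routines run many independent synthetic studies through the analysis
stages and summarize the outcomes. They serve two purposes: verifying that
the statistical machinery is calibrated (null rejection rates near nominal)
and measuring its power under planted effects at study-realistic sizes.
Every experiment derives all of its randomness from one integer seed.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import composition, proximity, simulate, states


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def proximity_study_outcomes(
    n_studies: int,
    assoc_prob: float,
    displacement_sigma: float = 8.0,
    seed: int = 0,
    n_null_draws: int = 100,
    params: simulate.SpatialSimParams | None = None,
) -> pd.DataFrame:
    """Run independent simulated imaging studies through the proximity stage.

    Each study simulates ``n_mice x n_sections`` sections at the given
    target-to-reference association strength, computes observed and
    random-cell-null per-mouse fractions, and applies the paired t-test.
    Returns one row per study with the p-value, the mean per-mouse
    observed - null difference, and the study-wide subject-with-neighbor
    fraction (pooled over all subjects).
    """
    base = params or simulate.SpatialSimParams()
    study_seeds = _spawn_seeds(seed, 2 * n_studies)
    rows = []
    for i in range(n_studies):
        sim_params = dataclasses.replace(
            base,
            assoc_prob=assoc_prob,
            displacement_sigma=displacement_sigma,
            seed=study_seeds[2 * i],
        )
        patterns = simulate.generate_point_pattern(sim_params)
        config = proximity.ProximityConfig(
            n_null_draws=n_null_draws, seed=study_seeds[2 * i + 1]
        )
        result = proximity.proximity_analysis(
            patterns, sim_params.target_category, sim_params.ref_category, config
        )
        pooled_fraction = (
            result.per_section["hits"].sum() / result.per_section["n"].sum()
        )
        rows.append(
            {
                "p": result.test.p,
                "mean_diff": float(np.mean(result.test.differences)),
                "pooled_fraction": float(pooled_fraction),
            }
        )
    return pd.DataFrame(rows)


def csr_neighbor_fraction_expectation(
    params: simulate.SpatialSimParams | None = None, radius: float = 20.0
) -> float:
    """Poisson-approximation of the subject-with-neighbor fraction under
    complete spatial randomness: ``1 - exp(-lambda * pi * r^2)`` with
    ``lambda`` the reference-cell intensity."""
    p = params or simulate.SpatialSimParams()
    lam = p.n_ref / (p.window_width * p.window_height)
    return float(1.0 - np.exp(-lam * np.pi * radius**2))


DEFAULT_COMPOSITION_BASE = (0.40, 0.24, 0.15, 0.05, 0.16)
DEFAULT_COMPOSITION_STATES = ("Oligo1", "Oligo2", "ARO", "IRO", "other")


def composition_null_pvalues(
    n_sims: int,
    seed: int = 0,
    base_props: tuple[float, ...] = DEFAULT_COMPOSITION_BASE,
    states_names: tuple[str, ...] = DEFAULT_COMPOSITION_STATES,
    n_samples_per_group: int = 10,
    cells_per_sample: int = 1000,
) -> np.ndarray:
    """Per-state p-values from exchangeable (no-effect) composition tables.

    Returns the pooled array of raw p-values across all simulations and
    states; under the null these should be approximately uniform.
    """
    seeds = _spawn_seeds(seed, n_sims)
    pvals = []
    for s in seeds:
        table = simulate.generate_composition_counts(
            list(base_props),
            effects={},
            n_samples_per_group=n_samples_per_group,
            cells_per_sample=cells_per_sample,
            seed=s,
            states=list(states_names),
        )
        result = composition.test_composition(table, "group")
        pvals.extend(result.table["p"].tolist())
    return np.asarray(pvals)


def composition_power(
    n_reps: int,
    fold: float = 3.0,
    target_state: str = "IRO",
    seed: int = 0,
    fdr: float = composition.DEFAULT_FDR,
    base_props: tuple[float, ...] = DEFAULT_COMPOSITION_BASE,
    states_names: tuple[str, ...] = DEFAULT_COMPOSITION_STATES,
    n_samples_per_group: int = 10,
    cells_per_sample: int = 1000,
) -> dict:
    """Fraction of replicates flagging the planted state, and how often the
    estimated effect has the planted (positive) sign when flagged."""
    seeds = _spawn_seeds(seed, n_reps)
    flagged = 0
    sign_ok = 0
    for s in seeds:
        table = simulate.generate_composition_counts(
            list(base_props),
            effects={target_state: fold},
            n_samples_per_group=n_samples_per_group,
            cells_per_sample=cells_per_sample,
            seed=s,
            states=list(states_names),
        )
        result = composition.test_composition(table, "group", fdr=fdr)
        row = result.table.set_index("state").loc[target_state]
        if row["significant"]:
            flagged += 1
            if row["effect_logodds"] > 0:
                sign_ok += 1
    return {
        "power": flagged / n_reps,
        "sign_agreement": sign_ok / flagged if flagged else float("nan"),
        "n_reps": n_reps,
    }


#: states whose signature the default assignment rules can recover; all other
#: planted states are expected to come out "unassigned"
DEFAULT_ASSIGN_ORDER = ("IRO", "ARO", "IRM", "T_NK")
_STATE_TO_RULE = {"IRO": "IRO", "ARO": "ARO", "IRM": "IRM", "CD8_T": "T_NK"}


def state_recovery_accuracy(
    fold: float = 8.0,
    seed: int = 3,
    tau: float = 0.5,
    cells_per_sample: int = 320,
    n_genes: int = 1500,
) -> float:
    """Fraction of cells whose assigned state matches the planted truth.

    Cells planted in a state without a dedicated signature (baseline
    oligodendrocyte and miscellaneous states) are counted correct when they
    come out ``unassigned``.
    """
    design = simulate.default_design(cells_per_sample=cells_per_sample, seed=seed)
    adata = simulate.generate_counts(
        design, simulate.default_profiles(fold=fold), n_genes=n_genes
    )
    norm = states.normalize_log(adata)
    scores = states.score_signatures(norm)
    assigned = states.assign_states(
        scores, [(name, tau) for name in DEFAULT_ASSIGN_ORDER]
    )
    truth = adata.obs["true_state"].to_numpy()
    expected = np.array([_STATE_TO_RULE.get(t, "unassigned") for t in truth])
    return float((assigned["state"].to_numpy() == expected).mean())
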