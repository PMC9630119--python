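"""Per-sample cell-state proportions and compositional change testing.

Cluster abundances from scRNA-seq are compositional: a sample contributes a
fixed number of cells split across states, and sample-to-sample variation is
overdispersed relative to a multinomial. Each state is therefore tested
state-vs-rest with a beta-binomial likelihood-ratio test against a two-level
group factor: the null model shares one mean proportion across groups, the
alternative gives each group its own mean, and both share a per-state
overdispersion estimated by maximum likelihood. P-values come from the
chi-squared distribution with 1 df and are Benjamini-Hochberg adjusted
across states. The default decision threshold is a deliberately permissive
FDR of 0.4, suited to flagging subtle compositional shifts for follow-up
rather than confirmatory inference.

Boxplot summaries use the Tukey convention: quartiles by linear
interpolation, whiskers to the most extreme point within 1.5x IQR of the
box, everything beyond an outlier.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.4


@dataclasses.dataclass
class CompositionTable:
    """Sample x state cell counts with per-sample metadata.

    ``counts`` is indexed by sample id with one integer column per state;
    ``metadata`` is indexed identically and carries grouping columns such as
    age, genotype and tissue.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    #: free-form annotations, e.g. planted ground truth from a simulation
    info: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.counts.index]
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.rint(values)):
            raise ValueError("counts must be integers")

    @property
    def states(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)  # zero-cell rows become NaN

    def empty_samples(self) -> list[str]:
        return list(self.counts.index[self.counts.sum(axis=1) == 0])


@dataclasses.dataclass
class CompositionTestResult:
    """Per-state beta-binomial LRT outcomes at a configured FDR."""

    table: pd.DataFrame  # columns: state, effect_logodds, p, p_adjusted, significant
    fdr: float
    groups: tuple[str, str]
    skipped: dict[str, str]

    def significant_states(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "state"])

    def to_dict(self) -> dict:
        return {
            "fdr": self.fdr,
            "groups": list(self.groups),
            "skipped": self.skipped,
            "states": self.table.to_dict(orient="records"),
        }


def proportions_per_sample(
    assignment: pd.DataFrame, metadata: pd.DataFrame
) -> CompositionTable:
    """Tabulate per-sample state counts from a per-cell assignment.

    ``assignment`` needs columns ``sample_id`` and ``state`` (one row per
    cell, the ``unassigned`` label is kept as its own state). ``metadata``
    is indexed by sample id; samples present in the metadata but receiving
    no cells appear as zero rows and are flagged in the log.
    """
    for col in ("sample_id", "state"):
        if col not in assignment.columns:
            raise KeyError(f"assignment is missing column {col!r}")
    if assignment["sample_id"].isna().any():
        raise ValueError("cell(s) with missing sample_id")
    counts = pd.crosstab(assignment["sample_id"], assignment["state"])
    counts = counts.reindex(index=metadata.index, fill_value=0)
    counts.columns.name = None
    counts.index.name = "sample_id"
    table = CompositionTable(counts=counts, metadata=metadata.copy())
    empty = table.empty_samples()
    if empty:
        logger.warning("samples with zero cells (proportions undefined): %s", empty)
    return table


def five_number(values: np.ndarray) -> dict:
    """Median, linear-interpolation quartiles, 1.5x-IQR whiskers, outliers."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
    }


def boxplot_summary(table: CompositionTable, group_keys: list[str]) -> pd.DataFrame:
    """Boxplot statistics of per-sample proportions per (group, state).

    One row per combination of grouping values and state, mirroring the
    per-sample-dot boxplot presentation of cluster proportions.
    """
    props = table.proportions.dropna(how="all")
    meta = table.metadata.loc[props.index, group_keys]
    rows = []
    grouped = props.groupby([meta[k] for k in group_keys], sort=True)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for state in table.states:
            summary = five_number(sub[state].to_numpy())
            rows.append({**dict(zip(group_keys, key)), "state": state, **summary})
    return pd.DataFrame(rows)


def _bb_loglik(y: np.ndarray, n: np.ndarray, mu: float, s: float) -> float:
    """Beta-binomial log-likelihood with mean mu and concentration s."""
    a, b = mu * s, (1.0 - mu) * s
    return float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(y + 1)
            - special.gammaln(n - y + 1)
            + special.gammaln(y + a)
            + special.gammaln(n - y + b)
            - special.gammaln(n + a + b)
            + special.gammaln(a + b)
            - special.gammaln(a)
            - special.gammaln(b)
        )
    )


def _unpack_mu(theta: float) -> float:
    return float(np.clip(special.expit(theta), 1e-12, 1 - 1e-12))


def _unpack_s(theta: float) -> float:
    return float(np.clip(np.exp(theta), 1e-8, 1e12))


def _fit_null(y: np.ndarray, n: np.ndarray) -> tuple[float, float, float]:
    mu0 = float(np.clip(y.sum() / n.sum(), 1e-9, 1 - 1e-9))

    def nll(theta):
        return -_bb_loglik(y, n, _unpack_mu(theta[0]), _unpack_s(theta[1]))

    best = None
    for s0 in (10.0, 1e3):
        res = optimize.minimize(
            nll, [special.logit(mu0), np.log(s0)], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    return _unpack_mu(best.x[0]), _unpack_s(best.x[1]), -float(best.fun)


def _fit_alt(
    y: np.ndarray, n: np.ndarray, g: np.ndarray, s_init: float
) -> tuple[float, float, float, float]:
    mus = []
    for gi in (0, 1):
        sel = g == gi
        mus.append(float(np.clip(y[sel].sum() / max(n[sel].sum(), 1), 1e-9, 1 - 1e-9)))

    def nll(theta):
        mu0, mu1 = _unpack_mu(theta[0]), _unpack_mu(theta[1])
        s = _unpack_s(theta[2])
        sel = g == 1
        return -(
            _bb_loglik(y[~sel], n[~sel], mu0, s) + _bb_loglik(y[sel], n[sel], mu1, s)
        )

    best = None
    for s0 in (s_init, 10.0):
        res = optimize.minimize(
            nll,
            [special.logit(mus[0]), special.logit(mus[1]), np.log(s0)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    return (
        _unpack_mu(best.x[0]),
        _unpack_mu(best.x[1]),
        _unpack_s(best.x[2]),
        -float(best.fun),
    )


def beta_binomial_lrt(
    y: np.ndarray, n: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """State-vs-rest beta-binomial likelihood-ratio test for one state.

    Returns ``(effect, p)`` where ``effect`` is the log-odds difference
    ``logit(mu_group1) - logit(mu_group0)`` and ``p`` is the chi-squared
    (1 df) tail of the likelihood ratio. Estimated fits are guarded so the
    alternative never scores below the null.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    group = np.asarray(group)
    _, _, ll0 = _fit_null(y, n)
    s_init = 10.0
    mu0, mu1, _, ll1 = _fit_alt(y, n, group, s_init)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    effect = float(special.logit(mu1) - special.logit(mu0))
    return effect, p


def test_composition(
    table: CompositionTable,
    group_factor: str,
    fdr: float = DEFAULT_FDR,
    group_order: tuple | None = None,
) -> CompositionTestResult:
    """Test every state for a compositional shift between two groups.

    ``group_factor`` names a metadata column with exactly two levels, each
    covering at least two samples. States observed in no sample, or
    occupying all cells of every sample (no 'rest' to compare against), are
    skipped with a log note. The ``significant`` flag marks states with
    BH-adjusted p at or below ``fdr``.
    """
    levels = group_order or tuple(sorted(table.metadata[group_factor].unique()))
    if len(levels) != 2:
        raise ValueError(f"group factor must have exactly 2 levels, got {levels}")
    g = table.metadata[group_factor].map({levels[0]: 0, levels[1]: 1})
    if g.isna().any():
        raise ValueError("samples outside the two requested groups")
    if (g == 0).sum() < 2 or (g == 1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    n = table.counts.sum(axis=1).to_numpy()
    keep = n > 0
    g_arr = g.to_numpy()[keep]
    n = n[keep]
    rows, skipped = [], {}
    for state in table.states:
        y = table.counts[state].to_numpy()[keep]
        if y.sum() == 0:
            skipped[state] = "state absent from all samples"
            logger.info("skipping state %s: absent everywhere", state)
            continue
        if np.all(y == n):
            skipped[state] = "state occupies 100% of every sample"
            logger.info("skipping state %s: no rest to compare against", state)
            continue
        effect, p = beta_binomial_lrt(y, n, g_arr)
        rows.append({"state": state, "effect_logodds": effect, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adjusted"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["p_adjusted"] <= fdr
    else:
        result = pd.DataFrame(
            columns=["state", "effect_logodds", "p", "p_adjusted", "significant"]
        )
    return CompositionTestResult(
        table=result, fdr=fdr, groups=(str(levels[0]), str(levels[1])), skipped=skipped
    )
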