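"""Normalization, signature scoring, state assignment, marker ranking."""
import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from wmglia.states import (
    SignatureSet,
    assign_states,
    default_signatures,
    normalize_log,
    rank_markers,
    score_signature,
    score_signatures,
    top_k_overlap,
)


def _adata(X, genes=None, cells=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def enum_rank_sum_p(x, y):
    """Literal enumeration of the two-sided rank-sum permutation p-value."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    mean_w = n1 * (len(pooled) + 1) / 2
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# normalization


def test_normalize_matches_elementwise_formula(rng):
    X = rng.poisson(3.0, size=(20, 50)) + 1  # +1 keeps libsizes positive
    norm = normalize_log(_adata(X))
    libsize = X.sum(axis=1, keepdims=True)
    expected = np.log1p(X / libsize * 1e4)
    np.testing.assert_allclose(np.asarray(norm.X), expected, rtol=1e-12)
    np.testing.assert_array_equal(norm.layers["counts"], X)


def test_normalize_single_expressed_gene_is_depth_invariant():
    """A cell expressing one gene maps to log(1 + scale) whatever the count."""
    X = np.array([[1.0, 0.0], [700.0, 0.0]])
    norm = normalize_log(_adata(X))
    assert np.allclose(np.asarray(norm.X)[:, 0], np.log1p(1e4))


def test_normalize_rejects_zero_libsize():
    with pytest.raises(ValueError, match="zero library size"):
        normalize_log(_adata(np.array([[0.0, 0.0], [1.0, 2.0]])))


# ---------------------------------------------------------------------------
# signature scoring


def test_score_constant_gene_contributes_zero():
    X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
    sig = SignatureSet("s", ("g0",))
    assert np.allclose(score_signature(_adata(X), sig), 0.0)


def test_score_matches_hand_computed_toy():
    # gene z-scores (population sd): g0 -> [-1.2247.., 0, 1.2247..],
    # g1 -> [-0.7071.., -0.7071.., 1.4142..]; score is their per-cell mean
    X = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 3.0]])
    sig = SignatureSet("s", ("g0", "g1"))
    scores = score_signature(_adata(X), sig)
    expected = np.array(
        [(-1.224744871 - 0.707106781) / 2, -0.707106781 / 2, (1.224744871 + 1.414213562) / 2]
    )
    np.testing.assert_allclose(scores, expected, atol=1e-8)


def test_score_invariant_to_gene_order(rng):
    X = rng.normal(size=(30, 6))
    genes = [f"g{j}" for j in range(6)]
    adata = _adata(X, genes)
    perm = rng.permutation(6)
    shuffled = _adata(X[:, perm], [genes[j] for j in perm])
    sig = SignatureSet("s", ("g1", "g3", "g5"))
    np.testing.assert_allclose(
        score_signature(adata, sig), score_signature(shuffled, sig), atol=1e-12
    )


def test_score_requires_at_least_one_present_gene():
    with pytest.raises(ValueError, match="no gene"):
        score_signature(_adata(np.ones((3, 2))), SignatureSet("s", ("absent",)))


def test_default_signatures_cover_expected_states():
    sigs = default_signatures()
    assert set(sigs) == {"IRO", "ARO", "IRM", "IFN_shared", "T_NK"}
    assert "Serpina3n" in sigs["ARO"].genes and "C4b" in sigs["ARO"].genes
    assert "Stat1" in sigs["IRO"].genes and "Stat1" in sigs["IRM"].genes


# ---------------------------------------------------------------------------
# state assignment


def test_assign_all_below_threshold_is_unassigned():
    scores = pd.DataFrame({"A": [0.1, -2.0], "B": [0.4, 0.2]})
    out = assign_states(scores, [("A", 0.5), ("B", 0.5)])
    assert list(out["state"]) == ["unassigned", "unassigned"]


def test_assign_tie_goes_to_earlier_rule():
    scores = pd.DataFrame({"A": [1.0], "B": [1.0]})
    assert assign_states(scores, [("B", 0.5), ("A", 0.5)])["state"].iloc[0] == "B"
    assert assign_states(scores, [("A", 0.5), ("B", 0.5)])["state"].iloc[0] == "A"


def test_assign_picks_highest_scoring_signature():
    scores = pd.DataFrame({"A": [0.9], "B": [1.8]})
    out = assign_states(scores, [("A", 0.5), ("B", 0.5)])
    assert out["state"].iloc[0] == "B"


def test_assign_empty_rules_errors():
    with pytest.raises(ValueError, match="non-empty"):
        assign_states(pd.DataFrame({"A": [1.0]}), [])


# ---------------------------------------------------------------------------
# marker ranking


def test_identical_groups_give_zero_fc_and_p_near_one(rng):
    block = rng.poisson(2.0, size=(6, 8)).astype(float)
    X = np.vstack([block, block])
    norm = normalize_log(_adata(X + 1))
    labels = np.array(["a"] * 6 + ["b"] * 6)
    # groups hold identical cells, so means agree exactly
    table = rank_markers(norm, labels, "a", "b")
    assert np.allclose(table["avg_log2FC"], 0.0, atol=1e-12)
    assert (table["p"] > 0.9).all()


@pytest.mark.parametrize("sizes", [(3, 4), (4, 4), (5, 6), (8, 8)])
def test_exact_p_equals_enumeration(rng, sizes):
    n1, n2 = sizes
    for _ in range(6):
        x = rng.integers(0, 4, size=n1).astype(float)  # ties guaranteed
        y = rng.integers(0, 4, size=n2).astype(float)
        adata = _adata(np.concatenate([x, y])[:, None] + 1.0)
        norm = normalize_log(adata)
        # build the expected p directly on the normalized values
        vals = np.asarray(norm.X)[:, 0]
        expected = enum_rank_sum_p(vals[:n1], vals[n1:])
        labels = np.array(["a"] * n1 + ["b"] * n2)
        table = rank_markers(norm, labels, "a", "b")
        assert table["p"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_fc_threshold_excludes_small_folds():
    """A gene at 0.9 log2-fold is dropped by the >1 threshold, kept at >0.8."""
    n = 40
    base = np.full(n, 8.0)
    X = np.column_stack([
        np.concatenate([base * 2**0.9, base]),   # planted 0.9 log2-fold
        np.concatenate([base * 2**1.5, base]),   # planted 1.5 log2-fold
        np.tile(np.full(2 * n, 100.0), (1,)).ravel(),  # constant libsize filler
    ])
    labels = np.array(["a"] * n + ["b"] * n)
    adata = _adata(X, genes=["small", "large", "filler"])
    norm = ad.AnnData(
        X=np.log1p(X), obs=adata.obs, var=adata.var
    )  # pre-normalized values; fold survives exactly
    t1 = rank_markers(norm, labels, "a", "b", fc_threshold=1.0)
    t08 = rank_markers(norm, labels, "a", "b", fc_threshold=0.8)
    assert "small" not in set(t1["gene"]) and "large" in set(t1["gene"])
    assert "small" in set(t08["gene"])


def test_bh_adjustment_monotone_in_p(rng):
    X = rng.poisson(4.0, size=(30, 40)).astype(float) + 1
    labels = np.array(["a"] * 15 + ["b"] * 15)
    table = rank_markers(normalize_log(_adata(X)), labels, "a", "b")
    ordered = table.sort_values("p")
    assert (np.diff(ordered["p_adjusted"]) >= -1e-12).all()
    assert (table["p_adjusted"] >= table["p"] - 1e-12).all()


def test_small_group_errors():
    X = np.ones((3, 2))
    labels = np.array(["a", "a", "b"])
    with pytest.raises(ValueError, match="at least 2 cells"):
        rank_markers(_adata(X), labels, "a", "b")


def test_label_permutation_swaps_direction(rng):
    X = rng.poisson(5.0, size=(20, 10)).astype(float) + 1
    norm = normalize_log(_adata(X))
    labels = np.array(["a"] * 10 + ["b"] * 10)
    t_ab = rank_markers(norm, labels, "a", "b").set_index("gene")
    t_ba = rank_markers(norm, labels, "b", "a").set_index("gene")
    np.testing.assert_allclose(
        t_ab["avg_log2FC"], -t_ba.loc[t_ab.index, "avg_log2FC"], atol=1e-12
    )
    np.testing.assert_allclose(t_ab["p"], t_ba.loc[t_ab.index, "p"], atol=1e-12)


# ---------------------------------------------------------------------------
# top-k overlap


def _marker_table(genes):
    return pd.DataFrame(
        {"gene": genes, "p": np.linspace(0, 1, len(genes)), "avg_log2FC": 1.0}
    )


def test_top_k_overlap_identical_tables():
    genes = [f"g{i}" for i in range(60)]
    table = _marker_table(genes)
    assert top_k_overlap(table, table, k=50) == set(genes[:50])


def test_top_k_overlap_disjoint_universes():
    a = _marker_table([f"a{i}" for i in range(20)])
    b = _marker_table([f"b{i}" for i in range(20)])
    assert top_k_overlap(a, b, k=10) == set()


def test_top_k_overlap_matches_set_oracle_and_symmetry(rng):
    pool = [f"g{i}" for i in range(40)]
    a = _marker_table(list(rng.permutation(pool)))
    b = _marker_table(list(rng.permutation(pool)))
    expected = set(a["gene"].head(15)) & set(b["gene"].head(15))
    assert top_k_overlap(a, b, k=15) == expected
    assert top_k_overlap(b, a, k=15) == expected
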