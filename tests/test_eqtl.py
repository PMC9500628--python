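import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_curve

from isogx import eqtl
from isogx.io import ExpressionMatrix


def test_kruskal_hand_example():
    """Two groups (1,2,3) vs (4,5,6): ranks split exactly, H = 3.857."""
    h, p = eqtl.kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
    assert h == pytest.approx(3.8571428571, rel=1e-9)
    assert p == pytest.approx(0.0495, abs=5e-4)


def test_kruskal_degenerate_conventions():
    h, p = eqtl.kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
    assert (h, p) == (0.0, 1.0)
    h, p = eqtl.kruskal_wallis([np.array([1.0, 2.0, 3.0])])
    assert np.isnan(h) and np.isnan(p)


def kruskal_permutation_oracle(groups, n_perm=100_000, seed=0):
    """Monte-Carlo permutation null of the H statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    flat = np.concatenate(groups)
    h_obs, _ = eqtl.kruskal_wallis(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(flat)
        splits = np.split(perm, np.cumsum(sizes)[:-1])
        h, _ = eqtl.kruskal_wallis(list(splits))
        if h >= h_obs - 1e-12:
            count += 1
    return count / n_perm


def test_kruskal_p_within_permutation_ci():
    """The chi-square p of a small layout sits near the exact permutation
    p (the asymptotic reference is known to be approximate at n = 8)."""
    groups = [np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0]), np.array([6.0, 7.0, 8.0])]
    _, p_chi2 = eqtl.kruskal_wallis(groups)
    p_perm = kruskal_permutation_oracle(groups, n_perm=20_000, seed=1)
    se = np.sqrt(p_perm * (1 - p_perm) / 20_000)
    # chi-square approximation tolerance: 4 MC sigmas plus 0.05 asymptotic slack
    assert abs(p_chi2 - p_perm) < 0.05 + 4 * se


@settings(max_examples=50, deadline=None)
@given(shift=st.floats(0.1, 10.0), scale=st.floats(0.1, 5.0))
def test_kruskal_invariant_to_monotone_transform(shift, scale):
    rng = np.random.default_rng(7)
    groups = [rng.normal(size=6), rng.normal(1.0, size=5), rng.normal(2.0, size=4)]
    h1, p1 = eqtl.kruskal_wallis(groups)
    trans = [np.exp(scale * g) + shift for g in groups]
    h2, p2 = eqtl.kruskal_wallis(trans)
    assert h1 == pytest.approx(h2, rel=1e-9)


def test_auc_extremes_and_flip(rng):
    y = np.r_[np.zeros(5), np.ones(5)]
    s = np.arange(10.0)
    assert eqtl.auc(s, y) == 1.0
    assert eqtl.auc(-s, y) == 0.0
    scores = rng.normal(size=10)
    assert eqtl.auc(scores, y) + eqtl.auc(scores, 1 - y) == pytest.approx(1.0)


def test_auc_matches_trapezoidal_integration(rng):
    for _ in range(100):
        n = int(rng.integers(6, 40))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = np.round(rng.normal(size=n), 1)  # ties included
        fpr, tpr, _ = roc_curve(y, s)
        assert eqtl.auc(s, y) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.1, 3.0))
def test_auc_invariant_to_monotone_transform(scale):
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=30)
    s = rng.normal(size=30)
    assert eqtl.auc(s, y) == pytest.approx(eqtl.auc(np.exp(scale * s), y), abs=1e-12)


def test_delong_ci_brackets_auc(rng):
    y = rng.integers(0, 2, size=60)
    s = rng.normal(size=60) + y
    a, lo, hi = eqtl.delong_ci(s, y)
    assert lo <= a <= hi
    assert 0.0 <= lo and hi <= 1.0


def test_eqtl_scan_schema_and_null(cohort):
    pairs = cohort.truth.eqtl_pairs
    res = eqtl.eqtl_scan(pairs, cohort.expression, cohort.genotypes, cohort.sample_meta)
    assert list(res.columns) == [
        "gene_id", "transcript_id", "variant_id", "H", "p_all", "p_healthy",
        "p_inflamed", "significant",
    ] or list(res.columns) == [
        "transcript_id", "variant_id", "H", "p_all", "p_healthy", "p_inflamed", "significant"
    ]
    assert (res["H"].dropna() >= 0).all()
    # flat expression has H near zero
    tpm = cohort.expression.tpm.copy()
    tpm.iloc[:, :] = 5.0
    flat = eqtl.eqtl_scan(
        pairs, ExpressionMatrix(tpm=tpm), cohort.genotypes, cohort.sample_meta
    )
    assert (flat["H"] == 0.0).all()
    assert (flat["p_all"] == 1.0).all()


def test_perfect_feature_gives_in_sample_auc_one(cohort):
    meta = cohort.sample_meta
    feats = pd.DataFrame({"oracle": meta["response"].astype(float)}, index=meta.index)
    res = eqtl.random_forest_validate(
        feats, meta["response"].astype(int), seed=0, n_trees=100, mode="in_sample"
    )
    assert res.auc == 1.0


def test_forest_probabilities_deterministic_under_seed(cohort, rng):
    meta = cohort.sample_meta
    feats = pd.DataFrame(
        rng.normal(size=(len(meta), 4)), index=meta.index, columns=list("abcd")
    )
    r1 = eqtl.random_forest_validate(feats, meta["response"].astype(int), seed=5, n_trees=50)
    r2 = eqtl.random_forest_validate(feats, meta["response"].astype(int), seed=5, n_trees=50)
    pd.testing.assert_series_equal(r1.probabilities, r2.probabilities)


def test_permuted_labels_give_chance_oob_auc(cohort):
    """OOB AUC under label permutation hovers around one half."""
    meta = cohort.sample_meta
    planted = list(cohort.truth.planted_dei["transcript_id"][:5])
    feats = np.log2(cohort.expression.tpm.loc[planted].T + 1.0)
    aucs = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        perm = pd.Series(
            rng.permutation(meta["response"].to_numpy()), index=meta.index
        ).astype(int)
        if perm.nunique() < 2:
            continue
        res = eqtl.random_forest_validate(feats, perm, seed=seed, n_trees=200, mode="oob")
        aucs.append(res.auc)
    inside = np.mean([(0.2 <= a <= 0.8) for a in aucs])
    assert inside >= 0.9


def test_planted_signal_beats_permuted_labels(cohort):
    meta = cohort.sample_meta
    planted = list(cohort.truth.planted_dei["transcript_id"][:8])
    feats = np.log2(cohort.expression.tpm.loc[planted].T + 1.0)
    labels = meta["response"].astype(int)
    wins = 0
    for seed in range(8):
        real = eqtl.random_forest_validate(feats, labels, seed=seed, n_trees=200).auc
        rng = np.random.default_rng(100 + seed)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=meta.index)
        null = eqtl.random_forest_validate(feats, perm, seed=seed, n_trees=200).auc
        wins += int(real > null)
    assert wins >= 7


def test_single_class_labels_rejected(cohort):
    meta = cohort.sample_meta
    feats = pd.DataFrame({"x": np.zeros(len(meta))}, index=meta.index)
    with pytest.raises(ValueError, match="single class"):
        eqtl.random_forest_validate(feats, pd.Series(1, index=meta.index), seed=0)


def test_network_expansion_rules():
    edges = pd.DataFrame(
        {
            "gene_a": ["aux2", "aux2", "aux1", "far", "sel1"],
            "gene_b": ["sel1", "sel2", "sel1", "other", "sel3"],
        }
    )
    nodes, kept = eqtl.expand_network({"sel1", "sel2", "sel3"}, edges)
    roles = nodes.set_index("gene_id")["role"]
    assert roles["aux2"] == "auxiliary"       # touches two selected genes
    assert "aux1" not in roles.index          # touches only one
    assert "far" not in roles.index
    # sel1-sel2 connect through one auxiliary node; sel1-sel3 directly
    conn = nodes.set_index("gene_id")["connected_within_one_aux"]
    assert conn["sel1"] and conn["sel2"] and conn["sel3"]


def test_network_expansion_order_invariant(rng):
    genes = [f"g{i}" for i in range(30)]
    edges = pd.DataFrame(
        {"gene_a": rng.choice(genes, 80), "gene_b": rng.choice(genes, 80)}
    )
    edges = edges[edges["gene_a"] != edges["gene_b"]].drop_duplicates()
    selected = set(genes[:6])
    n1, e1 = eqtl.expand_network(selected, edges)
    n2, e2 = eqtl.expand_network(selected, edges.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_frame_equal(
        n1.sort_values("gene_id").reset_index(drop=True),
        n2.sort_values("gene_id").reset_index(drop=True),
    )


def bfs_distance(adj, src, dst, cap=3):
    """Hand-rolled breadth-first search distance, capped."""
    if src == dst:
        return 0
    frontier, seen, d = {src}, {src}, 0
    while frontier and d < cap:
        d += 1
        frontier = {nb for x in frontier for nb in adj.get(x, ())} - seen
        if dst in frontier:
            return d
        seen |= frontier
    return cap + 1


def test_connectivity_matches_bfs_oracle(rng):
    genes = [f"g{i}" for i in range(25)]
    edges = pd.DataFrame(
        {"gene_a": rng.choice(genes, 60), "gene_b": rng.choice(genes, 60)}
    )
    edges = edges[edges["gene_a"] != edges["gene_b"]].drop_duplicates()
    selected = set(genes[:5])
    nodes, kept = eqtl.expand_network(selected, edges)
    adj: dict = {}
    for a, b in zip(kept["gene_a"], kept["gene_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for _, row in nodes[nodes["role"] == "selected"].iterrows():
        expect = any(
            bfs_distance(adj, row["gene_id"], other) <= 2
            for other in selected - {row["gene_id"]}
        )
        assert row["connected_within_one_aux"] == expect
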