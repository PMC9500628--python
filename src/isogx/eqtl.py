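"""eQTL testing, machine-learning validation and network expansion for the
selected candidate loci.

Transcript-wise expression-quantitative-trait tests use the Kruskal-Wallis
H statistic over raw dosage groups {0,1,2}, run on all biopsies pooled and
within each tissue stratum. Candidate feature sets are validated with a
random-forest classifier and ROC analysis (AUC with a DeLong confidence
interval); the selected gene set is expanded over a protein-interaction
edge list by admitting auxiliary genes that touch at least two selected
genes.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Groups are expression values per genotype class; empty groups must be
    dropped by the caller. All-tied data returns (0, 1); a single non-empty
    group returns (nan, nan) since no contrast exists.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        return np.nan, np.nan
    if sum(len(g) for g in groups) < 3:
        return np.nan, np.nan
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def eqtl_scan(
    pairs: pd.DataFrame,
    expr,
    genotypes,
    sample_meta: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis eQTL tests for (transcript, variant) pairs.

    ``pairs`` needs columns transcript_id, variant_id (and optionally
    gene_id, carried through). Expression is log2(TPM+1); each biopsy
    sample's genotype comes from its patient. Three p-values per pair:
    all biopsies pooled, healthy only, inflamed only; strata with fewer
    than two genotype groups give a missing p.
    """
    log2 = np.log2(expr.tpm + 1.0)
    dos = genotypes.dosages
    patient_of = sample_meta["patient_id"]
    state = sample_meta["tissue_state"]
    rows = []
    for _, pr in pairs.iterrows():
        tx, vid = pr["transcript_id"], pr["variant_id"]
        y = log2.loc[tx]
        g = dos[vid].reindex(patient_of.values)
        g.index = patient_of.index
        rec = {"transcript_id": tx, "variant_id": vid}
        if "gene_id" in pr.index:
            rec["gene_id"] = pr["gene_id"]
        for label, mask in (
            ("all", pd.Series(True, index=sample_meta.index)),
            ("healthy", state == "healthy"),
            ("inflamed", state == "inflamed"),
        ):
            yy = y[mask & g.notna()]
            gg = g[mask & g.notna()]
            grouped = [yy[gg == lvl].to_numpy() for lvl in (0.0, 1.0, 2.0)]
            h, p = kruskal_wallis(grouped)
            if label == "all":
                rec["H"] = h
            rec[f"p_{label}"] = p
        finite = [rec[f"p_{s}"] for s in ("all", "healthy", "inflamed") if not np.isnan(rec[f"p_{s}"])]
        rec["significant"] = bool(finite and min(finite) < p_max)
        rows.append(rec)
    cols = ["transcript_id", "variant_id", "H", "p_all", "p_healthy", "p_inflamed", "significant"]
    if "gene_id" in pairs.columns:
        cols.insert(0, "gene_id")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong asymptotic confidence interval (clipped to [0,1])."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    a = auc(s, y)
    all_r = _midrank(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - _midrank(pos)) / n            # placement values of positives
    v01 = 1.0 - (all_r[m:] - _midrank(neg)) / m      # placement values of negatives
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(var)
    return a, float(np.clip(a - half, 0.0, 1.0)), float(np.clip(a + half, 0.0, 1.0))


# ---------------------------------------------------------------------------
# random forest validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ValidationResult:
    feature_set: str
    mode: str
    probabilities: pd.Series
    auc: float
    ci_low: float
    ci_high: float


def random_forest_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    n_trees: int = 500,
    mode: str = "oob",
    feature_set: str = "",
) -> ValidationResult:
    """Bagged-tree class probabilities and ROC summary for one feature set.

    ``mode``: 'oob' (out-of-bag probabilities, the honest internal
    estimate), 'in_sample' (probabilities on the training data; optimistic
    at small n) or 'cv' (5-fold stratified cross-validated probabilities).
    """
    y = labels.loc[features.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need >= 2 samples per class")
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be complete")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        bootstrap=True,
    )
    if mode == "cv":
        cv = StratifiedKFold(n_splits=min(5, min(np.bincount(y.astype(int)))), shuffle=True, random_state=seed)
        prob = cross_val_predict(rf, X, y, cv=cv, method="predict_proba")[:, 1]
    else:
        rf.fit(X, y)
        if mode == "oob":
            prob = rf.oob_decision_function_[:, 1]
        elif mode == "in_sample":
            prob = rf.predict_proba(X)[:, 1]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    a, lo, hi = delong_ci(prob, y)
    return ValidationResult(
        feature_set=feature_set,
        mode=mode,
        probabilities=pd.Series(prob, index=features.index),
        auc=a,
        ci_low=lo,
        ci_high=hi,
    )


# ---------------------------------------------------------------------------
# interaction-network expansion
# ---------------------------------------------------------------------------

def expand_network(selected: set[str], edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene set with auxiliary genes touching >= 2 selected genes.

    Returns (nodes, kept_edges). Nodes carry their role (selected or
    auxiliary) and, for selected genes, whether they connect to another
    selected gene directly or through at most one auxiliary node.
    """
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    aux = []
    for node in g.nodes:
        if node in selected:
            continue
        touched = {nb for nb in g.neighbors(node) if nb in selected}
        if len(touched) >= 2:
            aux.append(node)
    keep_nodes = set(selected) | set(aux)
    sub = g.subgraph(keep_nodes)
    rows = []
    for node in sorted(keep_nodes):
        role = "selected" if node in selected else "auxiliary"
        connected = False
        if role == "selected" and node in sub:
            for other in selected - {node}:
                if other in sub and nx.has_path(sub, node, other):
                    if nx.shortest_path_length(sub, node, other) <= 2:
                        connected = True
                        break
        rows.append({"gene_id": node, "role": role, "connected_within_one_aux": connected})
    kept_edges = pd.DataFrame(
        [(a, b) for a, b in sub.edges], columns=["gene_a", "gene_b"]
    ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return pd.DataFrame(rows), kept_edges
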