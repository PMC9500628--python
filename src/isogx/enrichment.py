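"""GO over-representation of DEI gene sets.

Upper-tail hypergeometric test per term with Benjamini-Hochberg q-values,
applied per namespace within each run (approach x direction class), and the
union of genes from all significant terms as the candidate set for genomic
integration. The annotation file is taken as already propagated up the GO
graph; no DAG handling happens here.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NAMESPACES = ["BP", "CC", "MF"]


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: draw-set genes in the term, n: draw-set size, K: universe genes in
    the term, N: universe size. Exchangeable in (n, K).
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class EnrichmentThresholds:
    p_max: float = 0.01
    q_max: float = 0.05
    min_term_size: int = 2


def enrich(
    dei_genes: set[str],
    go: pd.DataFrame,
    universe: set[str],
    thresholds: EnrichmentThresholds | None = None,
    run: str = "",
) -> pd.DataFrame:
    """Significant over-represented terms for one gene set.

    BH is applied separately per namespace within this run. Terms with
    fewer than ``min_term_size`` universe genes are skipped. Records are
    filtered at p < p_max and q < q_max and sorted by (q, p).
    """
    th = thresholds or EnrichmentThresholds()
    if not dei_genes <= universe:
        raise ValueError("DEI genes must be a subset of the universe")
    dei = sorted(dei_genes)
    n = len(dei)
    N = len(universe)
    rows = []
    go_u = go[go["gene_id"].isin(universe)]
    for ns in NAMESPACES:
        sub = go_u[go_u["namespace"] == ns]
        ns_rows = []
        for term, grp in sub.groupby("term_id"):
            members = set(grp["gene_id"])
            K = len(members)
            if K < th.min_term_size:
                continue
            hits = sorted(members & set(dei))
            k = len(hits)
            p = hypergeom_test(k, n, K, N)
            ns_rows.append(
                {
                    "run": run,
                    "namespace": ns,
                    "term_id": term,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": p,
                    "gene_ids": ",".join(hits),
                }
            )
        if ns_rows:
            df = pd.DataFrame(ns_rows)
            df["q"] = bh_adjust(df["p"].to_numpy())
            rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["run", "namespace", "term_id", "k", "n", "K", "N", "p", "gene_ids", "q"]
        )
    out = pd.concat(rows, ignore_index=True)
    out = out[(out["p"] < th.p_max) & (out["q"] < th.q_max)]
    return out.sort_values(["q", "p", "term_id"]).reset_index(drop=True)


def dei_genes_for_run(meta_records: pd.DataFrame, tx2gene: pd.Series, cls: str) -> set[str]:
    """Genes with any transcript in the given direction class."""
    tx = meta_records.index[meta_records["class"] == cls]
    return set(tx2gene.reindex(tx).dropna())


def candidate_union(enrichment_runs: list[pd.DataFrame]) -> set[str]:
    """Union of hit genes across all significant terms of all runs."""
    if not enrichment_runs:
        raise ValueError("need at least one enrichment run")
    genes: set[str] = set()
    for df in enrichment_runs:
        for s in df["gene_ids"]:
            if s:
                genes.update(s.split(","))
    return genes
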