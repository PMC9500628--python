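"""Bulk expression deconvolution against a cell-type signature matrix.

Estimates per-sample immune-cell fractions by non-negative least squares
on the linear (TPM) scale and aggregates them into the three covariate
fractions used by the differential-expression models: T cells,
monocytes/macrophages and dendritic cells. NNLS is deterministic and, in
the noiseless regime, recovers the generating simplex exactly; it stands
in contract-compatibly for support-vector-regression deconvolution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import ExpressionMatrix, GeneModel

AGGREGATE_CLASSES = ["T", "mono_mac", "dendritic"]

#: canonical partition of the LM22 cell types into the three covariate
#: classes (plus "other"); applied when an LM22-style signature is supplied
LM22_AGGREGATION = {
    "T cells CD8": "T",
    "T cells CD4 naive": "T",
    "T cells CD4 memory resting": "T",
    "T cells CD4 memory activated": "T",
    "T cells follicular helper": "T",
    "T cells regulatory (Tregs)": "T",
    "T cells gamma delta": "T",
    "Monocytes": "mono_mac",
    "Macrophages M0": "mono_mac",
    "Macrophages M1": "mono_mac",
    "Macrophages M2": "mono_mac",
    "Dendritic cells resting": "dendritic",
    "Dendritic cells activated": "dendritic",
}


def summarize_to_genes(expr: ExpressionMatrix, genes: GeneModel, lenient: bool = False) -> pd.DataFrame:
    """Gene-level TPM table: sum of member-transcript TPMs (genes x samples)."""
    unmapped = [t for t in expr.transcript_ids if t not in genes.tx2gene.index]
    if unmapped:
        if not lenient:
            raise ValueError(f"unmapped transcripts: {unmapped[:5]}")
        warnings.warn(f"skipping {len(unmapped)} unmapped transcripts")
    mapped = expr.tpm.loc[[t for t in expr.transcript_ids if t in genes.tx2gene.index]]
    return mapped.groupby(genes.tx2gene.reindex(mapped.index)).sum()


def deconvolve_sample(
    mixture: pd.Series,
    signature: pd.DataFrame,
    min_gene_overlap: float = 0.5,
) -> pd.Series:
    """Fractions for one sample: argmin ||S f - m||^2 s.t. f >= 0, sum-1.

    ``mixture`` is a gene-level TPM profile; only signature genes present in
    it are used, and at least ``min_gene_overlap`` of them must be present.
    A degenerate all-zero solution falls back to uniform fractions with a
    warning.
    """
    common = [g for g in signature.index if g in mixture.index]
    if len(common) < min_gene_overlap * len(signature.index):
        raise ValueError(
            f"only {len(common)}/{len(signature.index)} signature genes present in mixture"
        )
    S = signature.loc[common].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("restricted signature matrix is rank deficient")
    m = mixture.loc[common].to_numpy(dtype=float)
    f, _ = nnls(S, m)
    total = f.sum()
    if total <= 0:
        warnings.warn("degenerate all-zero NNLS solution; returning uniform fractions")
        f = np.full(S.shape[1], 1.0 / S.shape[1])
    else:
        f = f / total
    return pd.Series(f, index=signature.columns)


def deconvolve(
    gene_tpm: pd.DataFrame,
    signature: pd.DataFrame,
    min_gene_overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-sample cell fractions (samples x cell types), rows sum to 1."""
    rows = {
        s: deconvolve_sample(gene_tpm[s], signature, min_gene_overlap)
        for s in gene_tpm.columns
    }
    return pd.DataFrame(rows).T


def aggregate(fractions: pd.DataFrame, aggregation_map: dict[str, str]) -> pd.DataFrame:
    """Sum member cell-type fractions into the three covariate classes.

    Cell types mapped to classes outside :data:`AGGREGATE_CLASSES` (e.g.
    "other") are ignored; an empty class yields 0.
    """
    missing = [c for c in fractions.columns if c not in aggregation_map]
    if missing:
        raise ValueError(f"aggregation map does not cover cell types: {missing}")
    out = pd.DataFrame(0.0, index=fractions.index, columns=AGGREGATE_CLASSES)
    for ct in fractions.columns:
        cls = aggregation_map[ct]
        if cls in AGGREGATE_CLASSES:
            out[cls] += fractions[ct]
    return out


def run_deconvolution(
    expr: ExpressionMatrix,
    genes: GeneModel,
    signature: pd.DataFrame,
    aggregation_map: dict[str, str],
    min_gene_overlap: float = 0.5,
) -> pd.DataFrame:
    """Full stage: summarize to genes, deconvolve, append aggregate columns."""
    gene_tpm = summarize_to_genes(expr, genes)
    frac = deconvolve(gene_tpm, signature, min_gene_overlap)
    agg = aggregate(frac, aggregation_map)
    return pd.concat([frac, agg.add_prefix("agg_")], axis=1)
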