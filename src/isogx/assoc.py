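"""Candidate-gene-window genotype association for treatment response.

Per-variant binary logistic Wald regression (response ~ minor-allele dosage
+ clinical covariates + first four genotype principal components), restricted
to +/-100 kb windows around candidate genes; per-region multiple-testing
adjustment through the eigenvalue-based effective number of tests (Li & Ji)
with a Sidak correction; and greedy LD pruning at r^2 <= 0.5 to independent
signals.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

GWAS_COVARIATES = [
    "age_at_diagnosis",
    "sex",
    "azathioprine_use",
    "aminosalicylate_use",
    "corticosteroid_use",
]


# ---------------------------------------------------------------------------
# QC and orientation
# ---------------------------------------------------------------------------

def variant_qc(gm: GenotypeMatrix, maf_min: float = 0.01, max_missing: float = 0.10) -> pd.Index:
    """Variants passing MAF and missingness filters."""
    D = gm.dosages
    missing = D.isna().mean(axis=0)
    af = D.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = (missing <= max_missing) & (maf >= maf_min)
    return D.columns[keep]


def minor_dosages(gm: GenotypeMatrix) -> pd.DataFrame:
    """Dosages re-oriented so each column counts the cohort-wide minor allele."""
    D = gm.dosages.astype(float)
    is_alt_minor = gm.minor_allele_orientation()
    out = D.copy()
    flip = [c for c in D.columns if not is_alt_minor[c]]
    out[flip] = 2.0 - D[flip]
    return out


def group_allele_freqs(dosage: pd.Series, response: pd.Series) -> tuple[float, float]:
    """Minor-allele frequency in responders and non-responders.

    ``dosage`` must already be minor-allele oriented; missing genotypes are
    excluded from both numerator and denominator.
    """
    out = []
    for grp in (1, 0):
        d = dosage[response == grp].dropna()
        if len(d) == 0:
            raise ValueError("empty response group")
        out.append(float(d.sum() / (2.0 * len(d))))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

def ld_thin(dosages: pd.DataFrame, r2_max: float = 0.2) -> list[str]:
    """Greedy positional thinning: keep a variant unless it correlates at
    r^2 > r2_max with an already-kept one. Used before PCA so local LD does
    not dominate the components."""
    kept: list[str] = []
    X = dosages.fillna(dosages.mean())
    arr = {c: X[c].to_numpy() for c in X.columns}
    for c in X.columns:
        ok = True
        for k in kept:
            r = np.corrcoef(arr[c], arr[k])[0, 1]
            if np.isfinite(r) and r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


def genotype_pca(gm: GenotypeMatrix, n_components: int = 4, thin_r2: float | None = 0.2) -> pd.DataFrame:
    """First principal components of the column-standardized dosage matrix.

    Constant columns are dropped; missing dosages are mean-imputed before
    standardization. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    D = gm.dosages
    if D.shape[0] < 5:
        raise ValueError("need >= 5 patients for genotype PCA")
    qc = variant_qc(gm)
    D = D[qc]
    if thin_r2 is not None:
        D = D[ld_thin(D, thin_r2)]
    X = D.fillna(D.mean()).to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep]
    if X.shape[1] < n_components:
        raise ValueError("not enough informative variants for PCA")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_components] * S[:n_components]
    for j in range(n_components):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            pcs[:, j] *= -1.0
    return pd.DataFrame(pcs, index=gm.patient_ids, columns=[f"PC{i+1}" for i in range(n_components)])


# ---------------------------------------------------------------------------
# Wald logistic regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WaldResult:
    beta: float
    se: float
    z: float
    p: float
    converged: bool
    separated: bool = False


def wald_logistic(response: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None = None) -> WaldResult:
    """Maximum-likelihood logistic fit; Wald beta/SE/p for the dosage term.

    Missing dosages must already be excluded. Perfect separation (or
    non-convergence) is flagged and the p-value set missing rather than 0.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    cols = [np.ones_like(y), np.asarray(dosage, dtype=float)]
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("model matrix is rank deficient")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return WaldResult(np.nan, np.nan, np.nan, np.nan, converged=False, separated=True)
    beta = res.params[1]
    se = res.bse[1]
    converged = bool(res.mle_retvals.get("converged", True))
    separated = (not converged) or (not np.isfinite(se)) or se > 1e3 or abs(beta) > 50
    if separated:
        return WaldResult(float(beta), float(se), np.nan, np.nan, converged=converged, separated=True)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(float(beta), float(se), float(z), float(p), converged=converged)


def wald_p_from_summary(beta: float, se: float) -> float:
    """p = 2(1 - Phi(|beta/SE|)); consistency check for printed summaries."""
    if se <= 0:
        raise ValueError("SE must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


# ---------------------------------------------------------------------------
# windows, Meff, pruning
# ---------------------------------------------------------------------------

def window_integrate(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    flank: int = 100_000,
) -> dict[str, list[str]]:
    """Variants within [start - flank, end + flank) of each candidate gene.

    ``genes``: index gene_id, columns chrom/start/end (0-based half-open).
    ``variants``: index variant id, columns chrom/pos (1-based). A variant
    may appear in several overlapping windows.
    """
    out: dict[str, list[str]] = {}
    pos0 = variants["pos"].to_numpy() - 1
    for gid, g in genes.iterrows():
        lo = max(0, int(g["start"]) - flank)
        hi = int(g["end"]) + flank
        on_chrom = (variants["chrom"] == g["chrom"]).to_numpy()
        inside = on_chrom & (pos0 >= lo) & (pos0 < hi)
        out[str(gid)] = list(variants.index[inside])
    return out


def meff_li_ji(corr: np.ndarray) -> float:
    """Effective number of tests from the eigenvalues of a correlation
    matrix: Meff = sum over eigenvalues of 1{l >= 1} + (l - floor(l))."""
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    lam = np.linalg.eigvalsh(corr)
    # the floor in f is discontinuous; snap near-integer eigenvalues first
    lam = np.round(np.clip(lam, 0.0, None), 9)
    meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return min(max(meff, 1.0), float(corr.shape[0]))


def meff_adjust(p_values: np.ndarray, dosages: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Sidak-style region adjustment: q = 1 - (1 - p)^Meff, capped at 1."""
    if dosages.shape[1] == 0:
        raise ValueError("region has no variants")
    if dosages.shape[1] == 1:
        meff = 1.0
    else:
        X = dosages.fillna(dosages.mean()).to_numpy(dtype=float)
        sd = X.std(axis=0)
        X = X[:, sd > 0]
        meff = meff_li_ji(np.corrcoef(X.T)) if X.shape[1] > 1 else 1.0
    q = 1.0 - (1.0 - np.asarray(p_values, dtype=float)) ** meff
    return np.minimum(q, 1.0), meff


def ld_prune(
    records: pd.DataFrame,
    dosages: pd.DataFrame,
    r2_max: float = 0.5,
    order: str = "p",
) -> list[str]:
    """Greedy pruning to independent signals.

    Accept the best remaining variant (lowest p; ties by position then id),
    discard every remaining variant with squared Pearson dosage correlation
    > r2_max against any accepted one. ``order='input'`` keeps the given
    row order instead, mirroring tools that retain by input order.
    """
    if order == "p":
        ordered = records.sort_values(["p", "pos", "variant_id"])
    elif order == "input":
        ordered = records
    else:
        raise ValueError(f"unknown order {order!r}")
    kept: list[str] = []
    X = dosages.fillna(dosages.mean())
    for vid in ordered["variant_id"]:
        ok = True
        for k in kept:
            r = np.corrcoef(X[vid].to_numpy(), X[k].to_numpy())[0, 1]
            if np.isfinite(r) and r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(vid)
    return kept


# ---------------------------------------------------------------------------
# full stage
# ---------------------------------------------------------------------------

def run_gwas(
    gm: GenotypeMatrix,
    patient_meta: pd.DataFrame,
    candidate_genes: list[str],
    gene_coords: pd.DataFrame,
    flank: int = 100_000,
    q_max: float = 0.05,
    r2_max: float = 0.5,
    n_pcs: int = 4,
) -> pd.DataFrame:
    """Association over candidate-gene windows; returns the per-variant
    table with region q-values and the LD-independent flag.

    Columns mirror a regional association report: locus, variant_id, chrom,
    pos, p, q, beta, se, af_resp, af_non, meff, significant, independent.
    """
    meta = patient_meta.loc[gm.patient_ids]
    qc_pass = variant_qc(gm)
    mdos = minor_dosages(gm)[qc_pass]
    pcs = genotype_pca(gm, n_components=n_pcs)
    covar = pd.concat([meta[GWAS_COVARIATES].astype(float), pcs], axis=1)
    y_all = meta["response"].to_numpy(dtype=float)

    coords = gene_coords.loc[[g for g in candidate_genes if g in gene_coords.index]]
    variants = gm.variants.loc[qc_pass]
    windows = window_integrate(coords, variants, flank)

    # fit each variant once even if it sits in several windows
    fits: dict[str, WaldResult] = {}
    afs: dict[str, tuple[float, float]] = {}
    for vid in sorted({v for vs in windows.values() for v in vs}):
        d = mdos[vid]
        mask = d.notna().to_numpy()
        res = wald_logistic(y_all[mask], d.to_numpy()[mask], covar.to_numpy()[mask])
        fits[vid] = res
        afs[vid] = group_allele_freqs(d, meta["response"])

    rows = []
    for gid, vids in windows.items():
        vids = [v for v in vids if not fits[v].separated]
        if not vids:
            continue
        p_vec = np.array([fits[v].p for v in vids])
        q_vec, meff = meff_adjust(p_vec, mdos[vids])
        region = pd.DataFrame(
            {
                "locus": gid,
                "variant_id": vids,
                "chrom": variants.loc[vids, "chrom"].to_numpy(),
                "pos": variants.loc[vids, "pos"].to_numpy(),
                "p": p_vec,
                "q": q_vec,
                "beta": [fits[v].beta for v in vids],
                "se": [fits[v].se for v in vids],
                "af_resp": [afs[v][0] for v in vids],
                "af_non": [afs[v][1] for v in vids],
                "meff": meff,
            }
        )
        region["significant"] = region["q"] < q_max
        sig = region[region["significant"]]
        kept = set(ld_prune(sig, mdos[list(sig["variant_id"])], r2_max)) if len(sig) else set()
        region["independent"] = region["variant_id"].isin(kept)
        rows.append(region)
    if not rows:
        return pd.DataFrame(
            columns=[
                "locus", "variant_id", "chrom", "pos", "p", "q", "beta", "se",
                "af_resp", "af_non", "meff", "significant", "independent",
            ]
        )
    return pd.concat(rows, ignore_index=True)
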