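"""Covariate-adjusted isoform-level differential expression.

Per-transcript ordinary least squares on log2(TPM+1) with an empirical-Bayes
moderated t statistic (per-transcript residual variances shrunk toward a
pooled prior estimated by moment matching on the scaled-F model), run
separately in healthy and inflamed strata under four covariate approaches,
then combined across strata by Fisher's method into consistent-direction
and opposite-direction differentially-expressed-isoform (DEI) sets.

The response contrast is oriented non-responders minus responders: a
positive log2FC means higher expression in non-responders.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)

APPROACHES = ["I", "II", "III", "IV"]

#: clinical covariates per approach; II-IV swap aminosalicylate use for a
#: deconvolved cell-fraction covariate
_CLINICAL = {
    "I": ["sex", "age_at_diagnosis", "corticosteroid_use", "azathioprine_use", "aminosalicylate_use"],
    "II": ["sex", "age_at_diagnosis", "corticosteroid_use", "azathioprine_use"],
    "III": ["sex", "age_at_diagnosis", "corticosteroid_use", "azathioprine_use"],
    "IV": ["sex", "age_at_diagnosis", "corticosteroid_use", "azathioprine_use"],
}
_FRACTION = {"I": None, "II": "agg_T", "III": "agg_mono_mac", "IV": "agg_dendritic"}

#: stringent combined-p threshold for the monocyte/macrophage-corrected run
P_THRESH = {"I": 0.05, "II": 0.05, "III": 0.005, "IV": 0.05}
LFC_THRESH = 2.0


@dataclasses.dataclass
class EBayesParams:
    """Prior df and prior variance of the scaled-F variance model."""

    d0: float
    s0_sq: float


def build_design(
    meta: pd.DataFrame,
    approach: str,
    fractions: pd.DataFrame | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Design matrix (samples x predictors): intercept, non-responder
    indicator, and the approach's covariates. Rank-deficient columns are
    dropped with a warning (or raise under ``strict``)."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    X["nonresponder"] = 1.0 - meta["response"].astype(float)
    for c in _CLINICAL[approach]:
        X[c] = meta[c].astype(float)
    frac_col = _FRACTION[approach]
    if frac_col is not None:
        if fractions is None:
            raise ValueError(f"approach {approach} needs cell fractions")
        X[frac_col] = fractions[frac_col].reindex(meta.index).astype(float)
    # drop covariates (never intercept/response) until full rank
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        droppable = [c for c in X.columns if c not in ("intercept", "nonresponder")]
        victim = None
        for c in reversed(droppable):
            trial = X.drop(columns=[c])
            if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
                victim = c
                break
        if victim is None:
            raise ValueError("design matrix rank deficient in intercept/response columns")
        if strict:
            raise ValueError(f"design matrix rank deficient (column {victim!r})")
        logger.warning("dropping rank-deficient covariate %r", victim)
        X = X.drop(columns=[victim])
    return X


def fit_transcripts(Y: np.ndarray, X: np.ndarray, coef_index: int) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Vectorized OLS of many transcripts against one design.

    Y is transcripts x samples, X samples x p (full rank). Returns
    (coefficients of column ``coef_index``, residual variances s_g^2,
    residual df, unscaled coefficient variance v = (X'X)^-1[j, j]).
    """
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than predictors")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv                  # transcripts x p
    resid = Y - B @ X.T
    df = n - p
    s2 = (resid ** 2).sum(axis=1) / df
    v = XtX_inv[coef_index, coef_index]
    return B[:, coef_index], s2, df, v


def fit_transcript(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """OLS for one transcript: all coefficients, s^2 and residual df."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("design matrix rank deficient")
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid / df) if df > 0 else np.nan
    return beta, s2, df


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = (tri - y) / polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * x:
            return x_new
        x = x_new
    return x


def estimate_ebayes(s2: np.ndarray, df: int) -> EBayesParams:
    """Moment-match the scaled-F model of the residual variances.

    Works on log variances: with s_g^2 ~ s0^2 * F(d_g, d0), the excess
    variance of log s_g^2 over trigamma(d_g/2) identifies d0 through the
    trigamma function, and the mean identifies s0^2. All-equal variances
    give d0 = +inf (complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 10:
        raise ValueError("need >= 10 positive residual variances")
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return EBayesParams(d0=float(d0), s0_sq=float(s0_sq))


def moderate(
    beta: np.ndarray,
    s2: np.ndarray,
    df: int,
    v: float,
    params: EBayesParams | None = None,
) -> tuple[np.ndarray, np.ndarray, EBayesParams]:
    """Moderated t statistics and two-sided p-values.

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d); t = beta / (s~ sqrt(v)) on
    d0 + d df. d0 = 0 reduces to the ordinary t; d0 = +inf pools all
    variances at s0^2 (normal reference).
    """
    if params is None:
        params = estimate_ebayes(s2, df)
    d0, s0_sq = params.d0, params.s0_sq
    if np.isinf(d0):
        s2_tilde = np.full_like(np.asarray(s2, dtype=float), s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_tilde * v)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, params


def expression_filter(tpm: pd.DataFrame, min_tpm: float = 1.0, min_frac: float = 0.25) -> pd.Index:
    """Transcripts expressed at >= min_tpm in >= min_frac of the samples."""
    keep = (tpm >= min_tpm).mean(axis=1) >= min_frac
    return tpm.index[keep]


def run_approach(
    expr,
    meta: pd.DataFrame,
    fractions: pd.DataFrame | None,
    approach: str,
    stratum: str,
    min_tpm: float = 1.0,
    min_frac: float = 0.25,
) -> pd.DataFrame:
    """DE table for one covariate approach in one tissue stratum.

    Returns a DataFrame with columns transcript_id, stratum, log2FC, s2,
    df, t, p, indexed by transcript.
    """
    sel = meta.index[meta["tissue_state"] == stratum]
    if len(sel) < 4:
        raise ValueError(f"stratum {stratum!r} has fewer than 4 samples")
    sub = meta.loc[sel]
    if sub["response"].nunique() < 2:
        raise ValueError(f"stratum {stratum!r} lacks both response groups")
    tpm = expr.tpm[sel]
    kept = expression_filter(tpm, min_tpm, min_frac)
    Y = np.log2(tpm.loc[kept].to_numpy(dtype=float) + 1.0)
    X = build_design(sub, approach, fractions)
    j = list(X.columns).index("nonresponder")
    beta, s2, df, v = fit_transcripts(Y, X.to_numpy(), j)
    t, p, _ = moderate(beta, s2, df, v)
    return pd.DataFrame(
        {
            "transcript_id": kept,
            "stratum": stratum,
            "log2FC": beta,
            "s2": s2,
            "df": df,
            "t": t,
            "p": p,
        }
    ).set_index("transcript_id", drop=False).rename_axis(None)


def fisher_combine(p_h: np.ndarray, p_i: np.ndarray) -> np.ndarray:
    """Fisher statistic X = -2(ln pH + ln pI) referred to chi-square(4)."""
    X = -2.0 * (np.log(p_h) + np.log(p_i))
    return stats.chi2.sf(X, df=4)


def meta_combine(
    healthy: pd.DataFrame,
    inflamed: pd.DataFrame,
    approach: str,
    p_thresh: float | None = None,
    lfc_thresh: float = LFC_THRESH,
) -> pd.DataFrame:
    """Combine the two strata into classified meta-DEI records.

    consistent: same log2FC sign in both strata, Fisher combined p below
    the approach threshold, and |mean log2FC| > 2. opposite: signs differ
    and each stratum individually passes (p < threshold, |log2FC| > 2).
    Transcripts present in only one stratum are excluded (count logged).
    """
    if p_thresh is None:
        p_thresh = P_THRESH[approach]
    common = healthy.index.intersection(inflamed.index)
    n_dropped = (len(healthy) - len(common)) + (len(inflamed) - len(common))
    if n_dropped:
        logger.info("meta_combine: %d single-stratum records excluded", n_dropped)
    h = healthy.loc[common]
    i = inflamed.loc[common]
    combined_p = fisher_combine(h["p"].to_numpy(), i["p"].to_numpy())
    summary_lfc = (h["log2FC"].to_numpy() + i["log2FC"].to_numpy()) / 2.0
    same_sign = np.sign(h["log2FC"].to_numpy()) == np.sign(i["log2FC"].to_numpy())
    consistent = same_sign & (combined_p < p_thresh) & (np.abs(summary_lfc) > lfc_thresh)
    each_passes = (
        (h["p"].to_numpy() < p_thresh)
        & (i["p"].to_numpy() < p_thresh)
        & (np.abs(h["log2FC"].to_numpy()) > lfc_thresh)
        & (np.abs(i["log2FC"].to_numpy()) > lfc_thresh)
    )
    opposite = ~same_sign & each_passes
    cls = np.where(consistent, "consistent", np.where(opposite, "opposite", "null"))
    out = pd.DataFrame(
        {
            "transcript_id": common,
            "approach": approach,
            "class": cls,
            "combined_p": combined_p,
            "summary_log2FC": summary_lfc,
            "log2FC_healthy": h["log2FC"].to_numpy(),
            "log2FC_inflamed": i["log2FC"].to_numpy(),
            "p_healthy": h["p"].to_numpy(),
            "p_inflamed": i["p"].to_numpy(),
        }
    ).set_index("transcript_id", drop=False).rename_axis(None)
    return out


def dei_set(meta_records: pd.DataFrame) -> pd.DataFrame:
    """The called DEIs: consistent- plus opposite-direction records."""
    return meta_records[meta_records["class"] != "null"]
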