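"""Synthetic study generator with planted ground truth.

Emulates the anatomy of a two-tissue anti-TNF response cohort: 84 genotyped
patients (55 responders / 29 non-responders), 22 unpaired colon biopsies
(11 healthy: 4 non-responders vs 7 responders; 11 inflamed: 7 vs 4) with
transcript-level expression, a cell-type signature, genotypes in LD blocks
near candidate genes, GO annotation and an interaction edge list.

Everything stochastic flows through one :class:`numpy.random.Generator`
seeded from ``CohortDesign.seed``; identical design + seed gives identical
outputs, including file bytes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .io import ExpressionMatrix, GeneModel, GenotypeMatrix

CELL_TYPES = ["T_cells", "monocytes_macrophages", "dendritic_cells", "epithelial"]

#: default cell-type -> covariate-class aggregation for the synthetic signature
AGGREGATION_MAP = {
    "T_cells": "T",
    "monocytes_macrophages": "mono_mac",
    "dendritic_cells": "dendritic",
    "epithelial": "other",
}


@dataclasses.dataclass
class CohortDesign:
    """Cohort dimensions; defaults mirror the emulated study layout."""

    n_patients: int = 84
    n_responders: int = 55
    n_biopsies_healthy: int = 11
    n_healthy_nonresponders: int = 4
    n_biopsies_inflamed: int = 11
    n_inflamed_nonresponders: int = 7
    n_transcripts: int = 300
    n_genes: int = 120
    n_variants: int = 240
    n_ld_blocks: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_patients, self.n_responders, self.n_biopsies_healthy,
            self.n_biopsies_inflamed, self.n_transcripts, self.n_genes,
            self.n_variants, self.n_ld_blocks,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if self.n_responders > self.n_patients:
            raise ValueError("n_responders exceeds n_patients")
        if self.n_healthy_nonresponders >= self.n_biopsies_healthy:
            raise ValueError("healthy biopsy split does not sum")
        if self.n_inflamed_nonresponders >= self.n_biopsies_inflamed:
            raise ValueError("inflamed biopsy split does not sum")
        if self.n_genes > self.n_transcripts:
            raise ValueError("need n_genes <= n_transcripts")
        for n_nr, n_tot in [
            (self.n_healthy_nonresponders, self.n_biopsies_healthy),
            (self.n_inflamed_nonresponders, self.n_biopsies_inflamed),
        ]:
            if n_nr < 2 or n_tot - n_nr < 2:
                raise ValueError("need >= 2 samples per response group per stratum")


@dataclasses.dataclass
class ExpressionParams:
    """Effect-size and noise settings for the expression generator.

    All effects act on the log2(TPM+1) scale. ``lfc`` is the planted
    response effect (non-responders minus responders); planted transcripts
    must clear the |log2FC| > 2 calling threshold, hence the default 3.
    """

    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    lfc: float = 3.0
    n_planted_consistent: int = 12
    n_planted_opposite: int = 4
    noise_sd: float = 0.5
    loading_scale: float = 1.0      # cell-fraction -> expression loadings
    covariate_sd: float = 0.15      # per-transcript clinical covariate effects
    fraction_confounding: float = 0.0  # response -> fraction shift (robustness knob)

    def __post_init__(self) -> None:
        if self.lfc <= 0:
            raise ValueError("planted |log2FC| must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class LDProfile:
    """Block sizes and within-block latent correlation for genotype simulation."""

    within_block_r: float = 0.9
    maf_low: float = 0.05
    maf_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_block_r <= 0.99):
            raise ValueError("within-block r must be in [0, 0.99]")
        if not (0.01 < self.maf_low < self.maf_high <= 0.5):
            raise ValueError("MAF range must lie in (0.01, 0.5]")


@dataclasses.dataclass
class VariantEffectParams:
    """Planted response log-odds effects for genotype simulation."""

    n_planted_blocks: int = 3
    beta: float = 2.2               # |log-odds| per ALT dosage for planted variants
    planted_maf_low: float = 0.30   # planted variants kept at mid-range MAF so
    planted_maf_high: float = 0.45  # their Wald z sits near 3, as in real cohorts
    covariate_beta_sd: float = 0.2


@dataclasses.dataclass
class GroundTruth:
    """Planted signals; the reference for parameter-recovery tests."""

    planted_dei: pd.DataFrame = None          # transcript_id, gene_id, lfc_healthy, lfc_inflamed, pattern
    planted_variants: pd.DataFrame = None     # variant_id, gene_id, beta
    true_fractions: pd.DataFrame = None       # samples x cell types, rows sum to 1
    candidate_gene_ids: list = dataclasses.field(default_factory=list)
    eqtl_pairs: pd.DataFrame = None           # transcript_id, variant_id, slope


@dataclasses.dataclass
class Annotations:
    gene_model: GeneModel
    go: pd.DataFrame
    signature: pd.DataFrame
    edges: pd.DataFrame
    marker_cell_type: pd.Series    # signature gene -> cell type it marks


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    design: CohortDesign,
    rng: np.random.Generator,
    planted_gene_ids: list[str] | None = None,
) -> Annotations:
    """Gene coordinates, transcript map, GO terms, signature and edges.

    Genes are laid out on synthetic chromosomes with non-overlapping
    intervals spaced widely enough that +/-100 kb windows of neighbouring
    genes overlap only occasionally, as in a real genome.
    """
    gene_ids = [f"G{i:04d}" for i in range(design.n_genes)]
    n_chrom = max(1, design.n_genes // 20)
    chroms, starts, ends = [], [], []
    per_chrom = int(np.ceil(design.n_genes / n_chrom))
    for i in range(design.n_genes):
        c = i // per_chrom
        k = i % per_chrom
        start = 500_000 + k * 400_000 + int(rng.integers(0, 50_000))
        length = int(rng.integers(5_000, 120_000))
        chroms.append(f"chr{c + 1}")
        starts.append(start)
        ends.append(start + length)
    genes = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}, index=gene_ids)

    # every gene gets >= 1 transcript; leftovers assigned round-robin
    tx_ids = [f"T{i:05d}" for i in range(design.n_transcripts)]
    assignment = list(range(design.n_genes))
    extra = rng.integers(0, design.n_genes, size=design.n_transcripts - design.n_genes)
    assignment += list(extra)
    tx2gene = pd.Series([gene_ids[g] for g in assignment], index=tx_ids)
    gene_model = GeneModel(genes=genes, tx2gene=tx2gene)

    # toy signature: each cell type has exclusive high-expressed marker
    # genes; markers never claim more than half the genome
    n_markers = min(8, max(1, design.n_genes // (2 * len(CELL_TYPES))))
    sig_gene_pool = [g for g in gene_ids if planted_gene_ids is None or g not in planted_gene_ids]
    sig_genes = list(rng.choice(sig_gene_pool, size=min(n_markers * len(CELL_TYPES), len(sig_gene_pool)), replace=False))
    sig = pd.DataFrame(
        rng.uniform(0.5, 2.0, size=(len(sig_genes), len(CELL_TYPES))),
        index=sig_genes,
        columns=CELL_TYPES,
    )
    marker_ct = pd.Series(index=sig_genes, dtype=object)
    for j, ct in enumerate(CELL_TYPES):
        block = sig_genes[j * n_markers : (j + 1) * n_markers]
        sig.loc[block, ct] += rng.uniform(30.0, 60.0, size=len(block))
        marker_ct[block] = ct

    # GO terms: background terms of varied size + one term concentrated on
    # planted genes (>= 80% planted) so enrichment recovery is testable
    terms = []
    namespaces = ["BP", "CC", "MF"]
    n_terms = 30
    for t in range(n_terms):
        ns = namespaces[t % 3]
        size = int(rng.integers(5, max(6, design.n_genes // 4)))
        members = rng.choice(gene_ids, size=min(size, design.n_genes), replace=False)
        for g in members:
            terms.append((f"GO:{9000000 + t}", ns, g))
    if planted_gene_ids:
        planted = list(planted_gene_ids)
        n_pad = max(0, int(np.ceil(len(planted) / 0.8)) - len(planted))
        others = [g for g in gene_ids if g not in planted]
        pad = list(rng.choice(others, size=min(n_pad, len(others)), replace=False))
        for g in planted + pad:
            terms.append(("GO:0099999", "BP", g))
    go = pd.DataFrame(terms, columns=["term_id", "namespace", "gene_id"])

    # interaction edges: hub genes touching >= 2 planted genes, plus noise
    edges = []
    if planted_gene_ids and len(planted_gene_ids) >= 2:
        hub_pool = [g for g in gene_ids if g not in planted_gene_ids]
        hubs = rng.choice(hub_pool, size=min(3, len(hub_pool)), replace=False)
        for h in hubs:
            partners = rng.choice(planted_gene_ids, size=2, replace=False)
            for p in partners:
                edges.append((h, p))
    n_noise = 40
    a = rng.choice(gene_ids, size=n_noise)
    b = rng.choice(gene_ids, size=n_noise)
    edges += [(x, y) for x, y in zip(a, b) if x != y]
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b"]).drop_duplicates()

    return Annotations(
        gene_model=gene_model,
        go=go,
        signature=sig,
        edges=edge_df,
        marker_cell_type=marker_ct,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _biopsy_layout(design: CohortDesign) -> pd.DataFrame:
    """Sample sheet for the two unpaired biopsy strata (one patient each)."""
    rows = []
    layout = [
        ("healthy", design.n_biopsies_healthy, design.n_healthy_nonresponders),
        ("inflamed", design.n_biopsies_inflamed, design.n_inflamed_nonresponders),
    ]
    i = 0
    for state, n_tot, n_nr in layout:
        for k in range(n_tot):
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "tissue_state": state,
                    "response": 0 if k < n_nr else 1,
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_expression(
    design: CohortDesign,
    params: ExpressionParams | None = None,
    annotations: Annotations | None = None,
    rng: np.random.Generator | None = None,
    patient_ids: pd.Series | None = None,
    eqtl_dosage_effect: pd.DataFrame | None = None,
    planted_tx_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate biopsy expression with planted differential isoforms.

    Returns (expression, sample metadata, ground truth). Expression is built
    on the log2(TPM+1) scale as baseline + signature-weighted cell-fraction
    component + clinical covariate effects + planted response effect +
    Gaussian noise, then back-transformed to TPM.

    ``eqtl_dosage_effect`` (samples x planted transcripts, already scaled)
    lets the cohort orchestrator inject genotype-dependent shifts.
    """
    params = params or ExpressionParams()
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    ann = annotations or generate_annotations(design, rng)

    meta = _biopsy_layout(design)
    n_s = len(meta)
    if patient_ids is not None:
        meta["patient_id"] = patient_ids.values
    else:
        meta["patient_id"] = [f"P{i:03d}" for i in range(n_s)]
    meta["sex"] = rng.integers(0, 2, size=n_s)
    meta["age_at_diagnosis"] = rng.normal(32.0, 9.0, size=n_s).round(1)
    for drug in ["corticosteroid_use", "azathioprine_use", "aminosalicylate_use"]:
        meta[drug] = rng.integers(0, 2, size=n_s)

    # true cell fractions: inflamed biopsies are immune-richer; an optional
    # confounding knob shifts immune mass with response
    alpha = np.tile(np.array([2.0, 1.5, 1.0, 5.0]), (n_s, 1))
    alpha[meta["tissue_state"].values == "inflamed"] = [4.0, 3.0, 1.5, 3.0]
    alpha[:, 0] += params.fraction_confounding * (1 - meta["response"].values)
    fracs = np.vstack([rng.dirichlet(a) for a in alpha])
    true_fracs = pd.DataFrame(fracs, index=meta.index, columns=CELL_TYPES)

    tx_ids = ann.gene_model.tx2gene.index
    n_t = design.n_transcripts

    # per-transcript loadings: marker-gene transcripts load on their cell type
    loadings = np.zeros((n_t, len(CELL_TYPES)))
    gene_of_tx = ann.gene_model.tx2gene
    for i, tx in enumerate(tx_ids):
        g = gene_of_tx[tx]
        if g in ann.marker_cell_type.index:
            j = CELL_TYPES.index(ann.marker_cell_type[g])
            loadings[i, j] = params.loading_scale * rng.uniform(2.0, 4.0)

    # planted DEIs live on genes without marker duty where possible
    n_planted = params.n_planted_consistent + params.n_planted_opposite
    if planted_tx_ids is not None:
        if len(planted_tx_ids) != n_planted:
            raise ValueError("planted_tx_ids length must match planted counts")
        planted_idx = np.array([tx_ids.get_loc(t) for t in planted_tx_ids])
    else:
        non_marker = [
            i for i, tx in enumerate(tx_ids) if gene_of_tx[tx] not in ann.marker_cell_type.index
        ]
        if len(non_marker) < n_planted:
            raise ValueError("not enough non-marker transcripts to plant DEIs")
        planted_idx = rng.choice(non_marker, size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    lfc_h = signs * params.lfc
    lfc_i = lfc_h.copy()
    lfc_i[params.n_planted_consistent :] *= -1.0   # opposite-direction block
    pattern = ["consistent"] * params.n_planted_consistent + ["opposite"] * params.n_planted_opposite

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n_t)
    baseline = np.clip(baseline, 1.0, None)
    # keep planted transcripts comfortably expressed so the TPM floor cannot
    # truncate a negative planted effect
    baseline[planted_idx] = np.clip(baseline[planted_idx], params.lfc + 1.5, None)

    cov_cols = ["sex", "corticosteroid_use", "azathioprine_use", "aminosalicylate_use"]
    C = meta[cov_cols].to_numpy(dtype=float)
    age_z = (meta["age_at_diagnosis"].to_numpy() - 32.0) / 9.0
    C = np.column_stack([C, age_z])
    cov_beta = rng.normal(0.0, params.covariate_sd, size=(n_t, C.shape[1]))

    nonresp = (1 - meta["response"].to_numpy())[None, :]       # 1 for non-responders
    is_inflamed = (meta["tissue_state"].to_numpy() == "inflamed")[None, :]

    X = np.tile(baseline[:, None], (1, n_s))
    X += loadings @ fracs.T
    X += cov_beta @ C.T
    effect = np.zeros((n_t, n_s))
    effect[planted_idx, :] = (
        lfc_h[:, None] * (~is_inflamed) + lfc_i[:, None] * is_inflamed
    ) * nonresp
    X += effect
    if eqtl_dosage_effect is not None:
        for tx in eqtl_dosage_effect.columns:
            i = tx_ids.get_loc(tx)
            X[i, :] += eqtl_dosage_effect[tx].reindex(meta.index).to_numpy()
    X += rng.normal(0.0, params.noise_sd, size=(n_t, n_s)) if params.noise_sd > 0 else 0.0

    tpm = np.maximum(np.exp2(X) - 1.0, 0.0)
    expr = ExpressionMatrix(
        tpm=pd.DataFrame(tpm, index=tx_ids, columns=meta.index),
        counts=pd.DataFrame(np.round(tpm * 30.0), index=tx_ids, columns=meta.index),
    )
    planted = pd.DataFrame(
        {
            "transcript_id": tx_ids[planted_idx],
            "gene_id": gene_of_tx.iloc[planted_idx].values,
            "lfc_healthy": lfc_h,
            "lfc_inflamed": lfc_i,
            "pattern": pattern,
        }
    ).set_index("transcript_id", drop=False)
    planted.index.name = None
    truth = GroundTruth(
        planted_dei=planted,
        true_fractions=true_fracs,
        candidate_gene_ids=sorted(set(planted["gene_id"])),
    )
    return expr, meta[["patient_id"] + [c for c in meta.columns if c != "patient_id"]], truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _equicorrelated_chol(m: int, r: float) -> np.ndarray:
    cov = np.full((m, m), r)
    np.fill_diagonal(cov, 1.0)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(f"block correlation r={r} gives non-positive-definite latent covariance")


def generate_genotypes(
    design: CohortDesign,
    ld_profile: LDProfile | None = None,
    effect_params: VariantEffectParams | None = None,
    annotations: Annotations | None = None,
    rng: np.random.Generator | None = None,
    anchor_gene_ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, GroundTruth]:
    """Simulate dosages in LD blocks plus logistic response labels.

    LD uses a latent-Gaussian threshold model: each haplotype draws a
    within-block equicorrelated normal vector and carries the ALT allele
    where the latent value falls below the MAF quantile. Response is
    Bernoulli from a logistic model over planted variant dosages and
    clinical covariates, with the intercept solved so the expected number
    of responders matches the design.

    Returns (genotypes, patient metadata, ground truth).
    """
    ld = ld_profile or LDProfile()
    ep = effect_params or VariantEffectParams()
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    ann = annotations or generate_annotations(design, rng)

    n, m = design.n_patients, design.n_variants
    n_blocks = design.n_ld_blocks
    block_sizes = np.full(n_blocks, m // n_blocks)
    block_sizes[: m % n_blocks] += 1

    # each block is anchored inside a distinct gene's +/-100 kb window
    genes = ann.gene_model.genes
    if anchor_gene_ids is not None:
        anchor_genes = list(anchor_gene_ids)
    else:
        anchor_genes = list(genes.index[: n_blocks]) if len(genes) >= n_blocks else list(genes.index)
    mafs = rng.uniform(ld.maf_low, ld.maf_high, size=m)
    # planted variants (middle of each planted block) get mid-range MAF
    block_of = np.repeat(np.arange(n_blocks), block_sizes)
    planted_js = []
    for b in range(min(ep.n_planted_blocks, n_blocks)):
        cols = np.where(block_of == b)[0]
        planted_js.append(int(cols[len(cols) // 2]))
    if ep.beta != 0.0:
        mafs[planted_js] = rng.uniform(ep.planted_maf_low, ep.planted_maf_high, size=len(planted_js))
    thresholds = ndtri(mafs)

    dos = np.empty((n, m))
    chrom_arr, pos_arr, vid_arr, block_arr = [], [], [], []
    j0 = 0
    for b, bs in enumerate(block_sizes):
        L = _equicorrelated_chol(int(bs), ld.within_block_r)
        z1 = rng.standard_normal((n, bs)) @ L.T
        z2 = rng.standard_normal((n, bs)) @ L.T
        dos[:, j0 : j0 + bs] = (z1 < thresholds[j0 : j0 + bs]) + (z2 < thresholds[j0 : j0 + bs])
        g = anchor_genes[b % len(anchor_genes)]
        g_start = int(genes.loc[g, "start"])
        base = max(0, g_start - 50_000)
        for k in range(bs):
            chrom_arr.append(genes.loc[g, "chrom"])
            pos_arr.append(base + 1 + k * 700 + int(rng.integers(0, 300)))
            vid_arr.append(f"rs{b:03d}{k:03d}")
            block_arr.append(b)
        j0 += bs

    variants = pd.DataFrame(
        {"chrom": chrom_arr, "pos": pos_arr, "id": vid_arr, "ref": "A", "alt": "G"},
        index=vid_arr,
    )
    patient_ids = [f"P{i:03d}" for i in range(n)]
    dosages = pd.DataFrame(dos, index=patient_ids, columns=vid_arr)

    # clinical covariates, independent of response by default
    pmeta = pd.DataFrame(index=pd.Index(patient_ids, name="patient_id"))
    pmeta["sex"] = rng.integers(0, 2, size=n)
    pmeta["age_at_diagnosis"] = rng.normal(32.0, 9.0, size=n).round(1)
    for drug in ["corticosteroid_use", "azathioprine_use", "aminosalicylate_use"]:
        pmeta[drug] = rng.integers(0, 2, size=n)

    # planted response effects: one variant per planted block
    planted_rows = []
    eta = np.zeros(n)
    blocks = np.asarray(block_arr)
    for b in range(min(ep.n_planted_blocks, n_blocks)):
        if ep.beta == 0.0:
            break
        block_cols = np.where(blocks == b)[0]
        j = int(block_cols[len(block_cols) // 2])
        beta = -ep.beta  # ALT allele lowers response odds, as for a risk allele
        eta += beta * (dos[:, j] - dos[:, j].mean())
        planted_rows.append(
            {
                "variant_id": vid_arr[j],
                "gene_id": anchor_genes[b % len(anchor_genes)],
                "beta": beta,
            }
        )
    cov_beta = rng.normal(0.0, ep.covariate_beta_sd, size=2)
    eta += cov_beta[0] * pmeta["sex"].to_numpy()
    eta += cov_beta[1] * (pmeta["age_at_diagnosis"].to_numpy() - 32.0) / 9.0

    target = design.n_responders / design.n_patients
    b0 = brentq(lambda c: expit(c + eta).mean() - target, -20, 20)
    pmeta["response"] = rng.binomial(1, expit(b0 + eta))

    gm = GenotypeMatrix(dosages=dosages, variants=variants)
    planted = pd.DataFrame(planted_rows, columns=["variant_id", "gene_id", "beta"])
    if len(planted):
        planted = planted.set_index("variant_id", drop=False)
        planted.index.name = None
    truth = GroundTruth(planted_variants=planted)
    return gm, pmeta, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticCohort:
    design: CohortDesign
    expression: ExpressionMatrix
    sample_meta: pd.DataFrame
    genotypes: GenotypeMatrix
    patient_meta: pd.DataFrame
    annotations: Annotations
    truth: GroundTruth


def generate_cohort(
    design: CohortDesign,
    expr_params: ExpressionParams | None = None,
    ld_profile: LDProfile | None = None,
    effect_params: VariantEffectParams | None = None,
    eqtl_slope: float = 1.0,
) -> SyntheticCohort:
    """Generate a fully cross-linked study: genotypes for all patients,
    biopsies drawn from genotyped patients consistent with their response
    label, and planted eQTLs tying planted variants to planted transcripts.
    """
    rng = np.random.default_rng(design.seed)
    expr_params = expr_params or ExpressionParams()
    n_planted = expr_params.n_planted_consistent + expr_params.n_planted_opposite

    # two-phase annotation build: a first pass (on its own stream) fixes the
    # gene model and signature so planted transcripts can be chosen on
    # non-marker genes; the second pass replays the same stream and layers
    # the planted-gene GO term and hub edges on top
    ann0 = generate_annotations(design, np.random.default_rng(design.seed + 1))
    gene_of_tx = ann0.gene_model.tx2gene
    pick_rng = np.random.default_rng(design.seed + 2)
    non_marker_tx = [
        t for t in gene_of_tx.index if gene_of_tx[t] not in ann0.marker_cell_type.index
    ]
    if len(non_marker_tx) < n_planted:
        raise ValueError("not enough non-marker transcripts to plant DEIs")
    planted_tx = [str(t) for t in pick_rng.choice(non_marker_tx, size=n_planted, replace=False)]
    planted_genes = sorted(set(gene_of_tx[t] for t in planted_tx))
    ann = generate_annotations(
        design, np.random.default_rng(design.seed + 1), planted_gene_ids=planted_genes
    )

    # anchor planted LD blocks on planted-DEI genes so the planted variants
    # fall inside candidate-gene windows
    other_genes = [g for g in ann.gene_model.genes.index if g not in planted_genes]
    n_eff = effect_params.n_planted_blocks if effect_params else VariantEffectParams().n_planted_blocks
    anchors = (planted_genes * ((n_eff // max(1, len(planted_genes))) + 1))[:n_eff]
    anchors += other_genes[: design.n_ld_blocks - len(anchors)]
    gm, pmeta, gt_truth = generate_genotypes(
        design, ld_profile, effect_params, annotations=ann, rng=rng,
        anchor_gene_ids=anchors[: design.n_ld_blocks],
    )

    # biopsy patients drawn from the genotyped cohort by response label
    resp_pool = list(pmeta.index[pmeta["response"] == 1])
    nonresp_pool = list(pmeta.index[pmeta["response"] == 0])
    need_nr = design.n_healthy_nonresponders + design.n_inflamed_nonresponders
    need_r = (design.n_biopsies_healthy + design.n_biopsies_inflamed) - need_nr
    if len(nonresp_pool) < need_nr or len(resp_pool) < need_r:
        raise ValueError("simulated label draw left too few patients in a response group")
    pick_nr = list(rng.choice(nonresp_pool, size=need_nr, replace=False))
    pick_r = list(rng.choice(resp_pool, size=need_r, replace=False))
    layout = _biopsy_layout(design)
    assigned = []
    it_nr, it_r = iter(pick_nr), iter(pick_r)
    for _, row in layout.iterrows():
        assigned.append(next(it_nr) if row["response"] == 0 else next(it_r))
    patient_ids = pd.Series(assigned, index=layout.index)

    # planted eQTLs: each planted variant shifts one planted transcript of
    # its anchor gene by slope * centered dosage (log2 scale)
    eqtl_rows = []
    eqtl_effect = None
    if gt_truth.planted_variants is not None and len(gt_truth.planted_variants):
        dos = gm.dosages
        shift = {}
        for _, vrow in gt_truth.planted_variants.iterrows():
            gene_tx = [t for t in planted_tx if gene_of_tx[t] == vrow["gene_id"]]
            if not gene_tx:
                continue
            tx = gene_tx[0]
            d = dos[vrow["variant_id"]].reindex(patient_ids.values).to_numpy()
            shift[tx] = pd.Series(eqtl_slope * (d - d.mean()), index=layout.index)
            eqtl_rows.append(
                {"transcript_id": tx, "variant_id": vrow["variant_id"], "slope": eqtl_slope}
            )
        if shift:
            eqtl_effect = pd.DataFrame(shift)

    expr, smeta, ex_truth = generate_expression(
        design,
        params=expr_params,
        annotations=ann,
        rng=rng,
        patient_ids=patient_ids,
        eqtl_dosage_effect=eqtl_effect,
        planted_tx_ids=planted_tx,
    )

    truth = GroundTruth(
        planted_dei=ex_truth.planted_dei,
        planted_variants=gt_truth.planted_variants,
        true_fractions=ex_truth.true_fractions,
        candidate_gene_ids=ex_truth.candidate_gene_ids,
        eqtl_pairs=pd.DataFrame(eqtl_rows, columns=["transcript_id", "variant_id", "slope"]),
    )
    return SyntheticCohort(
        design=design,
        expression=expr,
        sample_meta=smeta,
        genotypes=gm,
        patient_meta=pmeta,
        annotations=ann,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write every cohort file in its canonical text format; returns paths."""
    from pathlib import Path

    from . import io as fio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression_tpm.tsv",
        "counts": out / "expression_counts.tsv",
        "sample_meta": out / "samples.tsv",
        "patient_meta": out / "patients.tsv",
        "vcf": out / "cohort.vcf",
        "bed": out / "genes.bed",
        "tx2gene": out / "tx2gene.tsv",
        "go": out / "go.tsv",
        "signature": out / "signature.tsv",
        "edges": out / "edges.tsv",
    }
    fio.write_matrix(paths["expression"], cohort.expression.tpm, "transcript_id")
    fio.write_matrix(paths["counts"], cohort.expression.counts, "transcript_id")
    cohort.sample_meta.to_csv(paths["sample_meta"], sep="\t", index_label="sample_id")
    cohort.patient_meta.to_csv(paths["patient_meta"], sep="\t", index_label="patient_id")
    fio.write_vcf(paths["vcf"], cohort.genotypes)
    fio.write_gene_bed(paths["bed"], cohort.annotations.gene_model)
    fio.write_tx2gene(paths["tx2gene"], cohort.annotations.gene_model)
    cohort.annotations.go.to_csv(paths["go"], sep="\t", index=False)
    fio.write_matrix(paths["signature"], cohort.annotations.signature, "gene_id")
    cohort.annotations.edges.to_csv(paths["edges"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
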