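import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from isogx import assoc
from isogx.io import GenotypeMatrix


def logistic_ml_oracle(y, X):
    """Independent maximum-likelihood oracle: minimize the negative
    log-likelihood directly; SE from the analytic inverse Hessian."""

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    b = res.x
    mu = expit(X @ b)
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return b, se


@pytest.mark.parametrize("seed", range(6))
def test_wald_engine_matches_direct_ml(seed):
    rng = np.random.default_rng(seed)
    n = 30
    d = rng.integers(0, 3, size=n).astype(float)
    c = rng.normal(size=n)
    eta = -0.3 + 0.8 * d + 0.5 * c
    y = rng.binomial(1, expit(eta)).astype(float)
    if y.min() == y.max():
        pytest.skip("degenerate draw")
    res = assoc.wald_logistic(y, d, c[:, None])
    if res.separated:
        pytest.skip("separated draw")
    X = np.column_stack([np.ones(n), d, c])
    b_o, se_o = logistic_ml_oracle(y, X)
    assert res.beta == pytest.approx(b_o[1], abs=1e-6)
    assert res.se == pytest.approx(se_o[1], abs=1e-6)


def test_null_effect_p_one():
    assert assoc.wald_p_from_summary(0.0, 1.0) == pytest.approx(1.0)


def test_perfect_separation_flagged():
    y = np.r_[np.zeros(10), np.ones(10)]
    d = y * 2.0
    res = assoc.wald_logistic(y, d)
    assert res.separated
    assert np.isnan(res.p)  # missing, never 0


def test_published_summary_consistency():
    """Printed regression summaries: p recomputed from beta/SE matches the
    reported p at 4 decimal places."""
    assert round(assoc.wald_p_from_summary(1.0167, 0.38416), 4) == 0.0081
    assert round(assoc.wald_p_from_summary(-1.96, 0.60067), 4) == 0.0011


def test_pca_structure(cohort):
    pcs = assoc.genotype_pca(cohort.genotypes)
    assert pcs.shape == (84, 4)
    # duplicated patient rows give identical PC rows
    gm = cohort.genotypes
    dup = GenotypeMatrix(
        dosages=pd.concat([gm.dosages, gm.dosages.iloc[[0]].rename(index={gm.patient_ids[0]: "dup"})]),
        variants=gm.variants,
    )
    pcs2 = assoc.genotype_pca(dup)
    np.testing.assert_allclose(
        pcs2.loc["dup"].to_numpy(), pcs2.iloc[0].to_numpy(), atol=1e-8
    )


def test_pca_separates_subpopulations():
    """Two subpopulations with divergent allele frequencies split on PC1."""
    rng = np.random.default_rng(0)
    n1, n2, m = 40, 40, 60
    p1 = rng.uniform(0.1, 0.3, size=m)
    p2 = np.clip(p1 + 0.35, 0, 0.95)
    D = np.vstack(
        [rng.binomial(2, p1, size=(n1, m)), rng.binomial(2, p2, size=(n2, m))]
    ).astype(float)
    gm = GenotypeMatrix(
        dosages=pd.DataFrame(D, index=[f"P{i}" for i in range(n1 + n2)],
                             columns=[f"v{j}" for j in range(m)]),
        variants=pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, m + 1) * 1000, "id": [f"v{j}" for j in range(m)],
             "ref": "A", "alt": "G"},
            index=[f"v{j}" for j in range(m)],
        ),
    )
    pcs = assoc.genotype_pca(gm, thin_r2=None)
    group = np.r_[np.zeros(n1), np.ones(n2)]
    r = np.corrcoef(pcs["PC1"], group)[0, 1]
    assert abs(r) > 0.9


def test_window_membership_boundaries():
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [200_000], "end": [250_000]}, index=["g"])
    variants = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr1"], "pos": [100_001, 100_000, 350_000],
         "id": ["in_lo", "out_lo", "hi_out"]},
        index=["in_lo", "out_lo", "hi_out"],
    )
    win = assoc.window_integrate(genes, variants, flank=100_000)
    # pos 100001 -> pos0 100000 = start - flank: included; pos0 99999 excluded
    assert "in_lo" in win["g"] and "out_lo" not in win["g"]
    # pos0 349999 < 250000 + 100000: included
    assert "hi_out" in win["g"]


def test_window_matches_brute_force_scan(rng):
    genes = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=30),
            "start": rng.integers(0, 5_000_000, size=30),
        },
        index=[f"g{i}" for i in range(30)],
    )
    genes["end"] = genes["start"] + rng.integers(1_000, 200_000, size=30)
    variants = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], size=500),
            "pos": rng.integers(1, 5_200_000, size=500),
        },
        index=[f"v{i}" for i in range(500)],
    )
    flank = 100_000
    win = assoc.window_integrate(genes, variants, flank)
    for gid, g in genes.iterrows():
        expect = [
            vid
            for vid, v in variants.iterrows()
            if v["chrom"] == g["chrom"]
            and max(0, g["start"] - flank) <= v["pos"] - 1 < g["end"] + flank
        ]
        assert win[gid] == expect


def test_meff_bounds_and_special_cases(rng):
    # single variant
    q, meff = assoc.meff_adjust(np.array([0.04]), pd.DataFrame({"v": [0, 1, 2, 1, 0]}))
    assert meff == 1.0
    np.testing.assert_allclose(q, [0.04])
    # perfectly correlated variants count once
    base = rng.integers(0, 3, size=50).astype(float)
    D = pd.DataFrame({"a": base, "b": base, "c": base})
    _, meff = assoc.meff_adjust(np.array([0.01, 0.01, 0.01]), D)
    assert meff == pytest.approx(1.0, abs=1e-8)
    # independent variants: Meff = m and q = Sidak
    m = 6
    D = pd.DataFrame(rng.integers(0, 3, size=(4000, m)).astype(float))
    corr = np.corrcoef(D.to_numpy().T)
    assert assoc.meff_li_ji(np.eye(m)) == m
    # realized Meff of any correlation matrix stays within [1, m]
    assert 1.0 <= assoc.meff_li_ji(corr) <= m


def test_ld_prune_degenerate_cases(rng):
    base = rng.integers(0, 3, size=60).astype(float)
    recs = pd.DataFrame(
        {"variant_id": ["a", "b", "c"], "p": [0.01, 0.001, 0.05], "pos": [1, 2, 3]}
    )
    # all identical -> single survivor, the lowest p
    D = pd.DataFrame({"a": base, "b": base, "c": base})
    assert assoc.ld_prune(recs, D) == ["b"]
    # all independent -> all survive
    D2 = pd.DataFrame({c: rng.integers(0, 3, size=60).astype(float) for c in "abc"})
    assert set(assoc.ld_prune(recs, D2)) == {"a", "b", "c"}


def ld_prune_oracle(recs, D, r2_max):
    """Independent re-implementation of greedy pruning by explicit scan."""
    order = recs.sort_values(["p", "pos", "variant_id"])["variant_id"].tolist()
    kept = []
    for v in order:
        if all(
            np.corrcoef(D[v], D[k])[0, 1] ** 2 <= r2_max for k in kept
        ):
            kept.append(v)
    return kept


@pytest.mark.parametrize("seed", range(5))
def test_ld_prune_matches_oracle_and_certificate(seed):
    rng = np.random.default_rng(seed)
    m = 10
    base = rng.integers(0, 3, size=(80, 3)).astype(float)
    D = pd.DataFrame(
        {f"v{j}": base[:, j % 3] + rng.normal(0, rng.uniform(0.1, 2.0), 80) for j in range(m)}
    )
    recs = pd.DataFrame(
        {"variant_id": [f"v{j}" for j in range(m)], "p": rng.uniform(size=m),
         "pos": np.arange(m)}
    )
    kept = assoc.ld_prune(recs, D, r2_max=0.5)
    assert kept == ld_prune_oracle(recs, D, 0.5)
    # certificate: surviving set pairwise r^2 <= 0.5
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert np.corrcoef(D[a], D[b])[0, 1] ** 2 <= 0.5 + 1e-12


def test_group_allele_freqs_hand_count():
    # printed 6-patient toy table: dosages and labels counted by hand
    dosage = pd.Series([0.0, 1.0, 2.0, 1.0, 0.0, np.nan], index=list("abcdef"))
    response = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
    af_resp, af_non = assoc.group_allele_freqs(dosage, response)
    assert af_resp == pytest.approx(3 / 6)   # (0+1+2) / (2*3)
    assert af_non == pytest.approx(1 / 4)    # (1+0) / (2*2), missing excluded
    # all zero dosages -> AF 0
    assert assoc.group_allele_freqs(pd.Series([0.0, 0.0]), pd.Series([1, 0]))[0] == 0.0


def test_minor_orientation_flips_major_alt(cohort):
    gm = cohort.genotypes
    md = assoc.minor_dosages(gm)
    af = md.mean(axis=0) / 2.0
    assert (af <= 0.5 + 1e-12).all()


def test_planted_variant_beta_sign_matches_group_afs(cohort):
    """On synthetic data the sign of the minor-allele beta agrees with the
    direction of the responder/non-responder AF difference."""
    tab = assoc.run_gwas(
        cohort.genotypes, cohort.patient_meta,
        cohort.truth.candidate_gene_ids, cohort.annotations.gene_model.genes,
    )
    sig = tab[tab["significant"]]
    assert len(sig) > 0
    for _, row in sig.iterrows():
        if abs(row["af_resp"] - row["af_non"]) > 0.05:
            assert np.sign(row["beta"]) == np.sign(row["af_resp"] - row["af_non"])
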