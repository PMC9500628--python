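import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isogx import de
from isogx.io import ExpressionMatrix


def two_group_design(n1, n2):
    X = np.column_stack([np.ones(n1 + n2), np.r_[np.zeros(n1), np.ones(n2)]])
    return X


def test_noiseless_ols_recovers_coefficients(rng):
    X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
    b_true = np.array([1.0, -2.0, 0.5, 3.0])
    y = X @ b_true
    beta, s2, df = de.fit_transcript(y, X)
    np.testing.assert_allclose(beta, b_true, atol=1e-10)
    assert s2 == pytest.approx(0.0, abs=1e-18)
    assert df == 16


def test_two_sample_identity():
    """Intercept + response design: the response coefficient is the
    difference of group means."""
    y = np.r_[np.full(5, 2.0), np.full(7, 6.5)]
    beta, _, _ = de.fit_transcript(y, two_group_design(5, 7))
    assert beta[1] == pytest.approx(4.5, abs=1e-12)


def test_permuted_response_p_values_uniform(rng):
    """On null data the moderated p of the response coefficient is uniform
    over response-label permutations."""
    n = 12
    y = rng.normal(size=(200, n))
    ps = []
    for _ in range(60):
        perm = rng.permutation(n)
        X = two_group_design(6, 6)[perm]
        beta, s2, df, v = de.fit_transcripts(y, X, 1)
        _, p, _ = de.moderate(beta, s2, df, v)
        ps.extend(p.tolist())
    stat, pks = stats.kstest(ps, "uniform")
    assert pks > 0.01


def test_moderated_t_limits(rng):
    beta = rng.normal(size=50)
    s2 = rng.chisquare(5, size=50) / 5 * 0.3
    df, v = 8, 0.25
    # d0 = 0: ordinary t on df
    t0, p0, _ = de.moderate(beta, s2, df, v, de.EBayesParams(d0=0.0, s0_sq=1.0))
    t_ref = beta / np.sqrt(s2 * v)
    np.testing.assert_allclose(t0, t_ref, rtol=1e-12)
    np.testing.assert_allclose(p0, 2 * stats.t.sf(np.abs(t_ref), df), rtol=1e-12)
    # d0 = inf: pooled prior variance, normal reference
    tinf, pinf, _ = de.moderate(beta, s2, df, v, de.EBayesParams(d0=np.inf, s0_sq=0.3))
    np.testing.assert_allclose(tinf, beta / np.sqrt(0.3 * v), rtol=1e-12)
    np.testing.assert_allclose(pinf, 2 * stats.norm.sf(np.abs(tinf)), rtol=1e-10)


def test_identical_variances_give_infinite_prior_df():
    s2 = np.full(60, 0.7)
    params = de.estimate_ebayes(s2, 10)
    assert np.isinf(params.d0)
    # complete shrinkage: every moderated variance equals the prior
    t, _, _ = de.moderate(np.ones(60), s2, 10, 0.25, params)
    assert np.allclose(t, 1.0 / np.sqrt(params.s0_sq * 0.25))


def test_prior_df_recovered_from_scaled_f(rng):
    """Simulated variances with known prior df 4 are recovered by the
    moment-matching estimator within 25% (median over replicates)."""
    d0_true, s0_sq, dg = 4.0, 0.25, 16
    ratios = []
    for _ in range(50):
        sigma2 = d0_true * s0_sq / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(dg, size=5000) / dg
        ratios.append(de.estimate_ebayes(s2, dg).d0 / d0_true)
    assert abs(np.median(ratios) - 1.0) < 0.25


def test_fisher_combination_examples():
    # both strata null -> X = 0 -> combined p = 1
    assert de.fisher_combine(np.array([1.0]), np.array([1.0]))[0] == pytest.approx(1.0)
    # two p = 0.05: X = -2(ln .05 + ln .05) = 11.9829, chi2_4 upper tail
    X = -2 * (np.log(0.05) + np.log(0.05))
    expect = stats.chi2.sf(X, 4)
    got = de.fisher_combine(np.array([0.05]), np.array([0.05]))[0]
    assert got == pytest.approx(expect, rel=1e-12)
    assert got == pytest.approx(0.0175, abs=5e-4)
    # symmetry in strata
    assert de.fisher_combine(np.array([0.01]), np.array([0.2]))[0] == pytest.approx(
        de.fisher_combine(np.array([0.2]), np.array([0.01]))[0]
    )


@settings(max_examples=200, deadline=None)
@given(
    p1=st.floats(1e-10, 1.0), p2=st.floats(1e-10, 1.0), shrink=st.floats(0.01, 1.0)
)
def test_fisher_combination_monotone(p1, p2, shrink):
    """Decreasing either stratum p never increases the combined p."""
    base = de.fisher_combine(np.array([p1]), np.array([p2]))[0]
    better = de.fisher_combine(np.array([p1 * shrink]), np.array([p2]))[0]
    assert better <= base + 1e-15


def _records(tx, lfc, p, stratum):
    return pd.DataFrame(
        {"transcript_id": tx, "stratum": stratum, "log2FC": lfc, "s2": 0.1,
         "df": 5, "t": 1.0, "p": p}
    ).set_index("transcript_id", drop=False).rename_axis(None)


def test_meta_classification_rules():
    h = _records(["a", "b", "c"], [3.0, 3.0, 0.5], [0.01, 0.01, 0.9], "healthy")
    i = _records(["a", "b", "c"], [2.5, -3.0, 0.1], [0.01, 0.01, 0.9], "inflamed")
    m = de.meta_combine(h, i, "I")
    assert m.loc["a", "class"] == "consistent"
    assert m.loc["b", "class"] == "opposite"
    assert m.loc["c", "class"] == "null"
    # p = 1 in both strata is a null classification with combined p 1
    h1 = _records(["z"], [3.0], [1.0], "healthy")
    i1 = _records(["z"], [3.0], [1.0], "inflamed")
    m1 = de.meta_combine(h1, i1, "I")
    assert m1.loc["z", "combined_p"] == pytest.approx(1.0)
    assert m1.loc["z", "class"] == "null"


def test_single_stratum_transcripts_excluded():
    h = _records(["a", "b"], [3.0, 3.0], [0.01, 0.01], "healthy")
    i = _records(["a"], [2.5], [0.01], "inflamed")
    m = de.meta_combine(h, i, "I")
    assert list(m.index) == ["a"]


def test_approach_iii_uses_stringent_threshold():
    # two stratum ps of 0.04 combine to ~0.012: inside 0.05, outside 0.005
    h = _records(["a"], [3.0], [0.04], "healthy")
    i = _records(["a"], [2.5], [0.04], "inflamed")
    assert de.meta_combine(h, i, "I").loc["a", "class"] == "consistent"
    assert de.meta_combine(h, i, "III").loc["a", "class"] == "null"


def test_run_approach_invariant_to_sample_order(cohort):
    frac = cohort.truth.true_fractions.copy()
    frac.columns = ["agg_T", "agg_mono_mac", "agg_dendritic", "agg_other"]
    t1 = de.run_approach(cohort.expression, cohort.sample_meta, frac, "II", "healthy")
    perm = np.random.default_rng(0).permutation(cohort.expression.tpm.shape[1])
    expr2 = ExpressionMatrix(tpm=cohort.expression.tpm.iloc[:, perm])
    t2 = de.run_approach(expr2, cohort.sample_meta.iloc[perm], frac, "II", "healthy")
    pd.testing.assert_frame_equal(t1, t2)


def test_planted_zero_noise_lfc_recovered():
    from isogx.simulate import CohortDesign, ExpressionParams, generate_expression

    design = CohortDesign(seed=8, n_transcripts=60, n_genes=40)
    params = ExpressionParams(
        lfc=3.0, n_planted_consistent=2, n_planted_opposite=2,
        noise_sd=0.0, loading_scale=0.0, covariate_sd=0.0,
    )
    expr, meta, truth = generate_expression(design, params)
    tab = de.run_approach(expr, meta, None, "I", "healthy")
    for tx, row in truth.planted_dei.iterrows():
        assert tab.loc[tx, "log2FC"] == pytest.approx(row["lfc_healthy"], abs=1e-8)


def test_rank_deficient_covariate_dropped(cohort):
    meta = cohort.sample_meta.copy()
    meta["azathioprine_use"] = meta["corticosteroid_use"]  # collinear
    X = de.build_design(meta[meta["tissue_state"] == "healthy"], "I")
    assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]
    with pytest.raises(ValueError, match="rank deficient"):
        de.build_design(meta[meta["tissue_state"] == "healthy"], "I", strict=True)
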