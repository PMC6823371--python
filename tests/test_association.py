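"""Effect models: residualization, mixed models, regressions, sibships."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
import scipy.stats as st

from autozyg import (BIN_BOUNDS, Sibship, bin_trait_means, estimate_kinship,
                     fit_binary, fit_bivariate, fit_partitioned,
                     fit_univariate, grammar_residuals, residualize,
                     select_full_sibs, within_sib_effect)
from autozyg.association import ResidualTrait

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

def test_residualize_intercept_only_centres():
    y = np.array([1.0, 2.0, 6.0])
    rt = residualize(y, np.ones((3, 1)))
    np.testing.assert_allclose(rt.residuals, y - 3.0)
    assert rt.mu == pytest.approx(3.0)


def test_residualize_perfect_fit_and_orthogonality():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"const": 1.0, "age": rng.normal(50, 10, 200),
                      "sex": rng.integers(1, 3, 200)})
    y_exact = 2.0 + 0.1 * X["age"] - 0.5 * X["sex"]
    np.testing.assert_allclose(residualize(y_exact, X).residuals, 0.0,
                               atol=1e-10)
    y = y_exact + rng.normal(size=200)
    eps = residualize(y, X).residuals
    for c in ("age", "sex"):
        assert abs(np.corrcoef(eps, X[c])[0, 1]) < 1e-10


def test_residualize_names_collinear_columns():
    X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0)})
    X["twice_a"] = 2 * X["a"]
    with pytest.raises(ValueError, match="twice_a"):
        residualize(np.zeros(10), X)


def test_grammar_identity_grm_equals_ols():
    rng = np.random.default_rng(1)
    n = 150
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 0.5] + rng.normal(size=n)
    rt, info = grammar_residuals(y, X, np.eye(n))
    np.testing.assert_allclose(rt.residuals, residualize(y, X).residuals,
                               atol=1e-8)
    assert info["sigma_g2"] == pytest.approx(0.0, abs=1e-6)


def test_grammar_recovers_variance_ratio():
    """sigma_g^2 / sigma_e^2 = 1 on a block-family GRM is recovered."""
    rng = np.random.default_rng(2)
    n_fam, fam_size = 80, 3
    n = n_fam * fam_size
    blk = np.full((fam_size, fam_size), 0.5) + 0.5 * np.eye(fam_size)
    A = sla.block_diag(*[blk] * n_fam)
    u = np.linalg.cholesky(A) @ rng.normal(size=n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 0.5] + u + rng.normal(size=n)
    _, info = grammar_residuals(y, X, A)
    ratio = info["sigma_g2"] / info["sigma_e2"]
    assert 0.5 < ratio < 2.0


def test_grammar_null_heritability_matches_ols():
    rng = np.random.default_rng(3)
    n = 120
    blk = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
    A = sla.block_diag(*[blk] * 40)
    X = np.ones((n, 1))
    y = rng.normal(size=n)                      # h2 = 0
    rt, info = grammar_residuals(y, X, A)
    assert info["sigma_g2"] < 0.15
    np.testing.assert_allclose(rt.residuals, residualize(y, X).residuals,
                               atol=0.25)


def test_grammar_rejects_bad_grm():
    y = np.zeros(4)
    X = np.ones((4, 1))
    with pytest.raises(ValueError):
        grammar_residuals(y, X, np.arange(16.0).reshape(4, 4))      # asymmetric
    bad = -np.eye(4)
    with pytest.raises(ValueError):
        grammar_residuals(y, X, bad)                                # negative


# ---------------------------------------------------------------------------
# Regression designs
# ---------------------------------------------------------------------------

def test_univariate_exact_fit():
    f = np.linspace(0, 0.25, 50)
    est = fit_univariate(-2.0 * f, f)
    assert est.beta == pytest.approx(-2.0)
    assert est.se < 1e-10 or est.se == pytest.approx(0, abs=1e-8)
    assert est.beta_0625 == pytest.approx(-0.125)


def test_univariate_centering_invariance():
    rng = np.random.default_rng(4)
    f = rng.uniform(0, 0.25, 100)
    y = -3 * f + rng.normal(size=100)
    a = fit_univariate(y, f)
    b = fit_univariate(y, f - f.mean())
    assert a.beta == pytest.approx(b.beta)
    assert a.se == pytest.approx(b.se)


def test_univariate_permutation_null():
    """Permuting the estimator kills the effect at the nominal error rate."""
    rng = np.random.default_rng(5)
    f = rng.uniform(0, 0.25, 300)
    y = -4 * f + rng.normal(size=300)
    hits = 0
    reps = 200
    for _ in range(reps):
        est = fit_univariate(y, rng.permutation(f))
        hits += abs(est.beta / est.se) > 1.96
    assert 0.005 < hits / reps < 0.12


def test_univariate_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_univariate(np.zeros(10), np.full(10, 0.1))
    with pytest.raises(ValueError):
        fit_univariate(np.zeros(2), np.array([0.0, 1.0]))


def test_partitioned_zero_trait_and_collinear_flag():
    rng = np.random.default_rng(6)
    f1 = rng.uniform(0, 0.1, 60)
    f2 = rng.uniform(0, 0.1, 60)
    ests = fit_partitioned(np.zeros(60), f1, f2, rng.uniform(0, 0.1, 60))
    for e in ests:
        assert e.beta == pytest.approx(0.0, abs=1e-10)
    ests2 = fit_partitioned(rng.normal(size=60), f1, f2, f2)   # lt5 == gt5
    flagged = {e.model_tag for e in ests2 if "collinear" in e.flags}
    assert {"part_lt5", "part_gt5"} <= flagged


def test_bivariate_conditional_equals_univariate_with_noise_proxy():
    """Adding an independently-noised copy of F leaves the conditional
    F slope at its univariate value (the attenuation logic's clean case)."""
    rng = np.random.default_rng(7)
    n = 4000
    f = rng.uniform(0, 0.25, n)
    y = -8.0 * f + rng.normal(size=n)
    f_noisy = f + rng.normal(0, 0.05, n)
    uni = fit_univariate(y, f)
    biv = fit_bivariate(y, f, f_noisy)
    assert abs(biv[0].beta - uni.beta) < 3 * biv[0].se
    assert abs(biv[1].beta) < 3 * biv[1].se


def test_bivariate_ordering_follows_signal_carrier():
    """Whichever estimator carries the causal signal dominates jointly."""
    rng = np.random.default_rng(8)
    n = 3000
    shared = rng.uniform(0, 0.2, n)
    f_roh = shared + rng.normal(0, 0.02, n)
    f_grm = shared + rng.normal(0, 0.02, n)
    y_roh = -10.0 * f_roh + rng.normal(size=n)
    ests = fit_bivariate(y_roh, f_roh, f_grm)
    assert abs(ests[0].beta) > abs(ests[1].beta)
    y_grm = -10.0 * f_grm + rng.normal(size=n)
    ests2 = fit_bivariate(y_grm, f_roh, f_grm)
    assert abs(ests2[1].beta) > abs(ests2[0].beta)


def test_bivariate_perfect_collinearity_errors():
    f = np.linspace(0, 0.2, 30)
    with pytest.raises(ValueError):
        fit_bivariate(np.zeros(30), f, 2 * f)


def test_attenuation_law():
    """beta-ratio vs variance-ratio across noise levels has unit slope."""
    rng = np.random.default_rng(9)
    n = 20_000
    f = rng.uniform(0, 0.25, n)
    y = -8.0 * f + rng.normal(size=n)
    base = fit_univariate(y, f).beta
    ratios, vratios = [], []
    for noise_sd in (0.02, 0.05, 0.08, 0.12):
        f_star = f + rng.normal(0, noise_sd, n)
        ratios.append(fit_univariate(y, f_star).beta / base)
        vratios.append(np.var(f) / np.var(f_star))
    slope = st.linregress(vratios, ratios).slope
    assert slope == pytest.approx(1.0, abs=0.1)


def test_binary_contingency_table_matches_hand_odds_ratio():
    """Binary F in {0, 0.0625} reproduces the 2x2-table ln(OR) exactly."""
    n0_case, n0_ctl, n1_case, n1_ctl = 100, 900, 150, 850
    y = np.r_[np.ones(n0_case), np.zeros(n0_ctl),
              np.ones(n1_case), np.zeros(n1_ctl)]
    f = np.r_[np.zeros(n0_case + n0_ctl), np.full(n1_case + n1_ctl, 0.0625)]
    est = fit_binary(y, f, method="logit")
    hand_or = (n1_case / n1_ctl) / (n0_case / n0_ctl)
    assert est.beta * 0.0625 == pytest.approx(np.log(hand_or), abs=1e-6)


def test_binary_logit_and_linear_approximation_agree():
    """Both routes to ln(OR) agree within their joint CI on a grid."""
    rng = np.random.default_rng(10)
    n = 6000
    for lnor_0625 in (-0.4, -0.1, 0.3):
        beta_true = lnor_0625 / 0.0625
        f = rng.uniform(0, 0.25, n)
        eta = -0.3 + beta_true * f
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.ones((n, 1))
        a = fit_binary(y, f, X, method="logit")
        b = fit_binary(y, f, X, method="linapprox")
        joint = np.sqrt(a.se ** 2 + b.se ** 2)
        assert abs(a.beta - b.beta) < 1.96 * joint
        assert abs(a.beta - beta_true) < 3 * a.se


def test_binary_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_binary(np.ones(20), np.linspace(0, 1, 20))
    with pytest.raises(ValueError):
        fit_binary(np.r_[np.ones(10), np.zeros(10)], np.full(20, 0.1))
    # perfect separation on f
    y = np.r_[np.zeros(20), np.ones(20)]
    f = np.r_[np.zeros(20), np.full(20, 0.25)]
    with pytest.raises(ValueError):
        fit_binary(y, f, method="logit")


# ---------------------------------------------------------------------------
# Binned means
# ---------------------------------------------------------------------------

def test_bin_placement_against_printed_bounds():
    f = np.array([0.0, 0.05, 0.0015, 0.17, 0.99])
    df = bin_trait_means(np.zeros(5), 0.0, f)
    placed = {}
    for b in df.itertuples():
        if b.n:
            placed[b.bin] = b.n
    assert placed == {1: 2, 7: 1, 9: 1, 10: 1}     # 0.05 -> bin 7, 0 -> bin 1
    assert df["lo"].tolist() == list(BIN_BOUNDS[:-1])
    with pytest.raises(ValueError):
        bin_trait_means(np.zeros(2), 0.0, np.array([-0.1, 0.5]))


def test_bin_means_fall_on_fitted_line():
    rng = np.random.default_rng(11)
    n = 5000
    f = rng.beta(0.6, 6, n) * 0.4
    f = np.clip(f, 0, 1)
    y = -10.0 * f + rng.normal(0, 0.5, n)
    est = fit_univariate(y, f)
    df = bin_trait_means(y, est.mu, f)
    good = df[df["n"] > 30]
    assert len(good) >= 5
    pred = est.beta * good["mean_f"]
    dev = (good["mean_resid"] - pred) / good["se_resid"]
    assert np.abs(dev).max() < 4.0


# ---------------------------------------------------------------------------
# Kinship and the within-sibling design
# ---------------------------------------------------------------------------

def _hwe_person(rng, p):
    return rng.binomial(1, p) + rng.binomial(1, p)


def test_kinship_reference_pairs():
    """Duplicate ~0.5, unrelated ~0, full sibs ~0.25 with IBS0 > 0.001,
    parent-offspring ~0.25 with IBS0 = 0."""
    rng = np.random.default_rng(12)
    nv = 4000
    p = rng.uniform(0.1, 0.9, nv)
    mumA = rng.binomial(1, p, (2, nv))          # two haplotypes each
    dadA = rng.binomial(1, p, (2, nv))
    mumB = rng.binomial(1, p, (2, nv))
    dadB = rng.binomial(1, p, (2, nv))

    def child(mum, dad):
        return (mum[rng.integers(0, 2, nv), np.arange(nv)]
                + dad[rng.integers(0, 2, nv), np.arange(nv)])

    sib1, sib2 = child(mumA, dadA), child(mumA, dadA)
    unrel = child(mumB, dadB)
    parent = mumA.sum(axis=0)
    calls = np.vstack([sib1, sib1, sib2, unrel, parent]).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10**8), nv, replace=False))
    g = make_matrix(calls, pos=pos,
                    sample_ids=["dup1", "dup2", "sib2", "unrel", "parent"])
    pairs = estimate_kinship(g).set_index(["id1", "id2"])
    assert pairs.loc[("dup1", "dup2"), "kinship"] == pytest.approx(0.5, abs=0.02)
    assert pairs.loc[("dup1", "dup2"), "ibs0"] == 0.0
    assert pairs.loc[("dup1", "sib2"), "kinship"] == pytest.approx(0.25, abs=0.04)
    assert pairs.loc[("dup1", "sib2"), "ibs0"] > 0.001
    assert abs(pairs.loc[("dup1", "unrel"), "kinship"]) < 0.04
    assert pairs.loc[("dup1", "parent"), "kinship"] == pytest.approx(0.25, abs=0.04)
    assert pairs.loc[("dup1", "parent"), "ibs0"] == 0.0

    sibs = select_full_sibs(estimate_kinship(g))
    members = {frozenset(s.members) for s in sibs}
    assert frozenset({"dup1", "dup2", "sib2"}) in members      # PO pair excluded
    assert all("parent" not in s.members for s in sibs)
    assert any(s.has_mz_like for s in sibs)


def test_select_full_sibs_transitive_closure_and_empty():
    pairs = pd.DataFrame({"id1": ["a", "b"], "id2": ["b", "c"],
                          "kinship": [0.24, 0.26], "ibs0": [0.01, 0.01],
                          "n_shared": [1000, 1000]})
    sibs = select_full_sibs(pairs)
    assert len(sibs) == 1 and sorted(sibs[0].members) == ["a", "b", "c"]
    none = select_full_sibs(pairs.assign(kinship=[0.05, 0.02]))
    assert none == []


def test_within_sib_hand_arithmetic():
    """One sibship, F = (0.01, 0.03), residuals (1.0, 0.0): slope -50."""
    est = within_sib_effect(np.array([1.0, 0.0]), np.array([0.01, 0.03]),
                            [Sibship("f1", ["a", "b"])], ["a", "b"])
    assert est.beta == pytest.approx(-50.0)


def test_within_sib_mz_only_errors():
    with pytest.raises(ValueError):
        within_sib_effect(np.array([1.0, 0.0]), np.array([0.02, 0.02]),
                          [Sibship("f1", ["a", "b"])], ["a", "b"])


def test_sex_specific_fits_recover_configured_ratio():
    """Per-sex fits on a sex-scaled effect recover the male/female ratio."""
    rng = np.random.default_rng(13)
    n = 6000
    f = rng.uniform(0, 0.25, n)
    sex = rng.integers(1, 3, n)
    slope = np.where(sex == 1, -8.0, -4.0)      # males twice as affected
    y = slope * f + rng.normal(size=n)
    em = fit_univariate(y[sex == 1], f[sex == 1], "by_sex_male")
    ef = fit_univariate(y[sex == 2], f[sex == 2], "by_sex_female")
    assert em.beta == pytest.approx(-8.0, abs=3 * em.se)
    assert ef.beta == pytest.approx(-4.0, abs=3 * ef.se)
    ratio = em.beta / ef.beta
    assert 1.6 < ratio < 2.5
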