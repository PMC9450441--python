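"""GREML variance components and GBLUP prediction."""

import numpy as np
import pandas as pd
import pytest

from rfigp.genio import GRM
from rfigp.grm import build_grm_yang
from rfigp.mixedmodel import (GebvSet, TraitData, VarianceComponents,
                              fit_greml, genetic_correlation, heritability,
                              predict_gebv)
from rfigp.synthetic_data import simulate_bundle

from conftest import hwe_genotypes


def _identity_grm(n):
    return GRM(np.eye(n), [f"a{i}" for i in range(n)], 1)


def _sim_univariate(n=300, m=1000, h2=0.4, seed=0):
    gm = hwe_genotypes(n, m, seed=seed)
    g = build_grm_yang(gm, maf_min=0.01)
    rng = np.random.default_rng(seed + 1)
    w, v = np.linalg.eigh(g.matrix)
    gv = (v * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n)
    gv *= np.sqrt(h2) / gv.std()
    y = gv + rng.normal(0, np.sqrt(1 - h2), n)
    td = TraitData("t", gm.animal_ids, y, np.ones((n, 1)))
    return td, g, gv


def test_identity_grm_is_unidentifiable_with_ols_likelihood():
    """With G = I the genetic and residual variances are confounded; the REML
    likelihood must equal the closed-form OLS value."""
    rng = np.random.default_rng(0)
    n = 60
    y = rng.normal(2.0, 1.3, n)
    td = TraitData("t", [f"a{i}" for i in range(n)], y, np.ones((n, 1)))
    vc = fit_greml(td, _identity_grm(n))
    assert vc.unidentifiable
    rss = np.sum((y - y.mean()) ** 2)
    sigma2 = rss / (n - 1)
    expected = -0.5 * ((n - 1) * np.log(sigma2) + np.log(n) + (n - 1))
    assert vc.log_likelihood == pytest.approx(expected, abs=1e-8)
    assert vc.P[0, 0] + vc.R[0, 0] == pytest.approx(sigma2, rel=1e-6)


def test_univariate_recovery_and_se_scale():
    td, g, _ = _sim_univariate(n=600, m=2000, h2=0.4, seed=3)
    vc = fit_greml(td, g)
    h2, se = heritability(vc)
    assert abs(h2 - 0.4) < 3 * se
    assert 0 < se < 0.3


def test_heritability_arithmetic():
    vc = VarianceComponents(np.array([[0.30]]), np.array([[0.70]]),
                            np.zeros((1, 1)), np.zeros((1, 1)), 0.0, 1, True,
                            ["t"], [("G", 0, 0), ("R", 0, 0)], np.zeros((2, 2)))
    assert heritability(vc)[0] == pytest.approx(0.30)
    vc0 = VarianceComponents(np.array([[0.0]]), np.array([[1.0]]),
                             np.zeros((1, 1)), np.zeros((1, 1)), 0.0, 1, True,
                             ["t"], [("G", 0, 0), ("R", 0, 0)], np.zeros((2, 2)))
    assert heritability(vc0)[0] == 0.0


def test_genetic_correlation_arithmetic_and_degenerate():
    P = np.array([[1.0, 0.95], [0.95, 1.0]])
    vc = VarianceComponents(P, np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)),
                            0.0, 1, True, ["a", "b"],
                            [("G", 0, 0), ("G", 0, 1), ("G", 1, 1),
                             ("R", 0, 0), ("R", 1, 1)], np.zeros((5, 5)))
    assert genetic_correlation(vc)[0] == pytest.approx(0.95)
    vc.P = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert genetic_correlation(vc)[0] == pytest.approx(0.0)
    vc.P = np.array([[0.0, 0.0], [0.0, 1.0]])
    with pytest.warns(UserWarning, match="undefined"):
        rg, se = genetic_correlation(vc)
    assert np.isnan(rg)


def test_predict_shrinkage_limit_returns_centred_phenotypes():
    rng = np.random.default_rng(5)
    n = 40
    y = rng.normal(size=n)
    td = TraitData("t", [f"a{i}" for i in range(n)], y, np.ones((n, 1)))
    vc = VarianceComponents(np.array([[1.0]]), np.array([[1e-8]]),
                            np.zeros((1, 1)), np.zeros((1, 1)), 0.0, 1, True,
                            ["t"], [("G", 0, 0), ("R", 0, 0)])
    gebv = predict_gebv(td, _identity_grm(n), vc)
    assert np.abs(gebv.table["t"].to_numpy() - (y - y.mean())).max() < 1e-6


def test_masked_animal_gebv_matches_conditional_expectation():
    """Validation-animal GEBV equal the closed-form conditional mean."""
    td, g, _ = _sim_univariate(n=80, m=400, h2=0.5, seed=7)
    vc = fit_greml(td, g)
    train = td.animal_ids[:60]
    val = td.animal_ids[60:]
    td_train = TraitData("t", train, td.y[:60], td.X[:60])
    gebv = predict_gebv(td_train, g, vc, animals=val)
    sg2, se2 = vc.P[0, 0], vc.R[0, 0]
    gtt = g.matrix[:60, :60]
    gvt = g.matrix[60:, :60]
    v = sg2 * gtt + se2 * np.eye(60)
    vi = np.linalg.inv(v)
    x = td.X[:60]
    b = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ td.y[:60])
    expected = sg2 * gvt @ vi @ (td.y[:60] - x @ b)
    assert np.abs(gebv.table["t"].to_numpy() - expected).max() < 1e-8


def test_gebv_invariant_to_covariate_shift():
    td, g, _ = _sim_univariate(n=100, m=400, h2=0.4, seed=9)
    rng = np.random.default_rng(1)
    cov = rng.normal(size=100)
    td1 = TraitData("t", td.animal_ids, td.y, np.column_stack([np.ones(100), cov]))
    td2 = TraitData("t", td.animal_ids, td.y, np.column_stack([np.ones(100), cov + 57.0]))
    vc = fit_greml(td1, g)
    g1 = predict_gebv(td1, g, vc).table["t"].to_numpy()
    g2 = predict_gebv(td2, g, vc).table["t"].to_numpy()
    assert np.abs(g1 - g2).max() < 1e-8


def test_bivariate_perfect_correlation_matches_pooled_single_trait():
    """rg = 1 with equal variances is the same model as pooling the records."""
    gm = hwe_genotypes(240, 800, seed=13)
    g = build_grm_yang(gm, maf_min=0.01)
    rng = np.random.default_rng(14)
    w, v = np.linalg.eigh(g.matrix)
    gv = (v * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(240)
    gv *= np.sqrt(0.4) / gv.std()
    y = gv + rng.normal(0, np.sqrt(0.6), 240)
    ids = gm.animal_ids
    td_a = TraitData("a", ids[:120], y[:120], np.ones((120, 1)))
    td_b = TraitData("b", ids[120:], y[120:], np.ones((120, 1)))
    sg2, se2 = 0.4, 0.6
    vc_biv = VarianceComponents(
        sg2 * np.array([[1.0, 1.0], [1.0, 1.0]]), se2 * np.eye(2),
        np.zeros((2, 2)), np.zeros((2, 2)), 0.0, 1, True, ["a", "b"],
        [("G", 0, 0), ("G", 0, 1), ("G", 1, 1), ("R", 0, 0), ("R", 1, 1)])
    vc_uni = VarianceComponents(np.array([[sg2]]), np.array([[se2]]),
                                np.zeros((1, 1)), np.zeros((1, 1)), 0.0, 1, True,
                                ["pooled"], [("G", 0, 0), ("R", 0, 0)])
    gb = predict_gebv([td_a, td_b], g, vc_biv).table["a"].to_numpy()
    gu = predict_gebv(TraitData("pooled", ids, y, np.ones((240, 1))), g,
                      vc_uni).table["pooled"].to_numpy()
    assert np.corrcoef(gb, gu)[0, 1] > 0.99


def test_bivariate_logl_monotone_and_disjoint_residual_cov_fixed():
    gm, ped, rec, truth = simulate_bundle(
        n_countries=2, animals_per_country=150, n_heifers=0, n_chrom=4,
        n_sequence_variants=1000, n_qtl=300, n_large_qtl=5, n_bw_qtl=40,
        h2=(0.3, 0.3), genetic_correlation_matrix=((1.0, 0.8), (0.8, 1.0)),
        pheno_sd=(1.5, 1.5), n_founder_haplotypes=60, seed=17)
    g = build_grm_yang(gm, maf_min=0.01)
    home = truth[truth.dataset == "home_cow"]
    ove = truth[truth.dataset != "home_cow"]
    td1 = TraitData("home", list(home.animal_id), home.pheno_direct.to_numpy(),
                    np.ones((len(home), 1)))
    td2 = TraitData("ove", list(ove.animal_id), ove.pheno_direct.to_numpy(),
                    np.ones((len(ove), 1)))
    vc = fit_greml([td1, td2], g)
    diffs = np.diff(vc.logl_path)
    assert (diffs > -1e-5).all()          # monotone up to accept tolerance
    # disjoint cohorts: no residual covariance parameter exists
    assert ("R", 0, 1) not in vc.param_names
    assert vc.R[0, 1] == 0.0


def test_predict_refuses_unconverged_components():
    td, g, _ = _sim_univariate(n=50, m=200, seed=21)
    vc = fit_greml(td, g)
    vc.converged = False
    with pytest.raises(RuntimeError, match="converge"):
        predict_gebv(td, g, vc)
    assert isinstance(predict_gebv(td, g, vc, allow_unconverged=True), GebvSet)
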