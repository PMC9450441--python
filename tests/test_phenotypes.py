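"""ECM arithmetic, orthogonal polynomials, body-weight change, RFI derivation."""

import numpy as np
import pandas as pd
import pytest

from rfigp.phenotypes import (RfiModelSpec, compute_delta_bw, compute_ecm,
                              derive_rfi, lactating_cow_model, orthogonal_poly,
                              parity_stage, standardise, standardise_by_dataset)
from rfigp.pipeline import prepare_phenotypes
from rfigp.synthetic_data import simulate_bundle


@pytest.mark.parametrize("milk,fat,protein,expected", [
    (0.0, 0.0, 0.0, 0.0),
    (20.0, 0.8, 0.7, 7.98),
    (10.0, 1.0, 1.0, 8.8),
])
def test_ecm_weighted_combination(milk, fat, protein, expected):
    assert compute_ecm(milk, fat, protein) == pytest.approx(expected, abs=1e-12)


def test_ecm_rejects_negative_yield():
    with pytest.raises(ValueError, match="negative"):
        compute_ecm(-1.0, 0.5, 0.5)


def test_orthogonal_poly_degree_one_is_centred_x():
    x = np.array([3.0, 7.0, 11.0, 2.0])
    basis = orthogonal_poly(x, 1)
    centred = x - x.mean()
    assert abs(abs(np.corrcoef(basis[:, 0], centred)[0, 1]) - 1.0) < 1e-12
    assert basis[:, 0] @ np.ones(4) == pytest.approx(0.0, abs=1e-12)


def test_orthogonal_poly_columns_mutually_orthogonal():
    basis = orthogonal_poly(np.array([1.0, 2.0, 3.0]), 2)
    gram = basis.T @ basis
    assert np.allclose(gram, np.eye(2), atol=1e-12)
    assert np.allclose(basis.sum(axis=0), 0.0, atol=1e-12)


def test_orthogonal_poly_degree5_matches_raw_monomial_fit():
    """Degree-5 orthogonal basis spans the same space as raw monomials."""
    dim = np.arange(5, 307, dtype=float)
    rng = np.random.default_rng(0)
    y = 600 + 0.5 * dim - 0.002 * dim**2 + rng.normal(0, 5, dim.size)
    basis = orthogonal_poly(dim, 5)
    x_orth = np.column_stack([np.ones(dim.size), basis])
    fit_orth = x_orth @ np.linalg.lstsq(x_orth, y, rcond=None)[0]
    # raw-monomial oracle on a rescaled axis (raw DIM^5 is ill-conditioned)
    x_raw = np.vander((dim - dim.mean()) / 150.0, 6, increasing=True)
    fit_raw = x_raw @ np.linalg.lstsq(x_raw, y, rcond=None)[0]
    assert np.abs(fit_orth - fit_raw).max() < 1e-8


def test_orthogonal_poly_too_few_distinct_values():
    with pytest.raises(ValueError, match="distinct"):
        orthogonal_poly(np.array([1.0, 1.0, 2.0]), 2)


def test_delta_bw_linear_trajectory():
    dim = np.linspace(5, 200, 12)
    dbw = compute_delta_bw(dim, 500 + 0.5 * dim)
    assert np.abs(dbw - 0.5).max() < 1e-8


def test_delta_bw_constant_weight():
    dim = np.linspace(5, 300, 10)
    assert np.abs(compute_delta_bw(dim, np.full(10, 620.0))).max() < 1e-8


def test_delta_bw_quadratic_matches_analytic_difference():
    dim = np.linspace(5, 306, 40)
    dbw = compute_delta_bw(dim, 0.01 * dim**2)
    assert np.abs(dbw - 0.01 * (2 * dim - 1)).max() < 1e-6


def test_delta_bw_insufficient_span_returns_none():
    assert compute_delta_bw([10, 12, 14, 16, 18, 20, 22], np.arange(7) * 1.0) is None
    assert compute_delta_bw([10, 50, 90], [1.0, 2.0, 3.0]) is None


def _toy_records(n=120, seed=1, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(n)],
        "cg": rng.choice(["g1", "g2", "g3"], n),
        "parity": rng.integers(1, 4, n),
        "DIM": rng.integers(5, 306, n).astype(float),
        "ECM": rng.normal(8, 1, n),
        "MBW": rng.normal(600, 40, n),
        "dBW": rng.normal(0.1, 0.2, n),
    })
    cg_eff = df["cg"].map({"g1": 0.0, "g2": 1.0, "g3": -0.5})
    df["DMI"] = (12 + 0.3 * df["ECM"] + 0.02 * df["MBW"] + 1.1 * df["dBW"]
                 + 0.2 * df["parity"] + 0.005 * df["DIM"] + cg_eff
                 + rng.normal(0, noise, n))
    return df


def test_rfi_zero_when_dmi_is_exact_model_function():
    df = _toy_records(noise=0.0)
    out = derive_rfi(df, lactating_cow_model())
    assert np.abs(out["RFI"]).max() < 1e-8


def test_rfi_residual_mean_zero():
    df = _toy_records(noise=1.0)
    spec = lactating_cow_model()
    work = df.dropna(subset=spec.covariates + ["DMI"])
    out = derive_rfi(df, spec)
    # per-record residuals average zero by OLS; per-animal means re-aggregate them
    total = (out["RFI"] * out["n_records"]).sum()
    assert abs(total / len(work)) < 1e-10


def test_rfi_affine_invariance_of_covariates():
    df = _toy_records(noise=1.0)
    base = derive_rfi(df, lactating_cow_model())
    shifted = df.copy()
    shifted["ECM"] = 3.0 * shifted["ECM"] + 100.0
    shifted["MBW"] = shifted["MBW"] - 550.0
    again = derive_rfi(shifted, lactating_cow_model())
    assert np.abs(base["RFI"].to_numpy() - again["RFI"].to_numpy()).max() < 1e-8


def test_rfi_recovers_injected_deviation():
    """With noise-free intake records the derived RFI matches the simulator's truth."""
    gm, ped, rec, truth = simulate_bundle(
        n_countries=1, animals_per_country=2000, n_heifers=0,
        n_chrom=4, n_sequence_variants=800, n_qtl=200, n_large_qtl=5, n_bw_qtl=40,
        h2=(0.3,), genetic_correlation_matrix=((1.0,),), pheno_sd=(1.5,),
        n_founder_haplotypes=60, record_noise_sd=0.0, seed=9)
    rec = rec.copy()
    rec["ECM"] = compute_ecm(rec["milk"], rec["fat"], rec["protein"])
    rec["MBW"] = rec["BW"]
    derived = derive_rfi(rec, lactating_cow_model())
    merged = derived.merge(truth[["animal_id", "rfi_true"]], on="animal_id")
    r = np.corrcoef(merged["RFI"], merged["rfi_true"])[0, 1]
    assert r > 0.95


def test_standardise_hand_example_and_idempotence():
    z = standardise([1.0, 2.0, 3.0])
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    assert np.allclose(standardise(z), z, atol=1e-12)


def test_standardise_constant_vector_errors():
    with pytest.raises(ValueError, match="variance"):
        standardise([2.0, 2.0, 2.0], label="flat")


def test_standardise_by_dataset_pooled_moments():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"dataset": np.repeat(["a", "b", "c"], 50),
                       "RFI": rng.normal([0, 5, -2], [1, 3, 0.5], (50, 3)).T.ravel()})
    out = standardise_by_dataset(df)
    stats = out.groupby("dataset")["RFI"].agg(["mean", "std"])
    assert np.allclose(stats["mean"], 0.0, atol=1e-12)
    assert np.allclose(stats["std"], 1.0, atol=1e-12)


def test_parity_stage_levels():
    ps = parity_stage([1, 2, 5, 3], [10, 50, 150, 250])
    assert ps.tolist() == ["p1_s1", "p2_s2", "p3+_s3", "p3+_s4"]


def test_derived_cow_rfi_sd_in_observed_band(small_bundle):
    """Unstandardised cow RFI dispersion falls in the plausible 1.17-3.04 band."""
    rec = small_bundle.records
    cows = rec[rec["dataset"] != "home_heifer"].copy()
    cows["ECM"] = compute_ecm(cows["milk"], cows["fat"], cows["protein"])
    cows["MBW"] = cows["BW"]
    sds = []
    for _, grp in cows.groupby("dataset"):
        sds.append(derive_rfi(grp, lactating_cow_model())["RFI"].std())
    assert all(1.17 <= sd <= 3.04 for sd in sds)
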