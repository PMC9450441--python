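"""Yang GRM, weighted combination, PCA, FST, NJ tree, heterozygosities."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from rfigp.genio import GRM, GenotypeMatrix
from rfigp.grm import (build_grm_yang, combine_weighted_grm,
                       effective_maf_threshold, grm_pca, heterozygosity_report,
                       nj_tree, pairwise_fst)
from rfigp.synthetic_data import make_panel

from conftest import hwe_genotypes


def _gm(dosages, ids=None):
    n, m = np.asarray(dosages).shape
    variants = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": ["1"] * m,
                             "pos": np.arange(1, m + 1), "a1": ["A"] * m,
                             "a2": ["B"] * m})
    return GenotypeMatrix(ids or [f"a{i}" for i in range(n)], variants, dosages)


def test_yang_offdiagonal_hand_example():
    """Two animals, one variant, dosages (0,2): (0-1)(2-1)/(2*0.5*0.5) = -2."""
    g = build_grm_yang(_gm([[0], [2]]), maf_min=0.0)
    assert g.matrix[0, 1] == pytest.approx(-2.0)


def test_identical_genotypes_make_offdiagonal_equal_diagonal():
    row = [0, 1, 2, 1, 0, 2, 1]
    g = build_grm_yang(_gm([row, row, row]), maf_min=0.0)
    assert g.matrix[0, 1] == pytest.approx(g.matrix[0, 0])


def test_yang_grm_hwe_population_calibration():
    gm = hwe_genotypes(500, 5000, seed=11)
    g = build_grm_yang(gm, maf_min=0.01)
    diag = np.diag(g.matrix)
    off = g.matrix[np.triu_indices(500, 1)]
    assert 0.98 < diag.mean() < 1.02
    assert -0.01 < off.mean() < 0.01


def test_grm_invariant_to_variant_and_animal_order():
    gm = hwe_genotypes(40, 300, seed=5)
    g = build_grm_yang(gm, maf_min=0.01)
    rng = np.random.default_rng(0)
    vperm = rng.permutation(300)
    aperm = rng.permutation(40)
    gm2 = GenotypeMatrix([gm.animal_ids[i] for i in aperm],
                         gm.variants.iloc[vperm], gm.dosages[np.ix_(aperm, vperm)])
    g2 = build_grm_yang(gm2, maf_min=0.01)
    assert np.allclose(g2.matrix, g.matrix[np.ix_(aperm, aperm)], atol=1e-10)


def test_monomorphic_only_errors():
    with pytest.raises(ValueError):
        build_grm_yang(_gm([[2], [2], [2]]), maf_min=0.0)


@pytest.mark.parametrize("n,expected", [(2000, 0.01), (200, 0.05), (500, 0.02)])
def test_effective_maf_threshold(n, expected):
    assert effective_maf_threshold(n) == pytest.approx(expected)


def test_combine_weighted_grm_cases():
    a = GRM(np.eye(2), ["x", "y"], 10)
    b = GRM(2 * np.eye(2), ["x", "y"], 5)
    assert np.allclose(combine_weighted_grm(a, b, 1.0, 0.0).matrix, a.matrix)
    assert np.allclose(combine_weighted_grm(a, b, 1.0, 1.0).matrix, 1.5 * np.eye(2))
    assert np.allclose(combine_weighted_grm(a, b, 3.0, 1.0).matrix, 1.25 * np.eye(2))
    with pytest.raises(ValueError):
        combine_weighted_grm(a, b, 0.0, 0.0)
    with pytest.raises(ValueError):
        combine_weighted_grm(a, GRM(np.eye(2), ["x", "z"], 5), 1.0, 1.0)


def test_combine_weighted_is_convex_combination():
    rng = np.random.default_rng(3)
    m1 = rng.normal(size=(6, 6)); m1 = m1 @ m1.T
    m2 = rng.normal(size=(6, 6)); m2 = m2 @ m2.T
    ids = [f"a{i}" for i in range(6)]
    w = combine_weighted_grm(GRM(m1, ids, 1), GRM(m2, ids, 1), 2.0, 3.0)
    lo = (2 * np.linalg.eigvalsh(m1).min() + 3 * np.linalg.eigvalsh(m2).min()) / 5
    hi = (2 * np.linalg.eigvalsh(m1).max() + 3 * np.linalg.eigvalsh(m2).max()) / 5
    vals = np.linalg.eigvalsh(w.matrix)
    assert vals.min() >= lo - 1e-10 and vals.max() <= hi + 1e-10


def test_pca_identity_grm_no_structure():
    g = GRM(np.eye(5), [f"a{i}" for i in range(5)], 1)
    ps = grm_pca(g, 3, center=False)
    assert np.allclose(ps.eigenvalues, 1.0)


def test_pca_two_block_grm_separates_blocks():
    mat = np.block([[np.ones((4, 4)), np.zeros((4, 4))],
                    [np.zeros((4, 4)), np.ones((4, 4))]])
    np.fill_diagonal(mat, 1.1)
    g = GRM(mat, [f"a{i}" for i in range(8)], 1)
    ps = grm_pca(g, 2)
    pc1 = ps.pc_scores[:, 0]
    assert np.ptp(np.sign(pc1[:4])) == 0 and np.ptp(np.sign(pc1[4:])) == 0
    assert np.sign(pc1[0]) != np.sign(pc1[4])


def test_pca_separates_simulated_drifted_countries():
    from rfigp.synthetic_data import SimulationConfig, simulate_genotypes
    cfg = SimulationConfig(n_countries=2, animals_per_country=120, n_heifers=0,
                           n_chrom=4, n_sequence_variants=2000, n_qtl=10,
                           h2=(0.3, 0.3),
                           genetic_correlation_matrix=((1, 0.9), (0.9, 1)),
                           pheno_sd=(1.5, 1.5), country_fst=0.05,
                           n_founder_haplotypes=100, global_sire_fraction=0.0,
                           seed=8)
    gm, ped = simulate_genotypes(cfg)
    g = build_grm_yang(gm, maf_min=0.05)
    ps = grm_pca(g, 2)
    pc1 = ps.pc_scores[:, 0]
    grp = (ped["country"] == "country0").to_numpy()
    pooled_sd = np.sqrt((pc1[grp].var() + pc1[~grp].var()) / 2)
    assert abs(pc1[grp].mean() - pc1[~grp].mean()) > 3 * pooled_sd


def test_pca_k_too_large():
    with pytest.raises(ValueError):
        grm_pca(GRM(np.eye(3), ["a", "b", "c"], 1), 4)


def test_fst_identical_frequencies_zero():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.4, size=(40, 200)).astype(np.int8)
    gm = _gm(np.vstack([d, d]))
    groups = pd.Series(["g1"] * 40 + ["g2"] * 40, index=gm.animal_ids)
    gst, gp = pairwise_fst(gm, groups)
    assert gst.loc["g1", "g2"] == pytest.approx(0.0, abs=1e-12)


def test_fst_fixed_difference_is_one():
    gm = _gm(np.array([[0], [0], [2], [2]]))
    groups = pd.Series(["a", "a", "b", "b"], index=gm.animal_ids)
    gst, gp = pairwise_fst(gm, groups)
    assert gst.loc["a", "b"] == pytest.approx(1.0)
    assert gp.loc["a", "b"] == pytest.approx(1.0)


def test_fst_hand_example_hedrick():
    """p1=0.6, p2=0.4: H_S=0.48, H_T=0.5, G_ST=0.04, G'_ST=0.04*1.48/0.52."""
    d1 = np.array([2, 2, 2, 1, 1, 1, 1, 1, 1, 0])   # p = 0.6 over 10 animals
    d2 = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 2])   # p = 0.4
    gm = _gm(np.concatenate([d1, d2])[:, None])
    groups = pd.Series(["a"] * 10 + ["b"] * 10, index=gm.animal_ids)
    gst, gp = pairwise_fst(gm, groups)
    assert gst.loc["a", "b"] == pytest.approx(0.04, abs=1e-12)
    assert gp.loc["a", "b"] == pytest.approx(0.04 * 1.48 / 0.52, abs=1e-12)


def test_fst_label_permutation_collapses_to_null(small_bundle):
    gm = make_panel(small_bundle.genotypes, "array")
    ped = small_bundle.pedigree
    groups = pd.Series(ped["country"].to_numpy(), index=ped["animal_id"].to_numpy())
    gst, _ = pairwise_fst(gm, groups)
    rng = np.random.default_rng(1)
    shuffled = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
    gst_null, _ = pairwise_fst(gm, shuffled)
    real = gst.to_numpy()[np.triu_indices(len(gst), 1)].mean()
    null = gst_null.to_numpy()[np.triu_indices(len(gst), 1)].mean()
    assert null < real / 2


def test_nj_recovers_additive_four_taxon_tree():
    # tree: ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths below
    dm = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    tree = TreeNode.read(io.StringIO(nj_tree(dm, ["A", "B", "C", "D"])))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
    # recovered tree reproduces every pairwise distance
    for a, b, d in [("A", "B", 3), ("A", "C", 5), ("A", "D", 6),
                    ("B", "C", 6), ("B", "D", 7), ("C", "D", 7)]:
        assert tree.find(a).distance(tree.find(b)) == pytest.approx(d)


def test_nj_matches_scikit_bio_on_random_distances():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 3))
    dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = list("ABCDEF")
    ours = TreeNode.read(io.StringIO(nj_tree(dm, labels)))
    ref = skbio_nj(DistanceMatrix(dm, labels))
    assert ours.compare_rfd(ref) == 0.0


def test_nj_three_taxa_star_resolution():
    dm = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
    tree = TreeNode.read(io.StringIO(nj_tree(dm, ["x", "y", "z"])))
    assert {t.name: t.length for t in tree.tips()} == pytest.approx(
        {"x": 1.0, "y": 1.0, "z": 1.0})


def test_nj_label_permutation_invariance():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(5, 2))
    dm = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = list("ABCDE")
    t1 = TreeNode.read(io.StringIO(nj_tree(dm, labels)))
    perm = [3, 1, 4, 0, 2]
    t2 = TreeNode.read(io.StringIO(
        nj_tree(dm[np.ix_(perm, perm)], [labels[i] for i in perm])))
    assert t1.compare_rfd(t2) == 0.0


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])


def test_heterozygosity_hwe_population_agreement():
    gm = hwe_genotypes(500, 5000, seed=21)
    g = build_grm_yang(gm, maf_min=0.0)
    groups = pd.Series(["pop"] * 500, index=gm.animal_ids)
    rep = heterozygosity_report(gm, g, groups).iloc[0]
    assert abs(rep["HE_o"] - rep["HE_oHW"]) < 0.01
    assert abs(rep["HE_o"] - rep["HE_pr"]) < 0.01


def test_heterozygosity_all_homozygous_group():
    d = np.array([[2, 0, 2], [0, 2, 0], [1, 1, 1]])
    gm = _gm(d)
    g = GRM(np.eye(3), gm.animal_ids, 3)
    groups = pd.Series(["hom", "hom", "het"], index=gm.animal_ids)
    rep = heterozygosity_report(gm, g, groups).set_index("group")
    assert rep.loc["hom", "HE_o"] == 0.0
    assert rep.loc["het", "HE_o"] == 1.0


def test_heterozygosity_default_bundle_band(small_bundle):
    """Common-variant panel heterozygosities sit in the breed-typical band."""
    gm = make_panel(small_bundle.genotypes, "array")
    g = build_grm_yang(gm, "auto")
    ped = small_bundle.pedigree
    groups = pd.Series(ped["country"].to_numpy(), index=ped["animal_id"].to_numpy())
    rep = heterozygosity_report(gm, g, groups)
    for col in ("HE_o", "HE_oHW", "HE_pr"):
        assert rep[col].between(0.30, 0.36).all(), rep
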