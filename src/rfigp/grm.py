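"""Genomic relationship matrices and population-structure diagnostics.

The GRM follows Yang et al.'s estimator: off-diagonals average per-variant
standardised cross-products, while diagonals use the dedicated estimator
``1 + mean_i (x^2 - (1+2p)x + 2p^2) / (2p(1-p))`` whose expectation is
1 + F under inbreeding.  Allele frequencies come from the analysed sample,
missing dosages are mean-imputed (2p) at GRM time only.

Structure diagnostics: PCA of the (centred) GRM, pairwise multi-locus
G_ST with Hedrick's standardised G'_ST, a Saitou–Nei neighbour-joining tree
of the between-group distances, and observed/HWE/GRM-predicted
heterozygosities per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GRM, MISSING, GenotypeMatrix


@dataclass
class PopStructure:
    pc_scores: np.ndarray          # animals x k
    eigenvalues: np.ndarray        # length k, non-increasing
    animal_ids: list[str]


def effective_maf_threshold(n_animals: int) -> float:
    """MAF floor ensuring >= 20 segregating allele copies, clamped to [0.01, 0.05]."""
    if n_animals < 10:
        raise ValueError("need at least 10 animals")
    return float(min(max(10.0 / n_animals, 0.01), 0.05))


def build_grm_yang(gm: GenotypeMatrix, maf_min: float | str | None = "auto",
                   diagonal: str = "yang") -> GRM:
    """Yang-method GRM from the variants passing the MAF threshold.

    ``diagonal="yang"`` (default) uses Yang's dedicated diagonal estimator;
    ``diagonal="crossproduct"`` keeps the plain standardised cross-product on
    the diagonal, which makes GBLUP exactly dual to ridge SNP-BLUP.
    """
    if maf_min == "auto" or maf_min is None:
        maf_min = effective_maf_threshold(gm.n_animals)
    d = gm.dosages.astype(np.float64)
    miss = gm.dosages == MISSING
    d[miss] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = np.isfinite(maf) & (maf >= maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError(f"no polymorphic variant passes maf >= {maf_min}")
    d = d[:, keep]
    p = p[keep]
    het = 2.0 * p * (1.0 - p)
    n_used = int(keep.sum())

    centred = d - 2.0 * p
    centred[np.isnan(centred)] = 0.0          # mean imputation
    w = centred / np.sqrt(het)
    g = (w @ w.T) / n_used

    if diagonal == "yang":
        # Yang's diagonal estimator, per-animal over its non-missing variants
        num = d * d - (1.0 + 2.0 * p) * d + 2.0 * p * p
        ratio = num / het
        diag = 1.0 + np.nanmean(ratio, axis=1)
        np.fill_diagonal(g, diag)
    elif diagonal != "crossproduct":
        raise ValueError("diagonal must be 'yang' or 'crossproduct'")
    return GRM(g, list(gm.animal_ids), n_used, float(maf_min))


def combine_weighted_grm(grm_snp: GRM, grm_seq: GRM,
                         var_snp: float, var_seq: float) -> GRM:
    """Variance-weighted aggregate (v1*G1 + v2*G2)/(v1 + v2)."""
    if grm_snp.animal_ids != grm_seq.animal_ids:
        raise ValueError("GRMs cover different animal sets or orders")
    if var_snp < 0 or var_seq < 0:
        raise ValueError("variance weights must be non-negative")
    total = var_snp + var_seq
    if total == 0:
        raise ValueError("both variance weights are zero")
    mat = (var_snp * grm_snp.matrix + var_seq * grm_seq.matrix) / total
    return GRM(mat, list(grm_snp.animal_ids),
               grm_snp.n_variants_used + grm_seq.n_variants_used,
               min(grm_snp.maf_threshold, grm_seq.maf_threshold))


def grm_pca(grm: GRM, k: int, center: bool = True) -> PopStructure:
    """Top-k eigenpairs of the (optionally double-centred) GRM.

    Scores are eigenvector * sqrt(eigenvalue); eigenvalues are returned in
    non-increasing order.
    """
    n = grm.n_animals
    if k > n:
        raise ValueError(f"k={k} exceeds {n} animals")
    mat = grm.matrix
    if center:
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        mat = j @ mat @ j
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return PopStructure(scores, vals, list(grm.animal_ids))


def _group_freqs(gm: GenotypeMatrix, members: np.ndarray) -> np.ndarray:
    d = gm.dosages[members].astype(float)
    d[d == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0


def pairwise_fst(gm: GenotypeMatrix, groups: pd.Series | dict,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise multi-locus G_ST and Hedrick's G'_ST between groups.

    Per pair of groups: H_S = mean of within-group expected heterozygosities,
    H_T = 2*p_bar*(1-p_bar) from the mean frequency; multi-locus estimates use
    the ratio of sums, G_ST = sum(H_T - H_S)/sum(H_T); Hedrick's
    G'_ST = G_ST*(k-1+H_S)/((k-1)*(1-H_S)) with k = 2 and H_S, H_T the
    per-variant means over retained (polymorphic-in-pair) variants.
    """
    groups = pd.Series(groups) if isinstance(groups, dict) else groups
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ids = pd.Series(gm.animal_ids)
    freqs = {}
    for lab in labels:
        members = ids.isin(groups.index[groups == lab]).to_numpy()
        if members.sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 animals")
        freqs[lab] = _group_freqs(gm, members)
    gst = pd.DataFrame(0.0, index=labels, columns=labels)
    gprime = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            p1, p2 = freqs[a], freqs[b]
            hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
            pbar = (p1 + p2) / 2.0
            ht = 2 * pbar * (1 - pbar)
            keep = np.isfinite(hs) & np.isfinite(ht) & (ht > 0)
            if not keep.any():
                raise ValueError(f"groups {a!r}/{b!r} are monomorphic at every variant")
            hs_m = hs[keep].mean()
            ht_m = ht[keep].mean()
            g = (ht_m - hs_m) / ht_m      # ratio of averages
            denom = 1.0 - hs_m
            gp = g * (1.0 + hs_m) / denom if denom > 0 else 1.0
            gst.loc[a, b] = gst.loc[b, a] = g
            gprime.loc[a, b] = gprime.loc[b, a] = min(gp, 1.0)
    return gst, gprime


def nj_tree(distance_matrix: np.ndarray | pd.DataFrame,
            labels: list[str] | None = None) -> str:
    """Saitou–Nei neighbour-joining; unrooted tree as a newick string.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch, preserving the pairwise path length.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index) if labels is None else labels
        dm = distance_matrix.to_numpy(dtype=float)
    else:
        dm = np.asarray(distance_matrix, dtype=float)
    n = dm.shape[0]
    if labels is None:
        labels = [f"g{i}" for i in range(n)]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0) or np.any(dm < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")

    d = dm.copy()
    nodes = [f"{lab}" for lab in labels]        # newick fragments
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = d[a, b]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        new = d.shape[0]
        row = 0.5 * (d[a, :] + d[b, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new, : new] = row[: new]
        d[: new, new] = row[: new]
        nodes.append(f"({nodes[a]}:{li:.10g},{nodes[b]}:{lj:.10g})")
        active = [x for x in active if x not in (a, b)] + [new]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    branches = [la, lb, lc]
    for i in range(3):
        if branches[i] < 0:
            for j in range(3):
                if j != i:
                    branches[j] += branches[i] / 2.0
            branches[i] = 0.0
    la, lb, lc = branches
    return (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});")


def heterozygosity_report(gm: GenotypeMatrix, grm: GRM,
                          groups: pd.Series | dict) -> pd.DataFrame:
    """Observed, HWE-expected, and GRM-predicted heterozygosity per group.

    HE_o  : mean per-animal fraction of heterozygous calls within the group.
    HE_oHW: mean over variants of 2*p_g*(1-p_g) with within-group frequencies.
    HE_pr : HE_base*(1-F) with HE_base from pooled frequencies and
            F = mean(G_jj) - 1 over the group's GRM diagonal.
    """
    groups = pd.Series(groups) if isinstance(groups, dict) else groups
    ids = pd.Series(gm.animal_ids)
    p_all = gm.allele_freq()
    ok = np.isfinite(p_all)
    he_base = float(np.mean(2 * p_all[ok] * (1 - p_all[ok])))
    diag = np.diag(grm.matrix)
    grm_pos = {a: i for i, a in enumerate(grm.animal_ids)}
    rows = []
    for lab in sorted(groups.unique()):
        members = ids.isin(groups.index[groups == lab]).to_numpy()
        if not members.any():
            raise ValueError(f"group {lab!r} is empty")
        d = gm.dosages[members]
        valid = d != MISSING
        he_o = float(((d == 1).sum(axis=1) / valid.sum(axis=1)).mean())
        p_g = _group_freqs(gm, members)
        okg = np.isfinite(p_g)
        he_ohw = float(np.mean(2 * p_g[okg] * (1 - p_g[okg])))
        gidx = [grm_pos[a] for a in ids[members] if a in grm_pos]
        if not gidx:
            raise ValueError(f"group {lab!r} has no animals in the GRM")
        f = float(diag[gidx].mean() - 1.0)
        rows.append({"group": lab, "n": int(members.sum()), "HE_o": he_o,
                     "HE_oHW": he_ohw, "HE_pr": he_base * (1 - f), "F": f})
    return pd.DataFrame(rows)
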