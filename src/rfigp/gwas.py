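"""Mixed-linear-model association scans and the multi-trait meta statistic.

The per-variant model is y = 1*mu + X b + s_i alpha_i + g + e with
g ~ N(0, G sigma_g^2); the scan uses the standard two-stage approximation:
null variance components are estimated once by REML, the phenotype and
covariates are whitened through the eigendecomposition of G, and each
variant's effect is then a generalised-least-squares regression at fixed
variance ratio.  Wald p-values use a t reference with n - rank(X) - 1
degrees of freedom.

The multi-trait meta statistic for variant i is chi2_i = t_i' V^-1 t_i,
where t_i stacks the trait-wise signed t-values and V is the correlation
matrix of the signed-t vectors estimated over ALL scanned variants; under
the null chi2 ~ chi-squared with df = number of traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GRM, MISSING, GenotypeMatrix
from .mixedmodel import TraitData, VarianceComponents, fit_greml


@dataclass
class NullModel:
    """Null-model REML fit plus the spectral cache for O(n) per-variant solves."""

    vc: VarianceComponents
    animal_ids: list[str]
    eigvals: np.ndarray          # eigenvalues of the GRM submatrix
    eigvecs: np.ndarray
    y_rot: np.ndarray            # U' y
    x_rot: np.ndarray            # U' X
    scale: np.ndarray            # 1/sqrt(sg2 * d + se2)

    @property
    def sigma_g2(self) -> float:
        return float(self.vc.P[0, 0])

    @property
    def sigma_e2(self) -> float:
        return float(self.vc.R[0, 0])


def fit_null_model(y: np.ndarray, x: np.ndarray, grm: GRM,
                   animal_ids: list[str], name: str = "trait") -> NullModel:
    """Univariate REML of y = Xb + g + e, with the whitening cache."""
    td = TraitData(name, list(animal_ids), y, x)
    vc = fit_greml(td, grm)
    idx = grm.align(animal_ids)
    gsub = grm.matrix[np.ix_(idx, idx)]
    d, u = np.linalg.eigh(gsub)
    d = np.clip(d, 0.0, None)
    scale = 1.0 / np.sqrt(vc.P[0, 0] * d + vc.R[0, 0])
    return NullModel(vc, list(animal_ids), d, u, u.T @ np.asarray(y, float),
                     u.T @ np.atleast_2d(np.asarray(x, float)), scale)


def mlm_scan(gm: GenotypeMatrix, null: NullModel, *, min_maf: float = 0.01,
             chunk: int = 2048) -> pd.DataFrame:
    """Per-variant GLS effect, SE, signed t and Wald p at fixed null components.

    Variants below ``min_maf`` in the analysed animals are excluded; variants
    with no genotypic variance left after whitening are reported with a
    ``skip`` reason code and NaN statistics.
    """
    sub = gm.subset(animals=null.animal_ids)
    n = sub.n_animals
    maf = sub.maf()
    keep = np.flatnonzero(np.isfinite(maf) & (maf > min_maf))

    yt = null.scale * null.y_rot
    xt = null.scale[:, None] * null.x_rot
    q, _ = np.linalg.qr(xt)
    yr = yt - q @ (q.T @ yt)
    rank_x = xt.shape[1]
    df = n - rank_x - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom for the scan")

    m = keep.size
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    reason = np.array([""] * m, dtype=object)
    for start in range(0, m, chunk):
        cols = keep[start:start + chunk]
        s = sub.dosages[:, cols].astype(float)
        miss = sub.dosages[:, cols] == MISSING
        if miss.any():
            mu = np.where(miss, np.nan, s)
            s = np.where(miss, np.nanmean(mu, axis=0), s)
        st = null.scale[:, None] * (null.eigvecs.T @ s)
        sr = st - q @ (q.T @ st)
        ss = np.einsum("ij,ij->j", sr, sr)
        ok = ss > 1e-12
        sy = sr.T @ yr
        b = np.where(ok, sy / np.where(ok, ss, 1.0), np.nan)
        rss = (yr @ yr) - b * sy
        sigma2 = np.where(ok, rss / df, np.nan)
        beta[start:start + cols.size] = b
        se[start:start + cols.size] = np.sqrt(np.where(ok, sigma2 / np.where(ok, ss, 1.0),
                                                       np.nan))
        reason[start:start + cols.size] = np.where(ok, "", "zero_variance_after_whitening")
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = sub.variants.iloc[keep][["id", "chrom", "pos"]].copy()
    out["maf"] = maf[keep]
    out["n"] = n
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["skip"] = reason
    return out.reset_index(drop=True)


def meta_multitrait(scans: list[pd.DataFrame] | np.ndarray,
                    ridge: float = 1e-6) -> pd.DataFrame:
    """Multi-trait chi-squared from trait-wise signed-t vectors.

    Accepts either aligned scan tables (joined on variant ``id``) or a raw
    variants x traits matrix of signed t-values.  V is the Pearson
    correlation of the t-vectors over all variants; near-singular V gets a
    ridge on the diagonal with a warning.
    """
    if isinstance(scans, np.ndarray):
        tmat = scans
        meta = pd.DataFrame({"id": np.arange(tmat.shape[0]).astype(str)})
    else:
        if len(scans) < 2:
            raise ValueError("meta analysis needs >= 2 trait scans")
        base = scans[0][["id", "chrom", "pos", "t"]].rename(columns={"t": "t0"})
        for k, s in enumerate(scans[1:], start=1):
            base = base.merge(s[["id", "t"]].rename(columns={"t": f"t{k}"}),
                              on="id", how="inner")
        meta = base
        tmat = base[[f"t{k}" for k in range(len(scans))]].to_numpy(float)
    finite = np.all(np.isfinite(tmat), axis=1)
    v = np.corrcoef(tmat[finite], rowvar=False)
    v = np.atleast_2d(v)
    t_dim = tmat.shape[1]
    if np.any(np.abs(v[~np.eye(t_dim, dtype=bool)]) >= 0.999) or \
            np.linalg.eigvalsh(v).min() < 1e-8:
        warnings.warn("signed-t vectors nearly collinear; adding ridge to V")
        v = v + ridge * np.eye(t_dim)
    vinv = np.linalg.inv(v)
    chi2 = np.einsum("ij,jk,ik->i", tmat, vinv, tmat)
    chi2 = np.where(finite, chi2, np.nan)
    out = meta.copy()
    out["chi2"] = chi2
    out["df"] = t_dim
    out["p_meta"] = stats.chi2.sf(chi2, df=t_dim)
    out.attrs["V"] = v
    return out
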