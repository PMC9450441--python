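"""Uni/bi/tri-variate GREML variance components and GBLUP prediction.

Model: for trait t, y_t = X_t b_t + Z_t g_t + e_t with the stacked genetic
values distributed N(0, G (kron) P) over genotyped animals (G the genomic
relationship matrix, P the T x T additive (co)variance matrix) and residuals
N(0, R (kron) I) where cross-trait residual covariances exist only for
animals measured for both traits (and are estimated only when enough such
animals exist to identify them).

Estimation is restricted maximum likelihood.  The multivariate fitter uses
average-information (AI) updates with Levenberg-Marquardt damping and
step-halving under a monotone-likelihood guard; standard errors come from
the inverse AI matrix at the optimum.  Univariate fits use the exact
spectral (eigendecomposition) profile likelihood, which is fast and global
in the variance ratio, with the same AI-based standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genio import GRM

VAR_FLOOR_FRAC = 1e-8     # variance floor, as a fraction of phenotypic variance
MAX_CORR = 0.999


@dataclass
class TraitData:
    """Records for one trait: aligned animal ids, phenotypes, fixed-effect design."""

    name: str
    animal_ids: list[str]
    y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size or len(self.animal_ids) != self.y.size:
            raise ValueError(f"trait {self.name!r}: inconsistent record counts")


def trait_data_from_frame(df: pd.DataFrame, name: str, value_col: str = "RFI",
                          fixed_cols: tuple[str, ...] = ()) -> TraitData:
    """Build TraitData with an intercept plus dummy-coded fixed-effect columns."""
    cols = [np.ones(len(df))]
    for c in fixed_cols:
        levels = df[c].astype(str)
        if levels.nunique() > 1:
            cols.append(pd.get_dummies(levels, drop_first=True).to_numpy(float))
    return TraitData(name, list(df["animal_id"]), df[value_col].to_numpy(float),
                     np.column_stack(cols))


@dataclass
class VarianceComponents:
    P: np.ndarray
    R: np.ndarray
    se_P: np.ndarray
    se_R: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    trait_names: list[str]
    param_names: list[tuple[str, int, int]] = field(default_factory=list)
    param_cov: np.ndarray | None = None
    unidentifiable: bool = False
    logl_path: list[float] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return self.P.shape[0]

    def _param_index(self, kind: str, t: int, u: int) -> int | None:
        key = (kind, min(t, u), max(t, u))
        try:
            return self.param_names.index(key)
        except ValueError:
            return None


@dataclass
class GebvSet:
    """GEBV per genotyped animal per trait."""

    table: pd.DataFrame            # index animal_id, one column per trait

    def trait(self, name: str) -> pd.Series:
        return self.table[name]


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

class _Workspace:
    """Index bookkeeping and V/K assembly for a multi-trait REML problem."""

    def __init__(self, traits: list[TraitData], grm: GRM, overlap_min: int):
        self.traits = traits
        self.T = len(traits)
        self.G = grm.matrix
        self.idx = [grm.align(t.animal_ids) for t in traits]
        self.offsets = np.cumsum([0] + [t.y.size for t in traits])
        self.n = int(self.offsets[-1])
        self.y = np.concatenate([t.y for t in traits])
        self.X = linalg.block_diag(*[t.X for t in traits])
        self.gblock = {}
        for t in range(self.T):
            for u in range(t, self.T):
                self.gblock[(t, u)] = self.G[np.ix_(self.idx[t], self.idx[u])]
        # residual-covariance support: records of the same animal in two traits
        self.overlap: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for t in range(self.T):
            pos_t = {a: i for i, a in enumerate(traits[t].animal_ids)}
            for u in range(t + 1, self.T):
                shared = [(pos_t[a], j) for j, a in enumerate(traits[u].animal_ids)
                          if a in pos_t]
                if len(shared) >= overlap_min:
                    it, iu = map(np.array, zip(*shared))
                    self.overlap[(t, u)] = (it, iu)
        self.params: list[tuple[str, int, int]] = []
        for t in range(self.T):
            for u in range(t, self.T):
                self.params.append(("G", t, u))
        for t in range(self.T):
            self.params.append(("R", t, t))
        for (t, u) in self.overlap:
            self.params.append(("R", t, u))
        self.vpheno = np.array([t.y.var(ddof=1) for t in traits])

    # -- parameter vector <-> matrices ------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        P = np.zeros((self.T, self.T))
        R = np.zeros((self.T, self.T))
        for val, (kind, t, u) in zip(theta, self.params):
            m = P if kind == "G" else R
            m[t, u] = m[u, t] = val
        return P, R

    def pack(self, P: np.ndarray, R: np.ndarray) -> np.ndarray:
        return np.array([(P if k == "G" else R)[t, u] for k, t, u in self.params])

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Pull a proposal back into the admissible parameter space."""
        P, R = self.unpack(theta)
        for t in range(self.T):
            floor = VAR_FLOOR_FRAC * self.vpheno[t]
            P[t, t] = max(P[t, t], floor)
            R[t, t] = max(R[t, t], floor)
        for t in range(self.T):
            for u in range(t + 1, self.T):
                cap = MAX_CORR * np.sqrt(P[t, t] * P[u, u])
                P[t, u] = P[u, t] = np.clip(P[t, u], -cap, cap)
                if (t, u) in self.overlap:
                    rcap = MAX_CORR * np.sqrt(R[t, t] * R[u, u])
                    R[t, u] = R[u, t] = np.clip(R[t, u], -rcap, rcap)
        return self.pack(P, R)

    # -- V assembly and derivative application -----------------------------
    def build_v(self, theta: np.ndarray) -> np.ndarray:
        P, R = self.unpack(theta)
        v = np.zeros((self.n, self.n))
        o = self.offsets
        for t in range(self.T):
            for u in range(t, self.T):
                block = P[t, u] * self.gblock[(t, u)]
                v[o[t]:o[t + 1], o[u]:o[u + 1]] += block
                if t != u:
                    v[o[u]:o[u + 1], o[t]:o[t + 1]] += block.T
        for t in range(self.T):
            sl = slice(o[t], o[t + 1])
            v[sl, sl][np.diag_indices(o[t + 1] - o[t])] += R[t, t]
        for (t, u), (it, iu) in self.overlap.items():
            v[o[t] + it, o[u] + iu] += R[t, u]
            v[o[u] + iu, o[t] + it] += R[t, u]
        return v

    def apply_k(self, kind: str, t: int, u: int, vec: np.ndarray) -> np.ndarray:
        """K @ vec for the derivative matrix of parameter (kind, t, u)."""
        o = self.offsets
        out = np.zeros_like(vec)
        if kind == "G":
            block = self.gblock[(t, u)]
            out[o[t]:o[t + 1]] += block @ vec[o[u]:o[u + 1]]
            if t != u:
                out[o[u]:o[u + 1]] += block.T @ vec[o[t]:o[t + 1]]
        elif t == u:
            out[o[t]:o[t + 1]] = vec[o[t]:o[t + 1]]
        else:
            it, iu = self.overlap[(t, u)]
            out[o[t] + it] += vec[o[u] + iu]
            out[o[u] + iu] += vec[o[t] + it]
        return out

    def trace_pk(self, pmat: np.ndarray, kind: str, t: int, u: int) -> float:
        o = self.offsets
        if kind == "G":
            pb = pmat[o[t]:o[t + 1], o[u]:o[u + 1]]
            tr = float(np.sum(pb * self.gblock[(t, u)]))
            return 2.0 * tr if t != u else tr
        if t == u:
            return float(np.trace(pmat[o[t]:o[t + 1], o[t]:o[t + 1]]))
        it, iu = self.overlap[(t, u)]
        return 2.0 * float(pmat[o[t] + it, o[u] + iu].sum())

    # -- likelihood and derivatives ----------------------------------------
    def loglik(self, theta: np.ndarray) -> float:
        v = self.build_v(theta)
        try:
            c, low = linalg.cho_factor(v, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vi_x = linalg.cho_solve((c, low), self.X, check_finite=False)
        vi_y = linalg.cho_solve((c, low), self.y, check_finite=False)
        xtvix = self.X.T @ vi_x
        try:
            cx = linalg.cho_factor(xtvix, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        beta = linalg.cho_solve(cx, self.X.T @ vi_y, check_finite=False)
        ypy = float(self.y @ vi_y - (self.X.T @ vi_y) @ beta)
        return -0.5 * (logdet_v + logdet_x + ypy)

    def derivatives(self, theta: np.ndarray):
        """logL, score vector, AI matrix, and P@y at theta (dense algebra)."""
        v = self.build_v(theta)
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vi, info = linalg.lapack.dpotri(c, lower=True)
        if info != 0:
            raise linalg.LinAlgError("dpotri failed")
        vi = np.tril(vi) + np.tril(vi, -1).T
        w = vi @ self.X
        xtvix = self.X.T @ w
        cx = linalg.cho_factor(xtvix, check_finite=False)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        cinv = linalg.cho_solve(cx, np.eye(self.X.shape[1]), check_finite=False)
        pmat = vi - w @ cinv @ w.T
        py = pmat @ self.y
        logl = -0.5 * (logdet_v + logdet_x + float(self.y @ py))
        k = len(self.params)
        score = np.empty(k)
        kpy = np.empty((k, self.n))
        for i, (kind, t, u) in enumerate(self.params):
            kpy[i] = self.apply_k(kind, t, u, py)
            score[i] = -0.5 * (self.trace_pk(pmat, kind, t, u) - float(py @ kpy[i]))
        pkpy = pmat @ kpy.T
        ai = 0.5 * (kpy @ pkpy)
        ai = (ai + ai.T) / 2.0
        return logl, score, ai, py, pmat


def _pinned_params(ws: _Workspace, theta: np.ndarray,
                   score: np.ndarray) -> np.ndarray:
    """Parameters sitting on a bound whose gradient points outside it."""
    P, R = ws.unpack(theta)
    pinned = np.zeros(len(theta), dtype=bool)
    for i, (kind, t, u) in enumerate(ws.params):
        if t == u:
            floor = VAR_FLOOR_FRAC * ws.vpheno[t]
            val = P[t, t] if kind == "G" else R[t, t]
            if val <= floor * (1.0 + 1e-6) and score[i] < 0:
                pinned[i] = True
        else:
            mat = P if kind == "G" else R
            cap = MAX_CORR * np.sqrt(mat[t, t] * mat[u, u])
            if cap > 0 and abs(mat[t, u]) >= cap * (1.0 - 1e-9) \
                    and np.sign(score[i]) == np.sign(mat[t, u]):
                pinned[i] = True
    if pinned.all():
        pinned[:] = False  # degenerate: keep at least one free coordinate
    return pinned


def _start_values(ws: _Workspace) -> np.ndarray:
    P = np.zeros((ws.T, ws.T))
    R = np.zeros((ws.T, ws.T))
    for t in range(ws.T):
        P[t, t] = 0.5 * ws.vpheno[t]
        R[t, t] = 0.5 * ws.vpheno[t]
    for t in range(ws.T):
        for u in range(t + 1, ws.T):
            if (t, u) in ws.overlap:
                it, iu = ws.overlap[(t, u)]
                r_ph = np.corrcoef(ws.traits[t].y[it], ws.traits[u].y[iu])[0, 1]
                r0 = 0.5 * (r_ph if np.isfinite(r_ph) else 0.5)
            else:
                r0 = 0.25
            P[t, u] = P[u, t] = r0 * np.sqrt(P[t, t] * P[u, u])
    return ws.pack(P, R)


def fit_greml(traits: list[TraitData] | TraitData, grm: GRM, *,
              max_iter: int = 60, tol_logl: float = 1e-8, tol_param: float = 1e-6,
              overlap_min: int = 30, verbose: bool = False) -> VarianceComponents:
    """REML variance components for 1-3 traits sharing one GRM.

    Residual covariance between two traits is a free parameter only when at
    least ``overlap_min`` animals carry records for both; otherwise it is
    structurally fixed at zero (disjoint cohorts leave it unidentifiable).
    """
    if isinstance(traits, TraitData):
        traits = [traits]
    if not 1 <= len(traits) <= 3:
        raise ValueError("fit_greml supports 1 to 3 traits")
    if len(traits) == 1:
        return _fit_univariate(traits[0], grm, tol_logl=tol_logl)

    ws = _Workspace(traits, grm, overlap_min)
    theta = ws.project(_start_values(ws))
    converged = False
    n_iter = 0
    damp = 0.0
    scales = np.array([np.sqrt(ws.vpheno[t] * ws.vpheno[u])
                       for _, t, u in ws.params])
    state = ws.derivatives(theta)          # (logl, score, ai, py, pmat)
    logl_path = [float(state[0])]
    for n_iter in range(1, max_iter + 1):
        logl, score, ai = state[0], state[1], state[2]
        # active set: parameters pinned at a bound with the score pointing
        # outward are frozen, so the Newton step in the free coordinates
        # keeps its quadratic convergence instead of crawling along the bound
        pinned = _pinned_params(ws, theta, score)
        free = ~pinned
        accepted = None                    # (theta, state or None)
        trial_damp = damp
        tol_accept = 1e-9 * max(1.0, abs(logl))  # numerical noise floor
        for _ in range(8):
            step = np.zeros_like(theta)
            try:
                ai_f = ai[np.ix_(free, free)]
                step[free] = linalg.solve(
                    ai_f + trial_damp * np.diag(np.diag(ai_f)) +
                    1e-12 * np.eye(int(free.sum())), score[free], assume_a="sym")
            except linalg.LinAlgError:
                trial_damp = max(4.0 * trial_damp, 1e-4)
                continue
            # full step: evaluate complete derivatives (reused next iteration)
            cand = ws.project(theta + step)
            try:
                cand_state = ws.derivatives(cand)
            except linalg.LinAlgError:
                cand_state = None
            if cand_state is not None and np.isfinite(cand_state[0]) \
                    and cand_state[0] >= logl - tol_accept:
                accepted = (cand, cand_state)
                break
            # halved steps: cheap likelihood-only search
            alpha = 0.5
            exhausted = True
            for _ in range(10):
                cand = ws.project(theta + alpha * step)
                cand_logl = ws.loglik(cand)
                if np.isfinite(cand_logl) and cand_logl >= logl - tol_accept:
                    accepted = (cand, None)
                    exhausted = False
                    break
                alpha *= 0.5
            if accepted:
                break
            if exhausted and np.isfinite(cand_logl):
                # even a ~1e-3-scale step cannot improve the likelihood:
                # we are at a numerical optimum, more damping cannot help
                break
            trial_damp = max(4.0 * trial_damp, 1e-4)
        damp = trial_damp / 4.0 if trial_damp > 0 else 0.0
        if not accepted:
            # no step improves the likelihood beyond numerical noise: accept
            # the current point as a (possibly boundary) optimum
            converged = True
            break
        new_theta, new_state = accepted
        if new_state is None:
            new_state = ws.derivatives(new_theta)
        rel = np.max(np.abs(new_theta - theta) / scales)
        dll = new_state[0] - logl
        theta, state = new_theta, new_state
        logl_path.append(float(state[0]))
        if verbose:
            print(f"iter {n_iter}: logL={state[0]:.6f} dll={dll:.2e} rel={rel:.2e}")
        if abs(dll) < tol_logl and rel < tol_param:
            converged = True
            break

    logl, score, ai = state[0], state[1], state[2]
    try:
        param_cov = linalg.inv(ai)
    except linalg.LinAlgError:
        param_cov = np.full((len(theta), len(theta)), np.nan)
    P, R = ws.unpack(theta)
    se = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))
    se_P = np.zeros_like(P)
    se_R = np.zeros_like(R)
    for s, (kind, t, u) in zip(se, ws.params):
        m = se_P if kind == "G" else se_R
        m[t, u] = m[u, t] = s
    return VarianceComponents(P, R, se_P, se_R, logl, n_iter, converged,
                              [t.name for t in traits], list(ws.params), param_cov,
                              logl_path=logl_path)


# ---------------------------------------------------------------------------
# univariate spectral path
# ---------------------------------------------------------------------------

def _fit_univariate(td: TraitData, grm: GRM, tol_logl: float = 1e-8,
                    ) -> VarianceComponents:
    idx = grm.align(td.animal_ids)
    gsub = grm.matrix[np.ix_(idx, idx)]
    n = td.y.size
    p = np.linalg.matrix_rank(td.X)
    d, u_eig = np.linalg.eigh(gsub)
    d = np.clip(d, 0.0, None)
    yt = u_eig.T @ td.y
    xt = u_eig.T @ td.X

    unidentifiable = bool(np.ptp(d) < 1e-10)

    def neg_restricted(h: float) -> float:
        dv = h * d + (1.0 - h)
        if np.any(dv <= 0):
            return np.inf
        wi = 1.0 / dv
        xtw = xt * wi[:, None]
        xtwx = xt.T @ xtw
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtwx, xtw.T @ yt)
        resid = yt - xt @ beta
        rss = float(resid @ (wi * resid))
        sigma2 = rss / (n - p)
        logl = -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(dv))
                       + logdet_x + (n - p))
        return -logl

    if unidentifiable:
        h_opt = 0.5
    else:
        res = optimize.minimize_scalar(neg_restricted, bounds=(1e-6, 1 - 1e-6),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        h_opt = float(res.x)
    dv = h_opt * d + (1.0 - h_opt)
    wi = 1.0 / dv
    xtw = xt * wi[:, None]
    xtwx = xt.T @ xtw
    beta = np.linalg.solve(xtwx, xtw.T @ yt)
    resid = yt - xt @ beta
    sigma2 = float(resid @ (wi * resid)) / (n - p)
    sg2, se2 = h_opt * sigma2, (1.0 - h_opt) * sigma2
    logl = -neg_restricted(h_opt)

    # AI matrix at the optimum (V diagonal in the rotated basis)
    vi = wi / sigma2
    w = xt * vi[:, None]
    cinv = np.linalg.inv(xt.T @ w)
    pmat = np.diag(vi) - w @ cinv @ w.T
    py = pmat @ yt
    kg_py = d * py
    ke_py = py
    p_kg_py = pmat @ kg_py
    p_ke_py = pmat @ ke_py
    ai = 0.5 * np.array([[kg_py @ p_kg_py, kg_py @ p_ke_py],
                         [kg_py @ p_ke_py, ke_py @ p_ke_py]])
    try:
        param_cov = np.linalg.inv(ai)
        se = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))
    except np.linalg.LinAlgError:
        param_cov = np.full((2, 2), np.nan)
        se = np.array([np.nan, np.nan])
    if unidentifiable:
        param_cov = np.full((2, 2), np.nan)
        se = np.array([np.nan, np.nan])
    return VarianceComponents(
        np.array([[sg2]]), np.array([[se2]]),
        np.array([[se[0]]]), np.array([[se[1]]]),
        float(logl), 1, True, [td.name],
        [("G", 0, 0), ("R", 0, 0)], param_cov, unidentifiable)


# ---------------------------------------------------------------------------
# derived parameters
# ---------------------------------------------------------------------------

def heritability(vc: VarianceComponents, trait: int = 0) -> tuple[float, float]:
    """h2 = P_tt/(P_tt + R_tt) with a first-order delta-method SE."""
    pg, pe = vc.P[trait, trait], vc.R[trait, trait]
    tot = pg + pe
    if tot <= 0:
        raise ValueError("zero phenotypic variance")
    h2 = pg / tot
    se = np.nan
    ig = vc._param_index("G", trait, trait)
    ie = vc._param_index("R", trait, trait)
    if vc.param_cov is not None and ig is not None and ie is not None:
        grad = np.zeros(len(vc.param_names))
        grad[ig] = pe / tot**2
        grad[ie] = -pg / tot**2
        var = float(grad @ vc.param_cov @ grad)
        se = np.sqrt(var) if var >= 0 else np.nan
    return float(h2), float(se)


def genetic_correlation(vc: VarianceComponents, t1: int = 0, t2: int = 1,
                        ) -> tuple[float, float]:
    """rg = P_12/sqrt(P_11 P_22) with a delta-method SE; NaN when undefined."""
    p11, p22, p12 = vc.P[t1, t1], vc.P[t2, t2], vc.P[t1, t2]
    if p11 <= 0 or p22 <= 0:
        warnings.warn("zero genetic variance: genetic correlation undefined")
        return np.nan, np.nan
    rg = p12 / np.sqrt(p11 * p22)
    se = np.nan
    i11 = vc._param_index("G", t1, t1)
    i22 = vc._param_index("G", t2, t2)
    i12 = vc._param_index("G", t1, t2)
    if vc.param_cov is not None and None not in (i11, i22, i12):
        grad = np.zeros(len(vc.param_names))
        grad[i12] = 1.0 / np.sqrt(p11 * p22)
        grad[i11] = -0.5 * rg / p11
        grad[i22] = -0.5 * rg / p22
        var = float(grad @ vc.param_cov @ grad)
        se = np.sqrt(var) if var >= 0 else np.nan
    return float(rg), float(se)


# ---------------------------------------------------------------------------
# GBLUP prediction
# ---------------------------------------------------------------------------

def predict_gebv(traits: list[TraitData] | TraitData, grm: GRM,
                 vc: VarianceComponents, *, animals: list[str] | None = None,
                 allow_unconverged: bool = False) -> GebvSet:
    """Solve the mixed-model equations at fixed variance components.

    ``traits`` holds the *training* records only; GEBV are returned for all
    animals in the GRM (or the requested subset), including unphenotyped
    validation animals: g_hat = Cov(g, y) V^-1 (y - X b_hat).
    """
    if isinstance(traits, TraitData):
        traits = [traits]
    if not vc.converged and not allow_unconverged:
        raise RuntimeError("variance components did not converge; "
                           "pass allow_unconverged=True to predict anyway")
    ws = _Workspace(traits, grm, overlap_min=np.iinfo(np.int32).max)
    # rebuild overlap support from the fitted model so V matches the fit
    ws.overlap = {}
    for (kind, t, u) in vc.param_names:
        if kind == "R" and t != u:
            pos_t = {a: i for i, a in enumerate(traits[t].animal_ids)}
            shared = [(pos_t[a], j) for j, a in enumerate(traits[u].animal_ids)
                      if a in pos_t]
            if shared:
                it, iu = map(np.array, zip(*shared))
                ws.overlap[(t, u)] = (it, iu)
    theta = ws.pack(vc.P, vc.R)
    v = ws.build_v(theta)
    # a boundary fit (residual variance at its floor) with an indefinite or
    # rank-deficient kernel can leave V non-positive-definite; clip its
    # spectrum at a small positive floor in that case
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError:
        w_eig, u_eig = np.linalg.eigh(v)
        floor = 1e-8 * float(np.mean(np.diag(v)))
        v = (u_eig * np.clip(w_eig, floor, None)) @ u_eig.T
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    vi_y = linalg.cho_solve((c, low), ws.y, check_finite=False)
    vi_x = linalg.cho_solve((c, low), ws.X, check_finite=False)
    xtvix = ws.X.T @ vi_x
    beta = linalg.solve(xtvix, ws.X.T @ vi_y, assume_a="sym")
    py = linalg.cho_solve((c, low), ws.y - ws.X @ beta, check_finite=False)

    target_ids = list(grm.animal_ids) if animals is None else list(animals)
    rows = grm.align(target_ids)
    o = ws.offsets
    out = np.zeros((len(target_ids), ws.T))
    for t in range(ws.T):
        for u in range(ws.T):
            p_tu = vc.P[t, u]
            if p_tu == 0.0:
                continue
            gcols = grm.matrix[np.ix_(rows, ws.idx[u])]
            out[:, t] += p_tu * (gcols @ py[o[u]:o[u + 1]])
    table = pd.DataFrame(out, index=pd.Index(target_ids, name="animal_id"),
                         columns=[t.name for t in traits])
    return GebvSet(table)
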