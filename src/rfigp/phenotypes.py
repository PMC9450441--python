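"""Trait derivation: energy-corrected milk, body-weight change, and RFI.

Residual feed intake (RFI) is the residual of dry matter intake (DMI, kg/d)
after an ordinary-least-squares adjustment for production, body size, and
weight change.  Two model flavours are provided, mirroring how home-country
lactating cows and overseas cows are typically handled:

* lactating-cow model: mean + contemporary group + DIM + parity + ECM + MBW + dBW
* overseas-cow model:  mean + parity-stage + DIM + herd-year-season
                       + degree-2 orthogonal polynomial of age (+ trial)
                       + ECM + MBW + dBW

ECM (kg/d) = 0.1*milk + 5.2*fat + 2.6*protein, all in kg/d.  Per-animal RFI
is the mean residual over that animal's lactation records.  Datasets are
standardised ((x - mean)/SD, sample SD) before pooling across countries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RfiModelSpec:
    """Fixed factors, covariates and polynomial terms for the DMI adjustment."""

    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    polynomial_degrees: dict[str, int] = field(default_factory=dict)


def lactating_cow_model() -> RfiModelSpec:
    """Contemporary group + parity + DIM + ECM + MBW + dBW."""
    return RfiModelSpec(fixed_factors=["cg", "parity"],
                        covariates=["DIM", "ECM", "MBW", "dBW"])


def overseas_cow_model(with_trial: bool = False) -> RfiModelSpec:
    """Parity-stage x lactation-stage + HYS + poly(age, 2) + DIM + ECM + MBW + dBW."""
    factors = ["parityST", "hys"] + (["trial"] if with_trial else [])
    return RfiModelSpec(fixed_factors=factors,
                        covariates=["DIM", "ECM", "MBW", "dBW", "age"],
                        polynomial_degrees={"age": 2})


def compute_ecm(milk, fat, protein):
    """Energy-corrected milk, kg/day: 0.1*milk + 5.2*fat + 2.6*protein."""
    milk = np.asarray(milk, dtype=float)
    fat = np.asarray(fat, dtype=float)
    protein = np.asarray(protein, dtype=float)
    for name, arr in (("milk", milk), ("fat", fat), ("protein", protein)):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"negative {name} yield")
    return 0.1 * milk + 5.2 * fat + 2.6 * protein


def orthogonal_poly(x, degree: int) -> np.ndarray:
    """Orthogonal-polynomial basis of ``x`` (constant column excluded).

    Columns are mutually orthogonal, orthogonal to the 1-vector, and
    unit-norm — the QR construction used by standard statistical software.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(x).size < degree + 1:
        raise ValueError(
            f"orthogonal polynomial of degree {degree} needs > {degree} distinct values")
    xc = x - x.mean()
    v = np.vander(xc, degree + 1, increasing=True)
    q, r = np.linalg.qr(v)
    # fix signs so each column correlates positively with its raw monomial
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q[:, 1:] * signs[1:]


def compute_delta_bw(dim, bw, degree: int = 5, min_records: int = 7,
                     min_span: int = 30) -> np.ndarray | None:
    """Daily body-weight change from a smoothed weight trajectory.

    Fits a degree-``degree`` polynomial regression of BW on DIM (equivalent to
    an orthogonal-polynomial fit; same fitted values) and returns the
    difference in predicted BW between each record's day and the previous day.
    Returns ``None`` when the trajectory is too short or too narrow to
    support the fit (the animal is then excluded from RFI derivation).
    """
    dim = np.asarray(dim, dtype=float)
    bw = np.asarray(bw, dtype=float)
    ok = np.isfinite(dim) & np.isfinite(bw)
    dim, bw = dim[ok], bw[ok]
    if dim.size < min_records or np.ptp(dim) < min_span or np.unique(dim).size <= degree:
        return None
    poly = np.polynomial.Polynomial.fit(dim, bw, deg=degree)
    return poly(dim) - poly(dim - 1.0)


def parity_stage(parity, dim) -> pd.Series:
    """Parity {1, 2, 3+} crossed with lactation stage {<=30, 31-100, 101-200, >200} DIM."""
    parity = pd.Series(parity).astype(float)
    dim = pd.Series(dim).astype(float)
    pcls = np.where(parity >= 3, "3+", parity.astype("Int64").astype(str))
    stage = pd.cut(dim, bins=[-np.inf, 30, 100, 200, np.inf],
                   labels=["s1", "s2", "s3", "s4"])
    return pd.Series([f"p{p}_{s}" for p, s in zip(pcls, stage.astype(str))],
                     index=dim.index)


def _design_matrix(df: pd.DataFrame, spec: RfiModelSpec) -> np.ndarray:
    cols = [np.ones(len(df))]
    for factor in spec.fixed_factors:
        levels = df[factor].astype(str)
        observed = levels.unique()
        if len(observed) < 2:
            warnings.warn(f"factor {factor!r} has a single observed level; dropped",
                          stacklevel=3)
            continue
        dummies = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)
        cols.append(dummies)
    for cov in spec.covariates:
        x = df[cov].to_numpy(dtype=float)
        deg = spec.polynomial_degrees.get(cov)
        if deg:
            cols.append(orthogonal_poly(x, deg))
        else:
            cols.append(x[:, None])
    return np.column_stack(cols)


def derive_rfi(table: pd.DataFrame, spec: RfiModelSpec,
               dmi_col: str = "DMI") -> pd.DataFrame:
    """Per-animal RFI: mean OLS residual of DMI on the model's terms.

    Records with missing DMI or covariates are dropped before fitting.
    Returns one row per animal: ``animal_id, RFI, n_records`` plus carried-over
    identity columns (dataset, sire, birth year) where present.
    """
    missing_cols = [c for c in spec.fixed_factors + spec.covariates + [dmi_col]
                    if c not in table.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks model column(s) {missing_cols}")
    needed = spec.covariates + [dmi_col]
    work = table.dropna(subset=needed).copy()
    if work.empty:
        raise ValueError("no records left after dropping missing covariates")
    x = _design_matrix(work, spec)
    y = work[dmi_col].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    work["RFI"] = y - x @ beta
    carry = [c for c in ("dataset", "country", "sire_id", "birth_year") if c in work]
    out = work.groupby("animal_id", sort=False).agg(
        RFI=("RFI", "mean"), n_records=("RFI", "size"),
        **{c: (c, "first") for c in carry})
    return out.reset_index()


def standardise(values, label: str = "") -> np.ndarray:
    """(x - mean)/SD with sample SD (n-1); error on zero variance."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"zero or undefined variance in dataset {label or '<unnamed>'}")
    return (x - x.mean()) / sd


def standardise_by_dataset(df: pd.DataFrame, value_col: str = "RFI",
                           dataset_col: str = "dataset") -> pd.DataFrame:
    """Standardise a derived trait within each dataset before pooling."""
    out = df.copy()
    for label, idx in out.groupby(dataset_col).groups.items():
        out.loc[idx, value_col] = standardise(out.loc[idx, value_col], str(label))
    return out
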