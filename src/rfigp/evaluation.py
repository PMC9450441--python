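"""Cross-validation designs and GEBV accuracy / dispersion-bias metrics.

Two fold designs over the validation cohort: cohort-by-birth-year (four
folds, small trailing years merged) and sire-family random folds (all
paternal half-sibs share a fold; unknown-sire animals stay in training).
Accuracy is cor(GEBV, corrected phenotype)/sqrt(h2); bias is the regression
slope of corrected phenotypes on GEBV (1 = no inflation).  Fold summaries
report mean accuracy with SE = SD(fold accuracies)/sqrt(4) — approximate,
because training sets overlap across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import UNKNOWN_SIRE

TRAIN_ONLY = 0


@dataclass
class FoldAssignment:
    """Animal -> fold index (1..k) or 0 for train-only."""

    fold: pd.Series           # index animal_id, int values
    n_folds: int
    design: str

    def validation_ids(self, f: int) -> list[str]:
        return list(self.fold.index[self.fold == f])

    def training_ids(self, f: int) -> list[str]:
        return list(self.fold.index[self.fold != f])

    def counts(self) -> pd.Series:
        return self.fold.value_counts().sort_index()


def cohort_folds(phenotypes: pd.DataFrame, *, year_col: str = "birth_year",
                 n_folds: int = 4, min_frac: float = 0.15) -> FoldAssignment:
    """Four folds by birth year; small trailing years merge into the previous.

    A trailing year whose share of eligible animals is below ``min_frac``
    is pooled with its neighbour (the analogue of merging the last two small
    birth-year cohorts); more than four year groups keep merging from the
    most recent end until four remain.
    """
    df = phenotypes.drop_duplicates("animal_id")
    years = df[year_col].astype(int)
    n = len(df)
    counts = years.value_counts().sort_index()
    if len(counts) < n_folds:
        raise ValueError(f"only {len(counts)} birth-year labels; need >= {n_folds} folds")
    groups: list[list[int]] = [[y] for y in counts.index]

    def gsize(g):
        return int(counts.loc[g].sum())

    # pool trailing years (most recent first) while more than n_folds groups
    # remain, or while the trailing group is small and pooling still leaves
    # enough groups — the "last two small years become one fold" rule
    while len(groups) > n_folds or (len(groups) > n_folds
                                    and gsize(groups[-1]) < min_frac * n):
        last = groups.pop()
        groups[-1] = groups[-1] + last
    if len(groups) != n_folds:
        raise ValueError(f"cannot form {n_folds} birth-year folds "
                         f"(got {len(groups)} usable year groups)")
    year_to_fold = {y: i + 1 for i, g in enumerate(groups) for y in g}
    fold = years.map(year_to_fold).fillna(TRAIN_ONLY).astype(int)
    fold.index = df["animal_id"]
    return FoldAssignment(fold, n_folds, "cohort")


def sire_family_folds(pedigree: pd.DataFrame, *, k: int = 4,
                      seed: int = 0) -> FoldAssignment:
    """Random k folds allocating whole paternal half-sib families together.

    Unknown-sire animals are train-only.  Sires are shuffled by ``seed`` and
    dealt greedily to the currently smallest fold, balancing animal counts.
    """
    df = pedigree.drop_duplicates("animal_id")
    known = df[df["sire_id"].ne(UNKNOWN_SIRE) & df["sire_id"].notna()]
    sires = known["sire_id"].unique()
    if len(sires) < k:
        raise ValueError(f"{len(sires)} sires cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = list(sires[rng.permutation(len(sires))])
    fam_size = known.groupby("sire_id").size()
    totals = np.zeros(k)
    sire_fold = {}
    for s in shuffled:
        f = int(np.argmin(totals))
        sire_fold[s] = f + 1
        totals[f] += fam_size[s]
    fold = df["sire_id"].map(sire_fold).fillna(TRAIN_ONLY).astype(int)
    fold.index = df["animal_id"]
    return FoldAssignment(fold, k, "random")


def gebv_accuracy(gebv, corrected_pheno, h2: float) -> float:
    """cor(GEBV, y*)/sqrt(h2) — h2 is the validation-trait genomic h2."""
    g = np.asarray(gebv, float)
    y = np.asarray(corrected_pheno, float)
    if g.size != y.size or g.size < 10:
        raise ValueError("need >= 10 aligned animals")
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    if g.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(g, y)[0, 1] / np.sqrt(h2))


def gebv_bias(gebv, corrected_pheno) -> float:
    """OLS slope of corrected phenotypes on GEBV; 1 = unbiased dispersion."""
    g = np.asarray(gebv, float)
    y = np.asarray(corrected_pheno, float)
    vg = g.var(ddof=0)
    if vg == 0:
        return np.nan
    return float(np.cov(g, y, ddof=0)[0, 1] / vg)


@dataclass
class AccuracyReport:
    per_fold: pd.DataFrame        # columns: fold, n, accuracy, bias
    mean_accuracy: float
    se_accuracy: float            # sd of fold accuracies / sqrt(n_folds)
    mean_bias: float
    design: str = ""
    approximate_se: bool = True


def summarize(fold_results: list[dict], design: str = "",
              expected_folds: int | None = 4) -> AccuracyReport:
    """Aggregate per-fold accuracy/bias; SE = SD(accuracies)/sqrt(#folds)."""
    if expected_folds is not None and len(fold_results) != expected_folds:
        raise ValueError(f"expected {expected_folds} folds, got {len(fold_results)}")
    df = pd.DataFrame(fold_results).sort_values("fold").reset_index(drop=True)
    acc = df["accuracy"].to_numpy(float)
    se = float(np.std(acc, ddof=1) / np.sqrt(len(acc))) if len(acc) > 1 else np.nan
    return AccuracyReport(df, float(np.mean(acc)), se,
                          float(np.nanmean(df["bias"].to_numpy(float))), design)
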