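"""Sequence-variant filtering and sliding-window top-association selection.

The selection recipe: drop variants whose imputation R2 is <= 0.4 in *both*
named datasets, drop variants with discovery-set MAF <= 0.006, then walk
100-kb windows sliding by 50 kb along each chromosome and keep at most the
three most significant variants with p < 1e-3 per window.  Window-level
nominations are deduplicated into one set; single-trait and multi-trait
selections can be unioned into a combined set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionSet:
    """A named set of selected variant ids with its provenance."""

    name: str
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in selection set")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def as_set(self) -> set[str]:
        return set(self.variant_ids)


def filter_variants(variants: pd.DataFrame, *, r2_min: float = 0.4,
                    maf_min: float = 0.006,
                    datasets: tuple[str, str] = ("home", "overseas"),
                    maf_col: str = "maf") -> np.ndarray:
    """Boolean retain-mask: R2 > r2_min in at least one dataset AND maf > maf_min.

    (A variant is removed only when its imputation R2 fails in *both*
    datasets; the MAF bound is strict, so maf == maf_min is removed.)
    """
    r2_cols = [f"impute_r2_{d}" for d in datasets]
    missing = [c for c in r2_cols + [maf_col] if c not in variants.columns]
    if missing:
        raise KeyError(f"variant table lacks column(s) {missing}")
    r2_ok = np.zeros(len(variants), dtype=bool)
    for c in r2_cols:
        r2_ok |= variants[c].to_numpy(float) > r2_min
    maf_ok = variants[maf_col].to_numpy(float) > maf_min
    return r2_ok & maf_ok


def select_top_windows(scan: pd.DataFrame, *, window_bp: int = 100_000,
                       slide_bp: int = 50_000, top_k: int = 3,
                       p_max: float = 1e-3, name: str = "selection",
                       ) -> SelectionSet:
    """Up to ``top_k`` variants with p < p_max per sliding window, deduplicated.

    Windows are half-open intervals [w*slide, w*slide + window) anchored at
    position 0 of each chromosome.  Ties in p break by larger |t|, then by
    lower position, so the output is deterministic.
    """
    work = scan.dropna(subset=["p"]).copy()
    work = work[work["p"] < p_max]
    chosen: set[str] = set()
    for chrom, grp in work.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(int)
        order_cols = np.lexsort((grp["pos"].to_numpy(),
                                 -np.abs(grp["t"].to_numpy()),
                                 grp["p"].to_numpy()))
        if pos.size == 0:
            continue
        max_pos = int(pos.max())
        n_windows = max_pos // slide_bp + 1
        ids = grp["id"].to_numpy(object)
        pos_ranked = pos[order_cols]
        ids_ranked = ids[order_cols]
        for w in range(n_windows):
            lo = w * slide_bp
            hi = lo + window_bp
            in_win = (pos_ranked >= lo) & (pos_ranked < hi)
            chosen.update(ids_ranked[in_win][:top_k])
    ordered = [v for v in scan["id"] if v in chosen]
    return SelectionSet(name, ordered, provenance={
        "window_bp": window_bp, "slide_bp": slide_bp, "top_k": top_k,
        "p_max": p_max, "window_origin": 0, "n_candidates": int(len(work)),
    })


def combine_sets(sets: list[SelectionSet], name: str = "combined") -> SelectionSet:
    """Union of selection sets, deduplicated, provenance concatenated."""
    if not sets:
        raise ValueError("need at least one selection set")
    seen: set[str] = set()
    ordered: list[str] = []
    for s in sets:
        for v in s.variant_ids:
            if v not in seen:
                seen.add(v)
                ordered.append(v)
    return SelectionSet(name, ordered,
                        provenance={"sources": [s.name for s in sets],
                                    "sizes": [len(s) for s in sets]})


def exclude_panel(selection: SelectionSet, variants: pd.DataFrame,
                  panel: str = "array") -> SelectionSet:
    """Drop selected variants already present on the named array panel."""
    on_panel = set(variants.loc[variants[f"panel_{panel}"].astype(bool), "id"])
    kept = [v for v in selection.variant_ids if v not in on_panel]
    prov = dict(selection.provenance)
    prov["excluded_panel"] = panel
    return SelectionSet(selection.name, kept, prov)
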