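"""End-to-end scenario orchestration: derive -> GRM -> (GWAS -> select ->
weighted GRM) -> GREML -> GBLUP -> cross-validated accuracy.

A :class:`Scenario` mirrors one row of a prediction-study design table: which
cohorts train, whether they are modelled as correlated traits or merged into
one, which relationship matrix is used (array panel, sequence panel, or a
variance-weighted combination of the array GRM with a GRM from
GWAS-selected sequence variants), and the validation fold design.  The
validation population is always the home lactating-cow cohort.  Discovery
GWAS for weighted scenarios use only the overseas cohorts, so the selected
variants come from an independent discovery set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (FoldAssignment, cohort_folds, gebv_accuracy, gebv_bias,
                         sire_family_folds, summarize)
from .genio import GRM, GenotypeMatrix
from .grm import build_grm_yang, combine_weighted_grm
from .gwas import fit_null_model, meta_multitrait, mlm_scan
from .mixedmodel import TraitData, fit_greml, heritability, predict_gebv
from .phenotypes import (RfiModelSpec, compute_ecm, derive_rfi,
                         lactating_cow_model, standardise_by_dataset)
from .selection import (SelectionSet, combine_sets, exclude_panel,
                        filter_variants, select_top_windows)
from .synthetic_data import HOME_COW, HOME_HEIFER, SimulationConfig


@dataclass
class DataBundle:
    """Everything a scenario needs: genotypes, pedigree, records, config."""

    genotypes: GenotypeMatrix          # sequence-level, with panel columns
    pedigree: pd.DataFrame
    records: pd.DataFrame
    config: SimulationConfig | None = None
    truth: pd.DataFrame | None = None


@dataclass
class Scenario:
    name: str
    training_datasets: tuple[str, ...] = (HOME_COW,)
    model: str = "univariate"            # univariate|bivariate|trivariate|merged
    grm_kind: str = "array"              # array|sequence|weighted
    selection: str = "sm"                # s_rfi|s_dmi|m|sm (weighted only)
    design: str = "both"                 # cohort|random|both


def prepare_phenotypes(bundle: DataBundle) -> pd.DataFrame:
    """Per-animal standardised RFI (plus DMI deviation) for every cohort.

    Cow cohorts get RFI from the records via the lactating-cow adjustment
    model; heifers carry a pre-derived deviation.  Both traits are
    standardised within dataset before pooling.
    """
    rec = bundle.records.copy()
    cows = rec[rec["dataset"] != HOME_HEIFER].copy()
    cows["ECM"] = compute_ecm(cows["milk"], cows["fat"], cows["protein"])
    cows["MBW"] = cows["BW"]
    rows = []
    dmi_spec = RfiModelSpec(fixed_factors=["cg", "parity"], covariates=["DIM"])
    for dataset, grp in cows.groupby("dataset", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfi = derive_rfi(grp, lactating_cow_model())
            dmi = derive_rfi(grp, dmi_spec).rename(columns={"RFI": "DMI_dev"})
        merged = rfi.merge(dmi[["animal_id", "DMI_dev"]], on="animal_id")
        rows.append(merged)
    out = pd.concat(rows, ignore_index=True)
    heifers = rec[rec["dataset"] == HOME_HEIFER]
    if len(heifers):
        h = heifers.groupby("animal_id", sort=False).agg(
            RFI=("rfi_precomputed", "mean"), dataset=("dataset", "first"),
            country=("country", "first"), sire_id=("sire_id", "first"),
            birth_year=("birth_year", "first"), n_records=("record", "size"))
        h["DMI_dev"] = np.nan
        out = pd.concat([out, h.reset_index()], ignore_index=True)
    out = standardise_by_dataset(out, "RFI")
    cow_mask = out["DMI_dev"].notna()
    if cow_mask.any():
        out.loc[cow_mask] = standardise_by_dataset(out.loc[cow_mask], "DMI_dev")
    return out


def _overseas_labels(phenos: pd.DataFrame) -> list[str]:
    return sorted(d for d in phenos["dataset"].unique()
                  if d not in (HOME_COW, HOME_HEIFER))


def _trait_data(phenos: pd.DataFrame, datasets: list[str], name: str,
                value_col: str = "RFI", country_fixed: bool = True) -> TraitData:
    df = phenos[phenos["dataset"].isin(datasets)]
    cols = [np.ones(len(df))]
    if country_fixed and df["dataset"].nunique() > 1:
        cols.append(pd.get_dummies(df["dataset"].astype(str), drop_first=True)
                    .to_numpy(float))
    return TraitData(name, list(df["animal_id"]), df[value_col].to_numpy(float),
                     np.column_stack(cols))


def assemble_traits(phenos: pd.DataFrame, scenario: Scenario,
                    mask_ids: set[str] | None = None) -> list[TraitData]:
    """TraitData list for the scenario's model, optionally masking records."""
    work = phenos
    if mask_ids:
        work = phenos[~(phenos["animal_id"].isin(mask_ids)
                        & (phenos["dataset"] == HOME_COW))]
    sets = set(scenario.training_datasets)
    ove = [d for d in _overseas_labels(phenos) if d in sets]
    traits: list[TraitData] = []
    if scenario.model == "merged":
        traits.append(_trait_data(work, [HOME_COW, *ove], "merged"))
        return traits
    traits.append(_trait_data(work, [HOME_COW], "home"))
    if scenario.model in ("bivariate", "trivariate"):
        if scenario.model == "trivariate" or (HOME_HEIFER in sets and not ove):
            if HOME_HEIFER in sets:
                traits.append(_trait_data(work, [HOME_HEIFER], "heifer"))
        if ove:
            traits.append(_trait_data(work, ove, "overseas"))
    return traits


# ---------------------------------------------------------------------------
# discovery GWAS and variant selection
# ---------------------------------------------------------------------------

def run_discovery_gwas(bundle: DataBundle, phenos: pd.DataFrame, *,
                       p_max: float = 1e-3, window_bp: int = 100_000,
                       slide_bp: int = 50_000, top_k: int = 3,
                       ) -> dict[str, SelectionSet]:
    """Single-trait RFI and DMI scans plus the multi-trait meta, on overseas
    cohorts only; returns the four selection sets keyed s_rfi/s_dmi/m/sm
    (array-panel variants already excluded)."""
    gm = bundle.genotypes
    ove_labels = _overseas_labels(phenos)
    keep = filter_variants(gm.variants)
    seq = gm.subset(variant_mask=keep)
    # polygenic term fitted with the dense *marker* GRM (not the sequence
    # panel under test, which would absorb the causal signal being scanned)
    from .synthetic_data import make_panel
    marker_panel = "hd" if "panel_hd" in gm.variants.columns else "array"
    markers = make_panel(gm, marker_panel)
    scans = {}
    for trait, col in (("rfi", "RFI"), ("dmi", "DMI_dev")):
        df = phenos[phenos["dataset"].isin(ove_labels)].dropna(subset=[col])
        ids = list(df["animal_id"])
        x = np.column_stack([np.ones(len(df)),
                             pd.get_dummies(df["dataset"].astype(str),
                                            drop_first=True).to_numpy(float)])
        g = build_grm_yang(markers.subset(animals=ids), maf_min="auto")
        null = fit_null_model(df[col].to_numpy(float), x, g, ids, name=trait)
        scans[trait] = mlm_scan(seq, null)
    meta = meta_multitrait([scans["rfi"], scans["dmi"]])
    meta_scan = meta.rename(columns={"p_meta": "p"}).copy()
    meta_scan["t"] = np.sqrt(meta_scan["chi2"])
    sets = {
        "s_rfi": select_top_windows(scans["rfi"], window_bp=window_bp,
                                    slide_bp=slide_bp, top_k=top_k, p_max=p_max,
                                    name="s-tr:rfi"),
        "s_dmi": select_top_windows(scans["dmi"], window_bp=window_bp,
                                    slide_bp=slide_bp, top_k=top_k, p_max=p_max,
                                    name="s-tr:dmi"),
        "m": select_top_windows(meta_scan, window_bp=window_bp,
                                slide_bp=slide_bp, top_k=top_k, p_max=p_max,
                                name="m-tr"),
    }
    sets["s_union"] = combine_sets([sets["s_rfi"], sets["s_dmi"]], name="s-tr")
    sets["sm"] = combine_sets([sets["s_rfi"], sets["s_dmi"], sets["m"]],
                              name="sm-tr")
    return {k: exclude_panel(s, gm.variants, "array") for k, s in sets.items()}


def build_scenario_grm(bundle: DataBundle, scenario: Scenario,
                       phenos: pd.DataFrame,
                       selection_sets: dict[str, SelectionSet] | None = None,
                       ) -> tuple[GRM, dict]:
    """The relationship matrix the scenario calls for, plus weight metadata."""
    gm = bundle.genotypes
    info: dict = {"grm_kind": scenario.grm_kind}
    from .synthetic_data import make_panel
    if scenario.grm_kind in ("array", "hd", "dense", "sequence"):
        panel = {"dense": "hd"}.get(scenario.grm_kind, scenario.grm_kind)
        return build_grm_yang(make_panel(gm, panel), "auto"), info
    if scenario.grm_kind != "weighted":
        raise ValueError(f"unknown grm_kind {scenario.grm_kind!r}")
    if selection_sets is None:
        selection_sets = run_discovery_gwas(bundle, phenos)
    sel = selection_sets[scenario.selection]
    array_gm = make_panel(gm, "array")
    grm_snp = build_grm_yang(array_gm, "auto")
    if len(sel) == 0:
        warnings.warn("empty selection set; falling back to the array GRM")
        return grm_snp, info
    sel_mask = gm.variants["id"].isin(sel.as_set()).to_numpy()
    grm_seq = build_grm_yang(gm.subset(variant_mask=sel_mask), maf_min="auto")
    # provisional whole-set weights; run_scenario re-estimates them per
    # training fold (the genetic variance each GRM captures on home records)
    home = phenos[phenos["dataset"] == HOME_COW]
    td = _trait_data(home.assign(dataset=HOME_COW), [HOME_COW], "home")
    var_snp = fit_greml(td, grm_snp).P[0, 0]
    var_seq = fit_greml(td, grm_seq).P[0, 0]
    info.update(selection=sel.name, n_selected=len(sel),
                var_snp=float(var_snp), var_seq=float(var_seq),
                components=(grm_snp, grm_seq))
    return combine_weighted_grm(grm_snp, grm_seq, var_snp, var_seq), info


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

def _fold_assignments(phenos: pd.DataFrame, design: str, seed: int,
                      ) -> FoldAssignment:
    home = phenos[phenos["dataset"] == HOME_COW]
    if design == "cohort":
        return cohort_folds(home)
    return sire_family_folds(home, seed=seed)


def run_scenario(scenario: Scenario, bundle: DataBundle, *, seed: int = 0,
                 phenos: pd.DataFrame | None = None,
                 selection_sets: dict[str, SelectionSet] | None = None,
                 array_grm: GRM | None = None,
                 refit_vc_per_fold: bool = False,
                 out_dir: str | Path | None = None) -> dict:
    """Execute one scenario end-to-end and return its accuracy report(s).

    Variance components are estimated once per scenario from the full record
    set and treated as known in each fold's mixed-model equations;
    validation-fold phenotypes are always masked for prediction, and the
    heritability used in the accuracy denominator is re-estimated per
    training fold from the array GRM.  ``refit_vc_per_fold=True`` refits the
    full (multi-trait) GREML per fold instead.
    """
    if phenos is None:
        phenos = prepare_phenotypes(bundle)
    manifest = {
        "scenario": asdict(scenario), "seed": seed, "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(scenario), sort_keys=True).encode()).hexdigest()[:16],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    grm_full, grm_info = build_scenario_grm(bundle, scenario, phenos,
                                            selection_sets)
    weighted_parts = grm_info.pop("components", None)
    array_grm = array_grm if array_grm is not None else (
        grm_full if scenario.grm_kind == "array"
        else weighted_parts[0] if weighted_parts is not None
        else build_scenario_grm(bundle, Scenario("array-h2"), phenos)[0])

    traits_full = assemble_traits(phenos, scenario)
    vc = (fit_greml(traits_full, grm_full)
          if not (refit_vc_per_fold or weighted_parts) else None)

    home = phenos[phenos["dataset"] == HOME_COW].set_index("animal_id")
    designs = ("cohort", "random") if scenario.design == "both" else (scenario.design,)
    reports = {}
    for design in designs:
        folds = _fold_assignments(phenos.reset_index(drop=True), design, seed)
        fold_rows = []
        for f in range(1, folds.n_folds + 1):
            val_ids = folds.validation_ids(f)
            mask = set(val_ids)
            traits = assemble_traits(phenos, scenario, mask_ids=mask)
            train_home = home.loc[~home.index.isin(mask), "RFI"]
            td_home = TraitData("home_h2", list(train_home.index),
                                train_home.to_numpy(), np.ones((len(train_home), 1)))
            grm_fold = grm_full
            if weighted_parts is not None:
                # fold-specific weights: genetic variance each component GRM
                # explains on this fold's home training records
                grm_snp, grm_seq = weighted_parts
                w_snp = fit_greml(td_home, grm_snp).P[0, 0]
                w_seq = fit_greml(td_home, grm_seq).P[0, 0]
                grm_fold = combine_weighted_grm(grm_snp, grm_seq, w_snp, w_seq)
                vc_f = fit_greml(traits, grm_fold)
                grm_info.setdefault("fold_weights", []).append(
                    {"fold": f, "design": design, "var_snp": float(w_snp),
                     "var_seq": float(w_seq)})
            else:
                vc_f = fit_greml(traits, grm_full) if refit_vc_per_fold else vc
            gebv = predict_gebv(traits, grm_fold, vc_f, animals=val_ids,
                                allow_unconverged=True)
            # corrected phenotype: subtract training-estimated fixed effects
            ystar = home.loc[val_ids, "RFI"].to_numpy() - train_home.mean()
            # denominator h2 from the array GRM on the training home records
            h2_f, _ = heritability(fit_greml(td_home, array_grm))
            g = gebv.table.iloc[:, 0].to_numpy()
            fold_rows.append({"fold": f, "n": len(val_ids),
                              "corr": (np.corrcoef(g, ystar)[0, 1]
                                       if g.std() > 0 and ystar.std() > 0 else np.nan),
                              "bias": gebv_bias(g, ystar), "h2_fold": h2_f})
        # fold-averaged h2 as the common accuracy denominator (floored away
        # from zero: a near-zero fold estimate would explode the ratio)
        h2_bar = max(float(np.nanmean([r["h2_fold"] for r in fold_rows])), 0.05)
        for r in fold_rows:
            r["accuracy"] = r.pop("corr") / np.sqrt(h2_bar)
            r["h2_denom"] = h2_bar
        reports[design] = summarize(fold_rows, design=design,
                                    expected_folds=folds.n_folds)
    result = {
        "scenario": scenario.name, "manifest": manifest, "grm": grm_info,
        "vc_converged": bool(vc.converged) if vc is not None else None,
        "reports": reports,
    }
    if out_dir is not None:
        serial = {k: (v if k != "reports" else {
            d: {"mean_accuracy": r.mean_accuracy, "se_accuracy": r.se_accuracy,
                "mean_bias": r.mean_bias,
                "per_fold": r.per_fold.to_dict("records")}
            for d, r in v.items()}) for k, v in result.items()}
        (out_dir / "report.json").write_text(json.dumps(serial, indent=2))
    return result


def report_difference(results: dict[str, dict], baseline: str) -> pd.DataFrame:
    """Accuracy differences vs a baseline scenario, in percentage points."""
    if baseline not in results:
        raise KeyError(f"baseline scenario {baseline!r} missing from results")
    rows = []
    for name, res in results.items():
        for design, rep in res["reports"].items():
            base = results[baseline]["reports"][design].mean_accuracy
            rows.append({"scenario": name, "design": design,
                         "accuracy": rep.mean_accuracy, "bias": rep.mean_bias,
                         "difference_pct": 100.0 * (rep.mean_accuracy - base)})
    return pd.DataFrame(rows)
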