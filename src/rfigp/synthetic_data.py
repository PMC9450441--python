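"""Synthetic multi-country cattle data with the structure the pipeline assumes.

The generator emulates a single dairy breed measured for feed intake in
several countries: mild between-country differentiation (Balding–Nichols
drift on a shared founder frequency spectrum), linkage disequilibrium from a
founder-haplotype mosaic copying model, paternal half-sib families, an array
panel nested inside a sequence panel with the causal variants (optionally)
restricted to the sequence-only part, per-variant imputation-quality scores,
and record-level milk / body-weight / intake phenotypes from which residual
feed intake can be re-derived.

Three cohorts carry the trait: a home lactating-cow cohort (the validation
population analogue), a home growing-heifer cohort, and overseas cow cohorts
pooled as "overseas".  The same QTL affect all three, with configurable
genetic correlations, so the cohorts behave as correlated traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, UNKNOWN_SIRE, GenotypeMatrix

HOME_COW = "home_cow"
HOME_HEIFER = "home_heifer"

#: dataset labels carrying per-variant imputation-quality scores
R2_LABELS = ("home", "overseas")


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults target the observed ranges of the real multi-country material:
    heritabilities 0.19 (home cows), 0.27 (overseas cows), 0.36 (heifers);
    genetic correlations 0.95 / 0.34 / 0.25 between the cohort traits;
    FST-scale differentiation of a few per mil; Holstein-like expected
    heterozygosity around 0.33.
    """

    n_countries: int = 7            # country 0 is the home country
    animals_per_country: int | tuple[int, ...] = (400, 300, 300, 300, 300, 300, 300)
    n_heifers: int = 300            # growing heifers, home country only
    n_sires_per_country: int = 40
    n_global_sires: int = 25        # international AI sires shared by all countries
    global_sire_fraction: float = 0.5  # offspring share sired by the global pool
    n_chrom: int = 12
    chrom_length_bp: int = 10_000_000
    n_sequence_variants: int = 6_000
    array_fraction: float = 0.50
    hd_maf_min: float = 0.01        # dense marker panel: all common-ish non-causal
    n_qtl: int = 1000
    n_large_qtl: int = 20           # heavy-tailed subset of the QTL
    large_qtl_var_share: float = 0.45
    n_bw_qtl: int = 300             # body-weight QTL feeding the intake trait
    n_bw_large: int = 15
    bw_large_share: float = 0.5
    bw_genetic_sd: float = 35.0     # kg; body-weight environmental SD is 45
    causal_off_array: bool = True
    h2: tuple[float, ...] = (0.19, 0.27, 0.36)       # home cows, overseas, heifers
    genetic_correlation_matrix: tuple[tuple[float, ...], ...] = (
        (1.00, 0.95, 0.34),
        (0.95, 1.00, 0.25),
        (0.34, 0.25, 1.00),
    )
    pheno_sd: tuple[float, ...] = (1.5, 1.5, 0.45)   # RFI phenotypic SD per cohort
    country_fst: tuple[float, ...] | float = 0.01
    n_founder_haplotypes: int = 150
    records_per_animal: int = 2
    record_noise_sd: float = 0.30   # within-animal lactation-record noise on DMI
    unknown_sire_fraction: float = 0.10
    maf_floor: float = 0.01         # truncation of the founder frequency spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        rg = np.asarray(self.genetic_correlation_matrix, dtype=float)
        t = len(self.h2)
        if rg.shape != (t, t):
            raise ConfigError(f"genetic_correlation_matrix must be {t}x{t}")
        if not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
            raise ConfigError("genetic_correlation_matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(rg).min() < -1e-10:
            raise ConfigError("genetic_correlation_matrix must be positive semi-definite")
        if not all(0.0 <= h < 1.0 for h in self.h2):
            raise ConfigError("h2 must lie in [0, 1)")
        if not 0.0 < self.array_fraction < 1.0:
            raise ConfigError("array_fraction must be in (0, 1)")
        if self.n_qtl + self.n_bw_qtl > self.n_sequence_variants:
            raise ConfigError(
                f"n_qtl={self.n_qtl} + n_bw_qtl={self.n_bw_qtl} exceeds "
                f"{self.n_sequence_variants} variants")

    @property
    def fst_per_country(self) -> np.ndarray:
        f = self.country_fst
        if np.isscalar(f):
            return np.full(self.n_countries, float(f))
        f = np.asarray(f, dtype=float)
        if f.size != self.n_countries:
            raise ConfigError("country_fst must be scalar or one value per country")
        return f

    @property
    def rg(self) -> np.ndarray:
        return np.asarray(self.genetic_correlation_matrix, dtype=float)

    def scaled_down(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _mosaic_gamete(hap_pool: np.ndarray, chrom_slices: list[slice],
                   rng: np.random.Generator,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """One recombinant gamete copied from a haplotype pool (~1 crossover/chrom).

    ``weights`` biases which founder each segment is copied from (country-
    specific founder-usage frequencies); uniform when omitted.
    """
    m = hap_pool.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for sl in chrom_slices:
        length = sl.stop - sl.start
        n_x = rng.poisson(1.0)
        breaks = np.sort(rng.integers(1, length, size=n_x)) if n_x and length > 1 else []
        bounds = [0, *breaks, length]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if weights is None:
                src = rng.integers(hap_pool.shape[0])
            else:
                src = rng.choice(hap_pool.shape[0], p=weights)
            gamete[sl.start + lo: sl.start + hi] = hap_pool[src, sl.start + lo: sl.start + hi]
    return gamete


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sequence-level genotypes plus a pedigree with sires and birth years.

    Returns the full sequence-density :class:`GenotypeMatrix` (panel columns
    mark the nested array subset) and a pedigree DataFrame with columns
    ``animal_id, sire_id, birth_year, country, dataset``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_sequence_variants
    n_countries = config.n_countries
    fst = config.fst_per_country

    # variant map: equal variants per chromosome, sorted 1-based positions
    per_chrom = np.full(config.n_chrom, m // config.n_chrom)
    per_chrom[: m % config.n_chrom] += 1
    chroms, positions, chrom_slices = [], [], []
    start = 0
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1), size=k,
                                 replace=False))
        chroms.append(np.full(k, c))
        positions.append(pos)
        chrom_slices.append(slice(start, start + k))
        start += k
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    # U-shaped founder spectrum truncated away from fixation
    p = rng.beta(0.4, 0.4, size=m)
    p = np.clip(p, config.maf_floor, 1.0 - config.maf_floor)

    # one global founder-haplotype pool shared by every country (a single
    # breed); differentiation comes from country-specific founder-usage
    # weights.  With Dirichlet weights of total concentration A = (1-F)/F,
    # the per-country allele frequency is Beta(A*p, A*(1-p)) given the
    # realized founder frequency p — exactly Balding–Nichols drift with
    # parameter F — while haplotypes (hence LD and relatedness) stay shared
    # across countries.
    n_f = config.n_founder_haplotypes
    pool = (rng.random((n_f, m)) < p).astype(np.int8)
    weights = []
    for c in range(n_countries):
        f = fst[c]
        if f > 0:
            conc = (1.0 - f) / f
            weights.append(rng.dirichlet(np.full(n_f, conc / n_f)))
        else:
            weights.append(None)  # uniform

    # pedigree scaffold: cows in every country, heifers only at home
    apc = config.animals_per_country
    counts = list(apc) if not np.isscalar(apc) else [apc] * n_countries
    if len(counts) != n_countries:
        raise ConfigError("animals_per_country must be scalar or one count per country")
    records = []
    dosages = np.empty((sum(counts) + config.n_heifers, m), dtype=np.int8)
    year_choices = np.array([2013, 2014, 2015, 2016, 2017])
    year_probs = np.array([0.28, 0.28, 0.28, 0.08, 0.08])

    # international AI sires: shared across every country, drawn from the
    # breed-wide (uniform) founder distribution
    global_sires = {
        f"sire_glob_{s}": np.vstack([_mosaic_gamete(pool, chrom_slices, rng),
                                     _mosaic_gamete(pool, chrom_slices, rng)])
        for s in range(config.n_global_sires)
    }
    global_ids = list(global_sires)

    row = 0
    for c in range(n_countries):
        w_c = weights[c]
        n_animals = counts[c] + (config.n_heifers if c == 0 else 0)
        sire_ids = [f"sire_c{c}_{s}" for s in range(config.n_sires_per_country)]
        sire_haps = {
            s: (np.vstack([_mosaic_gamete(pool, chrom_slices, rng, w_c),
                           _mosaic_gamete(pool, chrom_slices, rng, w_c)]))
            for s in sire_ids
        }
        sire_haps.update(global_sires)
        use_global = rng.random(n_animals) < config.global_sire_fraction
        local_pick = rng.choice(sire_ids, size=n_animals)
        global_pick = rng.choice(global_ids, size=n_animals) if global_ids else local_pick
        assignments = np.where(use_global & (len(global_ids) > 0),
                               global_pick, local_pick)
        unknown = rng.random(n_animals) < config.unknown_sire_fraction
        for i in range(n_animals):
            sire = assignments[i]
            paternal = _mosaic_gamete(sire_haps[sire], chrom_slices, rng)
            maternal = _mosaic_gamete(pool, chrom_slices, rng, w_c)
            dosages[row] = paternal + maternal
            is_heifer = c == 0 and i >= counts[c]
            dataset = (HOME_HEIFER if is_heifer
                       else HOME_COW if c == 0 else f"ove{c}")
            records.append({
                "animal_id": f"an_c{c}_{i}",
                "sire_id": UNKNOWN_SIRE if unknown[i] else sire,
                "birth_year": int(rng.choice(year_choices, p=year_probs)),
                "country": f"country{c}",
                "dataset": dataset,
            })
            row += 1
    pedigree = pd.DataFrame(records)

    variants = pd.DataFrame({
        "id": [f"c{c}:{q}" for c, q in zip(chrom, pos)],
        "chrom": chrom.astype(str),
        "pos": pos,
        "a1": "A",
        "a2": "B",
    })
    gm = GenotypeMatrix(list(pedigree["animal_id"]), variants, dosages)

    maf = gm.maf()
    gm.variants["maf"] = maf

    # causal variants (feed-efficiency QTL plus a disjoint body-weight QTL
    # set feeding the intake trait), then the nested array panel
    qtl_pool = np.flatnonzero(maf >= 0.05)
    if qtl_pool.size < config.n_qtl + config.n_bw_qtl:
        raise ConfigError("not enough common variants for the requested QTL count")
    both = rng.choice(qtl_pool, size=config.n_qtl + config.n_bw_qtl, replace=False)
    qtl_idx = both[: config.n_qtl]
    bw_idx = both[config.n_qtl:]
    is_qtl = np.zeros(m, dtype=bool)
    is_qtl[qtl_idx] = True
    is_bw_qtl = np.zeros(m, dtype=bool)
    is_bw_qtl[bw_idx] = True

    marker_ok = ~((is_qtl | is_bw_qtl) & config.causal_off_array)
    array_pool = np.flatnonzero((maf >= 0.05) & marker_ok)
    n_array = int(round(config.array_fraction * m))
    if n_array > array_pool.size:
        n_array = array_pool.size
    array_idx = rng.choice(array_pool, size=n_array, replace=False)
    panel_array = np.zeros(m, dtype=bool)
    panel_array[array_idx] = True
    # dense marker tier: every common-ish marker (causal still excluded when
    # the study design keeps causal variants off the genotyping arrays)
    panel_hd = (maf >= config.hd_maf_min) & marker_ok
    panel_hd |= panel_array

    # imputation-quality scores: ~60% of variants clear the 0.4 threshold
    base_q = np.where(rng.random(m) < 0.60, rng.uniform(0.45, 1.0, m),
                      rng.uniform(0.0, 0.40, m))
    gm.variants["qtl"] = is_qtl
    gm.variants["qtl_bw"] = is_bw_qtl
    gm.variants["panel_array"] = panel_array
    gm.variants["panel_hd"] = panel_hd
    gm.variants["panel_sequence"] = True
    for label in R2_LABELS:
        gm.variants[f"impute_r2_{label}"] = np.clip(
            base_q + rng.normal(0.0, 0.05, m), 0.0, 1.0)
    return gm, pedigree


def make_panel(gm: GenotypeMatrix, panel_label: str) -> GenotypeMatrix:
    """Column-subset of the variants on the named panel (metadata preserved)."""
    col = f"panel_{panel_label}"
    if col not in gm.variants.columns:
        raise KeyError(f"unknown panel {panel_label!r}; have "
                       f"{[c[6:] for c in gm.variants.columns if c.startswith('panel_')]}")
    mask = gm.variants[col].to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError(f"panel {panel_label!r} is empty")
    if mask.all():
        return gm
    return gm.subset(variant_mask=mask)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _trait_index(dataset: str) -> int:
    if dataset == HOME_COW:
        return 0
    if dataset == HOME_HEIFER:
        return 2
    return 1  # any overseas country


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    v = x.var(ddof=0)
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_traits(gm: GenotypeMatrix, pedigree: pd.DataFrame,
                    config: SimulationConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record-level phenotypes plus the hidden per-animal truth.

    QTL effects for the three cohort traits are drawn from a multivariate
    normal with the configured genetic correlations; true breeding values are
    scaled so the realized within-cohort heritability matches ``config.h2``
    exactly.  Cow cohorts receive record-level milk, fat, protein, body
    weight, daily body-weight change, parity, DIM and contemporary-group
    labels, with DMI built as a linear function of energy-corrected milk,
    metabolic-scale body weight and weight change plus the genetic RFI
    deviation and noise — so the phenotype-derivation stage faces an unbiased
    recovery problem.  Heifers carry an already-derived trait deviation.

    Returns ``(records, truth)``; ``truth`` has one row per animal with the
    true breeding value per cohort trait (``tbv_t0..``), the injected animal
    RFI deviation ``rfi_true`` and the noise-free direct phenotype
    ``pheno_direct`` (tbv + environmental deviation at exact h2).
    """
    rng = np.random.default_rng(config.seed + 104729)
    rgmat = config.rg
    t_traits = rgmat.shape[0]
    if np.linalg.matrix_rank(rgmat) < t_traits and np.linalg.eigvalsh(rgmat).min() < 1e-12:
        # PSD but singular is allowed (rg = 1); truly invalid caught in config
        pass

    qtl = gm.variants["qtl"].to_numpy(dtype=bool)
    if not qtl.any():
        raise ConfigError("genotypes carry no causal candidates (no qtl flagged)")
    z = gm.dosages[:, qtl].astype(float)
    z[z == MISSING] = np.nan
    z = np.where(np.isnan(z), np.nanmean(z, axis=0), z)
    p_qtl = z.mean(axis=0) / 2.0
    z = z - 2.0 * p_qtl

    # correlated per-QTL effects; chol handles the PSD case via eigen fallback
    try:
        chol = np.linalg.cholesky(rgmat + 1e-12 * np.eye(t_traits))
    except np.linalg.LinAlgError as exc:
        raise ConfigError("genetic correlation matrix is not positive semi-definite") from exc
    effects = rng.standard_normal((qtl.sum(), t_traits)) @ chol.T
    # polygenic architecture: standardised per-allele effects (variance
    # 1/(2pq)) with a small heavy-tailed subset of larger loci carrying
    # ``large_qtl_var_share`` of the genetic variance
    n_qtl = qtl.sum()
    scale = np.ones(n_qtl)
    n_large = min(config.n_large_qtl, n_qtl)
    large_idx = np.array([], dtype=int)
    if n_large and 0.0 < config.large_qtl_var_share < 1.0 and n_large < n_qtl:
        share = config.large_qtl_var_share
        mult = share * (n_qtl - n_large) / ((1.0 - share) * n_large)
        large_idx = rng.choice(n_qtl, size=n_large, replace=False)
        scale[large_idx] = np.sqrt(mult)
        # fix the magnitude of each large locus (random orientation keeps the
        # cross-trait correlation); otherwise chi-squared draws leave half of
        # the nominally detectable loci with next-to-no realized effect
        rows = effects[large_idx]
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        effects[large_idx] = rows / np.maximum(norms, 1e-12) * np.sqrt(t_traits)
    gm.variants["qtl_large"] = False
    gm.variants.loc[np.flatnonzero(qtl)[large_idx], "qtl_large"] = True
    het_qtl = np.clip(2.0 * p_qtl * (1.0 - p_qtl), 1e-4, None)
    effects = effects * (scale / np.sqrt(het_qtl))[:, None]

    tbv_raw = z @ effects                      # animals x traits
    trait_of = pedigree["dataset"].map(_trait_index).to_numpy()
    if trait_of.max() >= t_traits:
        raise ConfigError(
            f"pedigree contains cohorts for trait index {trait_of.max()} but only "
            f"{t_traits} traits are configured (set n_heifers=0 for two-trait runs)")
    pheno_var = np.asarray(config.pheno_sd, dtype=float) ** 2

    # one uniform scale per trait (anchored on the cohort expressing it) so the
    # realized within-cohort h2 is exact while cross-cohort TBV correlations
    # keep the configured structure
    tbv = tbv_raw.copy()
    rfi_true = np.zeros(len(pedigree))
    pheno_direct = np.zeros(len(pedigree))
    env = np.zeros(len(pedigree))
    for t in range(t_traits):
        members = trait_of == t
        if not members.any():
            continue
        g_cohort = tbv_raw[members, t]
        centred = g_cohort - g_cohort.mean()
        v = centred.var(ddof=0)
        target = config.h2[t] * pheno_var[t]
        scale = np.sqrt(target / v) if v > 0 and target > 0 else 0.0
        tbv[:, t] = (tbv_raw[:, t] - g_cohort.mean()) * scale
        e = rng.standard_normal(members.sum())
        e -= e.mean()
        g_centred = tbv[members, t] - tbv[members, t].mean()
        gss = g_centred @ g_centred
        if gss > 0:
            e -= g_centred * (g_centred @ e) / gss  # exact realized h2
        e = _scale_to_var(e, (1.0 - config.h2[t]) * pheno_var[t])
        env[members] = e
        rfi_true[members] = tbv[members, t] + e
        pheno_direct[members] = tbv[members, t] + e

    # raw (unscaled) genetic value of the expressed trait, for h2 = 0 checks
    gv_raw = tbv_raw[np.arange(len(pedigree)), trait_of]

    # independent body-weight genetics: flows into DMI through the MBW term
    # (so the intake deviation carries production genetics the RFI adjustment
    # removes), giving the DMI scan complementary signal for the meta-GWAS
    bw_tbv = np.zeros(len(pedigree))
    bw_qtl = (gm.variants["qtl_bw"].to_numpy(dtype=bool)
              if "qtl_bw" in gm.variants.columns else np.zeros(gm.n_variants, bool))
    if bw_qtl.any() and config.bw_genetic_sd > 0:
        zb = gm.dosages[:, bw_qtl].astype(float)
        zb[zb == MISSING] = np.nan
        zb = np.where(np.isnan(zb), np.nanmean(zb, axis=0), zb)
        p_b = zb.mean(axis=0) / 2.0
        zb = zb - 2.0 * p_b
        n_b = int(bw_qtl.sum())
        b_eff = rng.standard_normal(n_b)
        s_b = np.ones(n_b)
        n_bl = min(config.n_bw_large, n_b)
        if n_bl and 0.0 < config.bw_large_share < 1.0 and n_bl < n_b:
            mult_b = config.bw_large_share * (n_b - n_bl) / ((1 - config.bw_large_share) * n_bl)
            idx_b = rng.choice(n_b, size=n_bl, replace=False)
            s_b[idx_b] = np.sqrt(mult_b)
            b_eff[idx_b] = np.sign(b_eff[idx_b])  # fixed magnitude, random sign
        het_b = np.clip(2.0 * p_b * (1.0 - p_b), 1e-4, None)
        raw_bw = zb @ (b_eff * s_b / np.sqrt(het_b))
        bw_tbv = _scale_to_var(raw_bw - raw_bw.mean(), config.bw_genetic_sd ** 2)

    truth = pd.DataFrame({
        "animal_id": pedigree["animal_id"],
        "dataset": pedigree["dataset"],
        "trait_index": trait_of,
        "rfi_true": rfi_true,
        "env": env,
        "pheno_direct": pheno_direct,
        "gv_raw": gv_raw,
        "bw_tbv": bw_tbv,
    })
    for t in range(t_traits):
        truth[f"tbv_t{t}"] = tbv[:, t]

    # record-level phenotype construction (cows only)
    rows = []
    seasons = ("Q1", "Q2", "Q3", "Q4")
    for i, ped in enumerate(pedigree.itertuples(index=False)):
        if ped.dataset == HOME_HEIFER:
            rows.append({
                "animal_id": ped.animal_id, "sire_id": ped.sire_id,
                "dataset": ped.dataset, "country": ped.country,
                "birth_year": ped.birth_year, "record": 0,
                "DIM": np.nan, "parity": np.nan, "age": np.nan,
                "milk": np.nan, "fat": np.nan, "protein": np.nan,
                "BW": np.nan, "dBW": np.nan, "DMI": np.nan,
                "cg": "", "hys": "", "rfi_precomputed": rfi_true[i],
            })
            continue
        n_rec = max(1, int(rng.integers(1, config.records_per_animal + 1)))
        parity = int(rng.integers(1, 5))
        age = 22 + 12 * (parity - 1) + float(rng.normal(0, 2))  # months at calving
        bw_base = 600.0 + bw_tbv[i] + float(rng.normal(0, 45))
        cg = f"{ped.country}_cg{int(rng.integers(4))}"
        herd = "h2" if (ped.country.endswith("3") and rng.random() < 0.5) else "h1"
        season = seasons[int(rng.integers(4))]
        hys = f"{ped.country}_{herd}_{ped.birth_year}_{season}"
        for r in range(n_rec):
            dim = int(rng.integers(5, 307))
            milk = max(0.1, float(rng.normal(20, 3)))
            fat = max(0.01, float(rng.normal(0.80, 0.10)))
            protein = max(0.01, float(rng.normal(0.70, 0.08)))
            bw = bw_base + float(rng.normal(0, 8))
            dbw = float(rng.normal(0.10, 0.20))
            ecm = 0.1 * milk + 5.2 * fat + 2.6 * protein
            dmi = (7.0 + 0.32 * ecm + 0.02 * bw + 1.2 * dbw
                   + 0.25 * parity + 0.01 * dim / 30.0
                   + rfi_true[i]
                   + float(rng.normal(0.0, config.record_noise_sd)))
            rows.append({
                "animal_id": ped.animal_id, "sire_id": ped.sire_id,
                "dataset": ped.dataset, "country": ped.country,
                "birth_year": ped.birth_year, "record": r,
                "DIM": dim, "parity": parity, "age": age,
                "milk": milk, "fat": fat, "protein": protein,
                "BW": bw, "dBW": dbw, "DMI": dmi,
                "cg": cg, "hys": hys, "rfi_precomputed": np.nan,
            })
    return pd.DataFrame(rows), truth


def simulate_bundle(config: SimulationConfig | None = None, **overrides):
    """Convenience wrapper: genotypes + pedigree + records + truth in one call."""
    if config is None:
        config = SimulationConfig(**overrides)
    gm, ped = simulate_genotypes(config)
    records, truth = simulate_traits(gm, ped, config)
    return gm, ped, records, truth
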