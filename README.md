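# rfigp — genomic prediction of residual feed intake across cohorts and countries

Residual feed intake (RFI) — the difference between a cow's actual and
expected dry matter intake after adjusting for production, body size and
weight change — is a key feed-efficiency trait, and one of the most
expensive phenotypes in dairy breeding.  No single country records enough
cows for accurate genomic prediction, which raises a practical question:
how much accuracy does a breeding program gain by (a) pooling raw
phenotypes from international partners as correlated traits, versus
(b) sharing only GWAS summary statistics and genotyping a custom panel of
selected sequence variants?

`rfigp` implements the full analysis chain needed to study that question,
and a synthetic-data generator that reproduces the relevant structure of a
multi-country Holstein population (shared founder haplotypes with mild
Balding–Nichols differentiation, international AI sires, paternal half-sib
families, nested array/HD/sequence panels with causal variants kept off the
arrays, record-level intake phenotypes).  The statistical core:

- **RFI derivation** — OLS adjustment `RFI = DMI − (mean + fixed factors +
  DIM + ECM + MBW + ΔBW)` per dataset, with ECM = 0.1·milk + 5.2·fat +
  2.6·protein (kg/d), orthogonal-polynomial covariates, per-animal
  averaging and within-dataset standardisation.
- **GRMs** — Yang-method relationship matrices with the `clamp(10/n, 0.01,
  0.05)` MAF rule, variance-weighted combination `G_w = (σ²_SNP·G_SNP +
  σ²_seq·G_seq)/(σ²_SNP + σ²_seq)`, PCA, Hedrick G'_ST, neighbour-joining
  trees, and observed/HWE/GRM-predicted heterozygosities.
- **GREML/GBLUP** — uni- to tri-variate REML (`y_T = X_T b_T + Z_T g_T +
  e_T`, `g ~ N(0, G ⊗ P)`), average-information updates with an active-set
  boundary treatment, spectral fast path for single traits, delta-method
  SEs for h² and r_g, and mixed-model-equation GEBV for unphenotyped
  validation animals.
- **GWAS + meta-analysis** — EMMAX-style two-stage mixed-model scans and
  the multi-trait statistic `χ²_i = t_i' V⁻¹ t_i` over signed t-values,
  with V estimated across all scanned variants.
- **Variant selection** — imputation-R²/MAF filters and top-3-per-100-kb
  sliding-window selection (50-kb slide, p < 1e-3).
- **Evaluation** — cohort-by-birth-year and sire-family fourfold
  cross-validation; accuracy `cor(GEBV, y*)/√h²`, dispersion bias (slope of
  y* on GEBV), and fold-mean summaries with SE = SD/2.

## Layout

    src/rfigp/        library (genio, synthetic_data, phenotypes, grm,
                      mixedmodel, gwas, selection, evaluation, pipeline, cli)
    analysis/         numbered drivers: 01_simulate_data ... 06_prediction_accuracy
    tests/            pytest suite (unit, property, and acceptance tests)
    scripts/          acceptance.py (end-to-end reproduction run)
    docs/methods.md   model, study conditions, numerical choices, limitations

## Worked example

```python
from rfigp.pipeline import DataBundle, Scenario, prepare_phenotypes, run_scenario
from rfigp.synthetic_data import SimulationConfig, simulate_bundle

cfg = SimulationConfig(n_countries=6, animals_per_country=(600, 400, 400, 400, 400, 400),
                       n_heifers=0, n_chrom=12, n_sequence_variants=4500,
                       array_fraction=0.5, h2=(0.19, 0.27), pheno_sd=(1.5, 1.5),
                       genetic_correlation_matrix=((1.0, 0.95), (0.95, 1.0)), seed=7)
bundle = DataBundle(*simulate_bundle(cfg))
phenos = prepare_phenotypes(bundle)

base = run_scenario(Scenario("home_only", ("home_cow",), "univariate", "array",
                             design="random"), bundle, seed=7, phenos=phenos)
biv = run_scenario(Scenario("with_overseas", ("home_cow", "ove1", "ove2", "ove3",
                                              "ove4", "ove5"), "bivariate", "array",
                            design="random"), bundle, seed=7, phenos=phenos)
for name, res in [("home only", base), ("+ overseas", biv)]:
    rep = res["reports"]["random"]
    print(f"{name}: accuracy {rep.mean_accuracy:.3f} (SE {rep.se_accuracy:.3f}), "
          f"bias {rep.mean_bias:.2f}")
```

prints (machine-exact values depend on BLAS, the pattern does not):

    home only: accuracy 0.162 (SE 0.187), bias 0.67
    + overseas: accuracy 0.232 (SE 0.179), bias 0.58

i.e. 600 home records alone support little accuracy, while adding 2000
overseas records of a genetically correlated (r_g ≈ 0.95) trait raises it
substantially — the phenotype-sharing effect (over 10 such replicates the
mean accuracy roughly doubles; see tests/test_acceptance.py).  The numbered scripts in
`analysis/` run the same machinery over the full scenario grid (array vs
dense vs weighted GRMs, uni/bi/tri-variate, cohort and random folds) and
write tables under `results/`.

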