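# Methods

`rfigp` re-creates, end to end and on synthetic data, a genomic-prediction
workflow for residual feed intake (RFI) in dairy cattle measured across
several countries: phenotype derivation, genomic relationship matrices
(GRMs) and population-structure diagnostics, multi-trait GREML/GBLUP,
sequence-level GWAS with a multi-trait meta statistic, window-based variant
selection, weighted-GRM prediction, and cross-validated accuracy and bias.
This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## Phenotype model

RFI is the residual of dry matter intake (DMI, kg/d) after an
ordinary-least-squares adjustment for production and body size:

    RFI = DMI - (mean + fixed factors + DIM + ECM + MBW + dBW)

with energy-corrected milk ECM = 0.1*milk + 5.2*fat + 2.6*protein (all
kg/d), MBW the mean body weight, and dBW the daily body-weight change.  Two
model flavours are provided: the lactating-cow model (contemporary group +
parity as factors) and an overseas-cow model (parity x lactation-stage
classes, herd-year-season, a degree-2 orthogonal polynomial of age at
calving, optionally trial).  Orthogonal polynomial bases are the QR
construction on centred monomials (columns unit-norm, orthogonal to the
intercept); dBW can be derived from a degree-5 polynomial regression of
body weight on days in milk (difference of predicted weights on consecutive
days), which equals the orthogonal-polynomial fit because both span the
same column space.  Per-animal RFI is the mean residual over lactation
records; each dataset is standardised ((x - mean)/SD, sample SD with n-1)
before pooling, and country of origin is always a fixed effect afterwards.
Records missing any covariate are dropped before fitting; factors with a
single observed level are dropped with a warning rather than silently
producing NaN.

## Relationship matrices

GRMs use Yang et al.'s estimator: off-diagonals are means over variants of
(x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)); diagonals use the dedicated
estimator 1 + mean[(x^2 - (1+2p)x + 2p^2)/(2p(1-p))].  Allele frequencies
come from the analysed sample; missing dosages are mean-imputed (2p) at GRM
time only and never stored.  The MAF floor is clamp(10/n, 0.01, 0.05) so at
least ~20 allele copies segregate.  A `diagonal="crossproduct"` option keeps
the plain standardised cross-product on the diagonal, which makes GBLUP
exactly dual to ridge SNP-BLUP (used as an oracle in the tests).  The
weighted GRM is (v_SNP*G_SNP + v_seq*G_seq)/(v_SNP + v_seq), with the
weights the genetic variances the two component GRMs capture on the
training records; the two variances come from two separate univariate GREML
fits (a joint two-kernel REML is out of scope), and are re-estimated per
training fold, so the weights vary across validation sets as they do in
practice.

Structure diagnostics run on the common-variant (array-density) panel:
PCA of the (double-centred) GRM with scores eigenvector*sqrt(eigenvalue);
pairwise multi-locus G_ST = (H_T - H_S)/H_T via the ratio of per-variant
means, and Hedrick's standardised G'_ST = G_ST*(k-1+H_S)/((k-1)(1-H_S))
with k = 2 (both reported, the tree uses G'_ST); a hand-written Saitou-Nei
neighbour-joining tree (negative branch lengths clamped to zero with the
deficit moved to the sibling, preserving path lengths; scikit-bio's `nj`
serves as an independent oracle in the tests); and three heterozygosities
per group: observed HE_o (mean per-animal heterozygous fraction),
Hardy-Weinberg HE_oHW (mean 2p(1-p) at within-group frequencies), and
GRM-predicted HE_pr = HE_base*(1-F) with F = mean(G_jj) - 1 over the
group's GRM diagonal (the reference leaves the F definition open; the
GRM-diagonal choice keeps it marker-based and panel-consistent).

## Mixed models

The GREML model for T traits (T <= 3) stacks y_t = X_t b_t + Z_t g_t + e_t
with vec(g) ~ N(0, G kron P) and residuals R kron I; cross-trait residual
covariance exists only for animals recorded for both traits and is
estimated only when at least 30 such animals exist, otherwise it is
structurally zero (disjoint cohorts cannot identify it).  Estimation is
REML: univariate fits use the exact spectral profile likelihood over the
variance ratio (global in one dimension, Brent search at 1e-10 tolerance);
multivariate fits use average-information (AI) updates.  The AI loop adds
three safeguards: (1) an active set — parameters pinned at a bound (variance
floor 1e-8 of the phenotypic variance, correlation cap 0.999) whose score
points outward are frozen for that iteration, keeping Newton's quadratic
convergence instead of crawling along the bound; (2) Levenberg-Marquardt
damping plus step-halving under a monotone-likelihood guard (accept
tolerance 1e-9*|logL|, the numerical noise floor of re-evaluating the
likelihood); (3) if not even a ~1e-3-scale step improves the likelihood the
current point is accepted as a (possibly boundary) optimum.  Convergence
requires |dlogL| < 1e-8 and a scale-aware relative parameter change < 1e-6.
Standard errors come from the inverse AI matrix; h2 = P_tt/(P_tt + R_tt)
and rg = P_12/sqrt(P_11 P_22) get first-order delta-method SEs.  Starting
values split the phenotypic variance half genetic, half residual, with
genetic correlations at half the phenotypic correlation where an overlap
exists (0.25 otherwise).  A GRM that is numerically a scalar multiple of I
makes the split unidentifiable; the fit flags this and returns the
OLS-residual REML likelihood.

GBLUP prediction solves g_hat = Cov(g, y) V^-1 (y - X b_hat) at fixed
variance components, returning GEBV for all genotyped animals including
unphenotyped validation animals.  A boundary fit combined with an
indefinite kernel (Yang diagonals on a handful of variants need not be PSD)
can leave V non-positive-definite; prediction then clips V's spectrum at a
small positive floor.

## GWAS and meta-analysis

The scan is the standard two-stage mixed-model approximation: null variance
components by univariate REML, then per-variant generalised-least-squares
effects at fixed components, computed in the whitened eigenbasis of the
GRM (O(n) per variant after one eigendecomposition).  The polygenic term
uses the dense *marker* GRM, not the sequence panel under test — fitting the
kernel from the panel being scanned absorbs the causal signal (proximal
contamination) and measurably halves power at this scale.  Wald p-values
use a t reference with n - rank(X) - 1 df; fixed effects are intercept +
dataset.  Variants need MAF > 0.01 in the analysed animals; zero genotypic
variance after whitening yields a reason-coded skip, not a silent NaN.

The multi-trait statistic for variant i is chi2_i = t_i' V^-1 t_i with t_i
the per-trait signed t-values and V their correlation matrix estimated over
ALL scanned variants (not only significant ones); df = number of traits.
Nearly collinear t-vectors (|r| >= 0.999) get a 1e-6 ridge with a warning.

## Variant selection

Sequence variants are dropped when the imputation-quality score is <= 0.4
in BOTH named datasets, or when the discovery-set MAF is <= 0.006 (both
bounds strict).  Selection walks half-open 100-kb windows sliding by 50 kb,
anchored at position 0 of each chromosome, keeping at most the three
variants with p < 1e-3 per window; ties in p break by larger |t| then lower
position, so selection is deterministic and order-invariant.  Window
nominations are deduplicated; the union sets (single-trait RFI, single-trait
DMI, multi-trait, and their combination) drop variants already on the array
panel before entering a weighted GRM.

## Cross-validation and metrics

Only the home lactating-cow cohort is validated.  Cohort folds split by
birth year with small trailing years merged (threshold: each fold at least
15% of eligible animals, and merging continues until exactly four folds);
random folds shuffle sires by seed and deal whole paternal half-sib
families greedily to the smallest fold, with unknown-sire animals kept in
training only.  For each fold, the training records are everything minus
the fold's home cows; fixed effects for the corrected phenotype y* and the
accuracy-denominator h2 (array GRM, home training records) are estimated on
training data only.  Accuracy is cor(GEBV, y*)/sqrt(h2); the denominator
uses the mean of the four training-fold h2 estimates, floored at 0.05 —
per-fold denominators occasionally collapse toward zero on a few hundred
records and would explode the ratio.  Bias is the regression slope of y* on
GEBV (1 = no dispersion inflation).  Fold summaries report mean accuracy
with SE = SD(four accuracies)/2, flagged approximate because training sets
overlap.  Multivariate variance components are estimated once per scenario
from the full record set and treated as known in each fold's mixed-model
equations (validation phenotypes are always masked for prediction);
refitting per fold is available but not the default at this scale.
Weighted-GRM scenarios re-estimate the component weights per fold as
described above.

## Synthetic study conditions

The generator emulates one breed measured in seven countries.  Key
mechanisms and defaults:

- **Genome**: 12 chromosomes of 10 Mb, 6000 sequence variants, founder
  allele frequencies Beta(0.4, 0.4) truncated at 0.01.  LD and relatedness
  come from a founder-haplotype mosaic copying model (150 global founder
  haplotypes, ~1 crossover per chromosome per gamete).
- **Countries**: one global founder pool with country-specific Dirichlet
  founder-usage weights of total concentration (1-F)/F.  By Dirichlet
  aggregation the per-country allele frequency is exactly Balding-Nichols
  Beta(A p, A(1-p)) drift with parameter F (default 0.01), while haplotypes
  stay shared across countries — a single breed with mild differentiation.
- **Pedigree**: 40 sires per country plus 25 international AI sires used
  for half of all matings (multi-country Holstein breeding uses the same
  elite bulls worldwide); offspring are sire-gamete x population-gamete;
  10% unknown sires; birth years 2013-2017 with small 2016/2017 shares so
  the cohort-fold merge rule is exercised.
- **Panels**: array = 50% of common (MAF >= 0.05) variants; hd = every
  variant above MAF 0.01; causal variants are excluded from both marker
  panels by default (they exist only in the sequence tier); per-variant
  imputation-quality scores are drawn so ~60% clear the 0.4 threshold.
  The array density is chosen so both marker tiers sit in the regime where
  kinship precision is saturated — the regime in which array and dense
  panels give equivalent prediction accuracy, as dense real arrays do; a
  much sparser desk-scale array is below saturation and systematically
  trails the dense tier.
- **Trait architecture**: 1000 causal variants with per-allele effects
  scaled by 1/sqrt(2pq) (equal expected variance per locus), of which 20
  loci carry 45% of the genetic variance.  A disjoint set of 300
  body-weight QTL (genetic SD 35 kg) feeds dry matter intake through the
  body-weight term, so the intake deviation carries production genetics
  that the RFI adjustment removes — this gives the intake scan signal that
  is complementary to the RFI scan, as in real data.  Effect vectors across the three
  cohort traits are multivariate normal with the configured genetic
  correlations (defaults 0.95 home-overseas, 0.34 home-heifer, 0.25
  heifer-overseas); the 20 large loci keep their MVN orientation but have
  fixed magnitude, because chi-squared magnitude draws would leave half of
  the nominally detectable loci with no realized effect in any one
  replicate.  True breeding values are rescaled so the realized
  within-cohort heritability is exact (defaults 0.19 home cows, 0.27
  overseas, 0.36 heifers), and environmental deviations are orthogonalised
  against them.
- **Records**: cow phenotypes are built bottom-up — milk/fat/protein, body
  weight and weight change per lactation record, DMI as a linear function
  of ECM, body weight and weight change plus the animal's genetic RFI
  deviation and record noise (SD 0.3 kg/d) — so the phenotype-derivation
  stage faces a genuine, unbiased recovery problem.  RFI phenotypic SD is
  1.5 kg/d for cows (within the 1.17-3.04 range reported for such
  populations) and 0.45 for heifers.  Heifers carry a pre-derived trait
  deviation, as heifer RFI typically arrives already adjusted.

What the generator does **not** emulate: lactation-curve biology (weight
trajectories are noise around a base weight; the record-level dBW is
emitted directly rather than re-derived from daily weights),
genotype-by-environment interaction, per-chip marker sets, allelic
(as opposed to identity-by-descent) linkage disequilibrium at long range,
and real imputation error (quality scores are labels for the filter, not
noise actually added to genotypes).  Consequently, passing tests show the
*estimators and the pipeline logic* behave correctly under the assumed
model at desk scale; they do not certify accuracy levels on real cattle
data.

## Problem sizes and calibration checks

All tests and the acceptance script regenerate data at fixed seeds.  The
heavier checks use: heritability recovery at n = 1500 and 4000 variants
over 10 seeds; genetic-correlation recovery with disjoint 600 + 2000
cohorts over 10 seeds; information-sharing comparisons with a 600-cow home
cohort plus 2000-2500 overseas cows over 10 replicates (4-fold sire-family
validation); a 20k-variant null for the meta-statistic calibration; and the
default 7-country bundle (~3100 animals, 6000 variants) for the structure
diagnostics, the array-vs-dense equivalence, and the acceptance script.
These sizes were chosen as the smallest at which the qualitative patterns
of interest (near-doubling of accuracy from sharing phenotypes; smaller but
consistent gains from sharing selected variants; array/dense equivalence)
are statistically stable.

## Known limitations

- The AI-REML correlation cap (0.999) means genetic correlations estimated
  at the boundary report 0.999 rather than a proper constrained estimate;
  SEs there come from the curvature of the free parameters only.
- The two-stage GWAS does not refit variance components per variant; at
  very large per-variant effects the test is slightly conservative.
- Weighted-GRM weights from two separate univariate fits double-count
  shared variance; with a near-causal selected set this is conservative
  toward the array component.
- The sliding-window selection can return very small sets at desk scale
  (tens of variants, versus thousands in a full-genome study); the weighted
  GRM built from them is low-rank, and prediction guards against the
  resulting indefinite V.  The weighted-GRM comparisons therefore use a
  denser sequence tier (16k variants) and a more oligogenic architecture
  (24 loci, 55% of genetic variance) than the default bundle, with a
  1200-cow home cohort, so the effect is resolvable against fold noise.
- With a strong correlation between the two traits' signed-t vectors
  (~0.7-0.8 here, because the intake deviation contains the whole RFI
  deviation), the multi-trait statistic t'V^-1 t requires a larger signal
  for concordant (pleiotropic) loci than a single-trait scan at the same
  tail probability, and preferentially admits trait-discordant loci.  At
  desk scale this can make the multi-trait selection predict *worse* than
  the single-trait union, so the expected multi-trait advantage need not
  materialise here (see the acceptance test docstring).
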