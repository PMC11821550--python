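# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter for
reproducibility.

## Association model

The unit of testing is the *genotype indicator*: for a biallelic SNP,
three binary variables mark whether a sample is hom-ref, het, or hom-alt
(a missing call is missing in all three; for every called sample exactly
one indicator is 1). For indicator y, environmental variable e and
structure covariates k, two nested logistic regressions are fitted by
Newton–Raphson/IRLS on the identical sample subset (rows with missing
y, e or k dropped pairwise):

    null:  logit P(y=1) = b0 + c'k
    full:  logit P(y=1) = b0 + b1·z(e) + c'k

with z(e) standardized over the used samples — b1 is therefore "per SD of
environment" and comparable across variables; the raw-scale coefficient
is reported alongside. The G score 2(LL_full − LL_null) and Wald score
b1²/Var(b1) are referred to chi-square with 1 df. Significance requires
both q(p_G) < 0.05 (Storey q-values over all records of a run) and
p_W < 0.05; the dual rule guards against the two scores' different
finite-sample failure modes.

Numerical choices: convergence at max |Δβ| < 1e-8 within 50 iterations;
fitted probabilities clipped at 1e-12; covariance from the inverse
observed information. Quasi-complete separation is declared when any
coefficient passes 15 in absolute value on standardized predictors (an
odds ratio beyond e¹⁵ on this scale is not a finite MLE); separated,
constant-response and non-converged fits carry status flags and are never
reported significant. The null fit is cached per missingness pattern, so
a 19-variable scan costs one null fit per indicator.

q-values: π₀ is estimated by the median of #{p > λ}/(m(1 − λ)) over
λ ∈ {0.05, …, 0.95}, capped at 1 (the median variant of the usual
smoother; it is robust and has no tuning parameter), then
q(p₍ᵢ₎) = min_{j≥i} π₀·m·p₍ⱼ₎/j. With π₀ = 1 this is exactly
Benjamini–Hochberg. Pooling across variables is the default; per-variable
pooling is available (`q_mode="per_variable"`) since either convention is
defensible for a multi-variable run.

## Structure correction

PCA of the dosage matrix with allele-frequency scaling: each SNP column
is centered by 2p̂ and divided by sqrt(2p̂(1−p̂)), missing entries
mean-imputed, p̂ estimated from called genotypes. This "Patterson"
scaling matches SNP-PCA convention; a `scaling="unit"` mode (empirical
SD) is provided, under which the total variance equals the number of
retained SNPs exactly. Variance proportions are reported relative to the
standardized matrix's total variance. Component signs are fixed by
forcing the largest-magnitude loading positive so downstream regressions
are bit-reproducible. The default is one covariate (k=1); `suggest_k`
implements the eigenvalue-ratio knee (profile 0.075/0.019/0.012 → k=1),
off by default.

## HDplot

Per locus, reads over heterozygous samples are pooled: a = Σ ref reads,
b = Σ alt reads, ratio = a/(a+b), D = (a−b)/√(a+b) — the normal
approximation to the z-score of a Binomial(a+b, ½) count, with no
continuity correction (matching the method's plotted scale). H is the
het proportion among called samples. The keep rule is |D| ≤ d_max
(default 7, boundary inclusive); an optional H ceiling is exposed but
off by default, since only the D rule is universally used. Loci with no
heterozygote reads have undefined D and are retained (no evidence is not
evidence of paralogy) and logged.

## Spatial autocorrelation

Weights: k = 20 nearest neighbours by haversine distance on lon/lat
(adequate at sub-continental scale; no projection dependency),
row-standardized to 1/k, ties broken by sample order so neighbour sets
are deterministic. Global I = (n/S₀)·Σᵢⱼ wᵢⱼzᵢzⱼ/Σzᵢ²; local
Iᵢ = n·zᵢ·(Wz)ᵢ/Σz², which sums to n·I under row standardization.
Pseudo p = (exceedances + 1)/(n_perm + 1), one-sided in the observed
direction by default (two-sided available), n_perm = 999 by default so
the smallest attainable p is 0.001. Local permutation is conditional:
zᵢ is held fixed and its k neighbour values are drawn without
replacement from the other n−1 observations. Binary genotype indicators
are analyzed as numeric 0/1 vectors.

## Annotation, enrichment, reduction

GFF3 gene/exon/UTR features are indexed per sequence (1-based inclusive
converted to 0-based half-open internally); sub-features attach to genes
by their Parent attribute, falling back to span containment. A SNP in a
gene is classified with precedence UTR > exon > intron — a UTR is
sub-exonic, so this reproduces the three-way exon/intron/UTR accounting;
a SNP overlapping several genes yields one hit per gene.

Enrichment: annotations are propagated to all is_a/part_of ancestors
(true-path rule; part_of treated as ancestry, toggleable), the
background N counts genes with ≥1 propagated annotation in the tested
namespace (reference-set semantics), and each term present in the
cluster is scored by the upper hypergeometric tail P(X ≥ k). Raw
p < 0.05 is the significance gate; BH-adjusted values are reported
alongside. Genes hit by several SNPs can be expanded one-entry-per-SNP
(suffixes gene_1, gene_2, …, background expanded identically) or counted
once (`mode="single"`).

Semantic reduction: IC(t) = −ln p(t) with p(t) the corpus fraction
annotated to t (via the closure) relative to the namespace root; the log
base cancels in SimRel's ratio and the (1 − p) factor uses the
probability directly, so the choice of natural log does not affect
output. Terms are visited in ascending enrichment p; each joins the
earliest representative with SimRel ≥ C (default 0.7, the "medium"
convention), recording that similarity as its dispensability, else
founds a cluster. This greedy variant is documented as such — the
reference tool's exact representative heuristic is not published, and no
equivalence is claimed.

## Synthetic data generator

The generator emulates the features the analysis chain assumes, at the
benchmark scale of 240 samples × 2000 SNPs × 19 variables:

- **Landscape & structure.** Samples uniform on a lon/lat rectangle;
  admixture q = expit((lon − 130)/8), a logistic hybrid-zone cline.
  Population frequencies are Balding–Nichols,
  Beta(p(1−F)/F, (1−p)(1−F)/F) around p_anc ~ U(0.05, 0.95), with
  F = 0.15 by default — enough divergence that PC1 carries a clearly
  dominant share of variance (~0.07 at this scale), as expected for two
  closely related species.
- **Environment.** 19 variables in 4 blocks sharing latent factors;
  within-block correlation is rho = 0.8 in expectation (affine copies at
  rho = 1). The winter-block factor decreases with longitude and the
  second block with latitude, each carrying `env_gradient_strength`
  = 0.4 of the factor variance. This partial coupling is deliberate:
  climate must track geography enough to confound an uncorrected test,
  yet a structure-corrected model must retain an identifiable signal —
  full collinearity with the ancestry cline would make planted effects
  unrecoverable by construction, which is not how climate and ancestry
  relate on a real landscape (climate also varies with latitude,
  elevation and continentality).
- **Planted effects.** 5% of loci are adaptive: the carrier probability
  P(dosage ≥ 1) follows expit(β₀ + β₁·z_env) with β₀ matching the
  locus' baseline carrier frequency and recorded β₁ (default magnitude
  U(0.5, 1.5), random sign); carriers split het/hom-alt by the
  Hardy–Weinberg conditional odds, so the hom-ref indicator obeys an
  exact logistic model with coefficient −β₁ on the scale the engine
  estimates. Adaptive p_anc is drawn U(0.15, 0.5): effects load on minor
  alleles at MAF-viable frequencies, keeping the carrier class
  informative rather than saturated.
- **Reads.** Depth ~ Poisson(40); het alt reads Binomial(depth, ½);
  homozygotes single-allele. 5% of loci are merged paralogs: reads of an
  independent hidden locus are added and the genotype re-called from the
  pooled signal (mixed evidence → het), producing the excess apparent
  heterozygosity and skewed pooled ratios the HDplot screen targets.
  Zero-depth calls are missing; additional calls are set missing
  completely at random at rate 0.10.
- **Determinism.** One integer seed; each stage draws from a
  deterministically derived sub-stream, and fixture files are
  byte-identical across runs.

What the generator does **not** emulate: linkage disequilibrium between
loci, coalescent genealogies, selection dynamics over generations,
non-random missingness, depth variation between libraries, or
measurement error in the environmental variables. Passing tests
therefore demonstrate that the inference chain is correctly calibrated
and powered under its own assumptions — not that those assumptions hold
for any particular field dataset.

Synthetic annotation resources (2 kb exonic gene models tiling the
simulated chromosomes, a 20-term biological-process ontology, and a
gene→term table in which genes harboring adaptive SNPs share specific
transport/homeostasis terms) exercise the annotation, enrichment and
reduction stages with a planted overrepresentation; they are labelled
synthetic throughout.

## Variable grouping and sign classification

Variable grouping uses average-linkage clustering on 1 − |r| with
correlations failing the significance gate (p ≥ 0.01) zeroed; because
average linkage does not guarantee a pairwise bound, groups from the cut
at 1 − 0.6 are recursively split at their top merge until every group's
weakest pair has |r| > 0.6. An indicator significant for several
variables of a set is assigned the β₁ sign of its most significant
(lowest q_G) association, ties broken by larger |β₁| and logged; the
median allele frequency of a sign group uses the composing allele for
homozygote indicators and the minor allele for het indicators. The
default winter/summer six-variable sets (Bio6/9/11/14/17/19 and
Bio5/8/10/13/16/18) and the four-variable winter core (Bio6, Bio11,
Bio14, Bio17) are this package's configuration defaults for bioclim
inputs, not a claim about any particular dataset; the simulated winter
block is Bio1–Bio5.

## Problem sizes

Defaults are sized so the full test suite runs in well under a minute of
pure computation per heavy test: calibration loops use 2000 null fits at
n=200 and 100 power replicates at n=240; recovery and HDplot
distribution checks use 500-locus panels; the acceptance script runs the
complete 2000-locus chain with 999-permutation Moran tests on 50
vectors. These sizes give binomial standard errors small enough for the
stated tolerances (e.g. ±3·SE ≈ ±0.015 on the type-I rate).

## Known limitations

- The logistic engine detects separation by coefficient magnitude, not
  by certificate; pathological near-separated fits may converge with
  large but sub-threshold coefficients and wide variances (they are then
  rarely significant, which is the safe direction).
- Storey's median-of-λ π₀ is slightly conservative under strong signal
  fractions; q-values then lean toward BH.
- The local Moran permutation loop is O(n · n_perm · n); at the default
  scale this is seconds, but very large panels should reduce n_perm.
- The greedy SimRel reduction depends on the input ordering rule
  (ascending p, ties by term id); it is deterministic but not claimed
  optimal.
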