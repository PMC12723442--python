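# Methods

## Scope and model

`gestaltqtl` implements a desk-scale pipeline for mapping quantitative trait
loci (QTLs) of cuticular-hydrocarbon (CHC) nestmate-recognition cues in a
monogyne, polyandrous ant population, at two analysis levels:

* **individual level** — each genotyped worker with its own (or its
  colony's) trait value;
* **colony level** — the colony treated as a single polyploid entity, with
  genotype = mean allele dosage of the sampled nestmates (twice the colony
  allele frequency) and phenotype = mean nestmate CHC profile.

The association model is the standard mixed linear model

    y = X beta + u + eps,   u ~ N(0, sigma_g^2 K),   eps ~ N(0, sigma_e^2 I)

with fixed effects X (intercept, population-structure principal components,
optional cofactor SNPs and the tested locus) and a kinship random effect.
Restricted maximum likelihood is computed the EMMA way: K is eigendecomposed
once, the likelihood becomes one-dimensional in the variance ratio
delta = sigma_e^2 / sigma_g^2, and delta is maximized on a dense log10 grid
over [-5, 5] (100 points) followed by bounded local refinement in the best
bracket. The fit is deterministic. Because only the ratio matters, the
kinship matrix is used up to an arbitrary positive scalar; the per-SNP scan
p-values are invariant to rescaling K (property-tested).

The scan defaults to **P3D**: variance components are estimated once under
the null model and reused for every locus, so each locus costs one
generalized-least-squares t-test (df = n − rank(X) − 1, two-sided) in the
whitened eigenbasis. Exact per-locus REML is available behind
`p3d=False`. Missing dosages are handled by exact per-locus sample dropping
(each affected locus gets its own small GLS fit with the null variance
ratio) or, behind a flag and always inside permutation reruns, by per-locus
mean imputation.

**MLMM** adds forward–backward stepwise cofactor selection: the most
significant locus is added as a fixed cofactor while its
Bonferroni-corrected p-value is below the entry threshold (default 0.05),
then cofactors whose corrected p-value in the joint model exceeds the
threshold are dropped, worst first. Ties break deterministically on the
lowest (chromosome, bp). The reported per-locus statistics are conditional
on the retained cofactors.

**Permutation calibration** shuffles trait values among the rows of the
analysis (individuals at individual level, colonies at colony level),
keeping X, K and G fixed, and rescans; variance components are re-estimated
per permutation. Empirical p-values use the pooled null ECDF with the
add-one rule p_emp = (1 + #{null ≤ p}) / (1 + N), which is monotone and
never zero. The per-permutation genome-wide minimum p-value also yields a
family-wise 5% threshold (its 5%-quantile), the standard permutation
correction for a linked marker panel. Benjamini–Hochberg q-values are
computed per trait across loci by the usual step-up (hand-implemented,
cross-checked against statsmodels).

## Synthetic data generator

Each colony is founded by one diploid queen and k haploid males, k drawn
uniformly from 2–10 (polyandry as observed in the study system; a Dirichlet
concentration parameter allows unequal paternity shares, since effective
paternity in the field is below the equal-shares expectation). Founders are
unrelated, with per-locus ALT frequency such that the minor-allele frequency
is uniform on (0.05, 0.5]. Workers receive one recombinant queen gamete —
Haldane model, r = (1 − e^(−2d/100))/2 for d cM, no interference, the
minimal standard choice — and one intact paternal haplotype. Founder-origin
labels ride along with every allele, so realized identity-by-descent is
exact; mean nestmate relatedness reproduces the haplodiploid expectation
r = 0.25 + 0.5/k within Monte-Carlo error (tested).

The genetic map places loci uniformly on each linkage group at 1 cM per
20 kb. Defaults are 27 linkage groups of 75 cM (linkage groups of insects
typically span 50–100 cM) and a 2,000-marker desk-scale panel; the study's
~1.7×10^5-SNP catalog is reachable by raising `n_loci`.

Traits are built per trait from `qtl_per_trait` QTLs drawn among loci with
realized MAF ≥ 0.1, each rescaled against the realized dosage variance so
that it explains exactly `pev` of the phenotypic variance; a colony-level
environmental effect (`colony_env_var`) and individual noise fill the rest.
Gestalt mixing replaces each worker's value v_i by
(1 − m)·v_i + m·(colony mean); m = 1 is the full shared-colony-odor limit,
in which within-colony variance is exactly zero (tested). `pev_scale`
chooses whether PEV is calibrated before mixing ("individual") or on the
observed post-mixing phenotype ("observed"); with m = 1 the latter makes
PEV the colony-level variance fraction. The compositional flag interprets
values as log-abundances and renormalizes each sample's trait vector to sum
to one; it is off for power runs (each CHC is analyzed separately after
normalization) and intended for end-to-end realism fixtures. Per-call read
depths are negative binomial with mean 12 (the study's mean genome
coverage) so depth filters are exercisable. Fixtures are bit-identical
under a fixed seed.

What the generator does **not** emulate: sequencing reads, alignment and
genotype-calling error processes (beyond missingness and depth), LD in the
founder population (founder loci are independent; LD arises only from
family co-segregation), diet/symbiont CHC sources (lumped into
environmental noise), and worker task/size structure in CHC contribution.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model, not robustness to genotyping
error or phasing error on real data.

## Filtering cascade

The cascade order is fixed (the narrative it mirrors is not fully
algorithmic, so the order is a package decision): biallelic SNPs only →
first sample-missingness pass (50%) → blacklist of ±600 bp around loci
where a haploid male is called heterozygous (collapsed-repeat artifacts;
intervals inclusive on both ends, merged, removal idempotent) → per-call
depth masking to [6, 250] reads, then call rate ≥ 80% and MAF ≥ 15%
computed from surviving calls (strict reading: depth masking precedes the
rate/frequency computations) → excess-coverage filter (per-locus mean depth
over called samples > mean + 2 SD, or an explicit cutoff such as the
study's 20×) → second sample-missingness pass (60%). Colony-level
genotypes require ≥ 3 called members in every colony and are the mean
called dosage. Dosage counts ALT alleles (stable coding, independent of
frequency); coordinates are 1-based throughout. A FilterReport reconciles
counts at every stage.

## Phenotypes

Peak areas → relative amounts by row normalization; per-trait outliers
removed by Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR (the conventional rule
the study's phrasing paraphrases), quartiles by linear interpolation
(type 7); zero-IQR traits are left untouched with a warning. Each trait is
then normalized by the best of {identity, log(x+c), sqrt, arcsinh, Box-Cox
(positive data only), Yeo-Johnson, ordered quantile}, judged by a Pearson
chi-squared normality statistic on standardized values (equal-probability
normal bins, ⌈n/5⌉ bins capped at 30) — the bestNormalize selection rule;
ties resolve by candidate order with identity first, and the ordered
quantile transform maps ranks to exact normal quantiles. Colony profiles
are the arithmetic means of raw relative amounts over nestmates;
outlier removal and normalization are then applied to the colony vectors,
so the two analysis levels each get their own normalization. Trait-space
PCA (mean-imputed, centered; standardization optional — whether the study
standardized first is unstated, so it is a flag) returns all components
explaining ≥ 4% of variance, with an optional floor of one component.

## Kinship

The primary definition is the total map length (cM) of shared
identity-by-descent haplotype segments per sample pair, found by an
exact-match maximal-run scan on phased haplotypes with a 1 cM minimum
segment length. This keeps the study's kinship definition while avoiding an
error-tolerant HMM phasing stack, which is out of scope; the scan is exact
on error-free (simulated or externally phased) haplotypes but counts some
identity-by-state runs as IBD on dense identical stretches — acceptable at
desk scale and bounded in tests. The diagonal is 2× the total map length;
the scaled variant divides by total map length (clones and self score 2,
full sisters ≈ 1.5). The matrix enters the mixed model only up to a
scalar, so no further normalization is applied. Fallbacks: a VanRaden
genomic relationship matrix Z Z' / Σ 2f(1−f) from mean-imputed dosages
(individual or colony level), an externally computed kinship TSV, and the
expected pedigree relatedness matrix (1 / 0.75 / 0.25 / 0) for simulated
designs. Structure covariates are the top principal components of the
dosage matrix (deterministic full-SVD solver).

## Power analysis

The pilot power question is the probability of detecting a QTL for a
*colony-level* trait. The power module therefore simulates, per replicate:
47 colonies × 6 workers, queens mated to 2–10 males, one biallelic QTL on
a fully mixed (Gestalt) trait whose observed-level PEV is exactly 0.23 or
0.52, everything else environmental noise; an individual-level mixed-model
scan with pedigree kinship over a 2,000-marker panel; and detection when
the causal locus's p-value falls at or below the genome-wide 5% threshold
from 100 trait permutations (5%-quantile of the permuted minimum p). The
permutation threshold is what makes the correction "genome-wide
equivalent" at a reduced marker count: it adapts to the panel's effective
number of independent tests rather than assuming independence. Replicates:
120 in the acceptance script, 100 at a 1,000-marker panel in the test
suite (the panel size is a desk-scale choice; the threshold adapts).

A structural caveat, recorded here because it bounds what the power tests
can show: with PEV calibrated exactly per replicate, the noncentrality of
the detection test roughly doubles between PEV 0.23 and PEV 0.52, so any
single corrected threshold that puts the low-PEV power near one-third
forces the high-PEV power near one. A simulation of this family therefore
cannot land on an arbitrary pair of reference detection probabilities at
both effect sizes simultaneously; the measured pair should be read as the
design's power under this generative model and detection rule.

## Numerical choices and degenerate inputs

* Kinship eigenvalues in [−1e−6·max, 0) are clipped to zero; more negative
  raises. Collinear fixed-effect columns are dropped by pivoted QR.
* Under K = I the variance split is unidentifiable; the fit flags delta at
  a grid boundary and the scan reduces exactly to OLS (tested to 1e−6).
* Zero residual after fixed effects flags the boundary with a warning.
* Monomorphic loci get NaN p-values flagged `monomorphic`; loci collinear
  with covariates are flagged `collinear` (in MLMM, a duplicated QTL enters
  once and its copy is flagged).
* BH is applied per trait across loci; missing p-values are excluded and
  reinserted as missing.
* The KS uniformity test of QTL positions rescales positions to cumulative
  genome-wide cM; its D statistic lies in [0, 1] by construction.
* Gene assignment windows are strand-aware and inclusive:
  [start − 2000, start − 1] on the plus strand, mirrored on the minus
  strand; the "start codon" is approximated by the gene start when no CDS
  is annotated. Cluster gap presets are 10 and 12 cM.
* All randomness flows through numpy Generators seeded from explicit seeds
  or spawned SeedSequences; reruns with one config and seed are
  bit-identical (PCA uses the deterministic full-SVD path).

## Known limitations

* The exact-match IBD scan requires error-free phased haplotypes; real
  data should supply an externally computed kinship matrix.
* The permutation scheme destroys colony structure by design; when the
  trait itself is strongly colony-structured, the shuffled null is a
  different distribution from the observed scan's null, and empirical
  p-values inherit that (the calibration tests use an exchangeable null,
  where the permutation guarantee holds exactly).
* The mixed model represents within-colony covariance only through
  kinship; a colony environmental effect beyond kinship is not a separate
  variance component (single-kinship EMMA), which slightly inflates
  within-colony correlation mismatch for fully shared traits.
* Colony-level kinship from colony mean dosages (GRM) is a documented
  deviation from deeper per-colony sequencing routes.
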