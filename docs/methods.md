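# Methods

`soyepi` implements the analysis chain used to dissect days-to-flowering
(DTF) in a large, highly inbred soybean cultivar panel: population-structure
diagnostics, a compressed mixed-linear-model (CMLM) genome-wide association
scan, biologically filtered construction of an epistasis candidate marker
set, and a Bayesian multilocus interaction search verified by two-locus
regression.  This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not demonstrate.

## Population-structure statistics (`popstruct`)

**Identity-by-state.** IBS(i,j) is the mean over markers of
`(2 − |g_i − g_j|)/2` on alternate-allele dosages `g ∈ {0,1,2}`, i.e. the
average fraction of shared alleles.  `1 − IBS` is the normalized Manhattan
distance on dosages and feeds the tree construction.

**Kimura two-parameter distance.** Pairs are compared only at sites where
*both* samples are homozygous, each call treated as a haploid base.  This is
an interpretation choice: the panel is ~97% homozygous, and restricting to
homozygous sites avoids the ambiguity of classifying a heterozygote as a
transition or transversion.  With transition and transversion difference
fractions P and Q over the compared sites,

    d = −(1/2) · ln((1 − 2P − Q) · sqrt(1 − 2Q)).

Saturated pairs (log argument ≤ 0) are capped at a configurable maximum
(default 5 substitutions/site) and flagged with a warning.

**Principal coordinates.** Classical metric MDS: double-center `−D²/2`,
eigendecompose, scale eigenvectors by the square root of the non-negative
eigenvalues.  Whether the original analysis decomposed raw or squared
distances is unknowable from the outputs; classical MDS (squared,
double-centered) is the standard reading and reproduces all pairwise
distances exactly when D is Euclidean — a property the tests exploit.

**BIONJ.** Variance-weighted neighbor joining: the usual NJ selection
criterion, with the reduced distance to a merged node taken as the
variance-optimal convex combination `λ d_ik + (1−λ) d_jk − λ l_i − (1−λ) l_j`
and the variance matrix updated as `λ v_ik + (1−λ) v_jk − λ(1−λ) v_ij`.
Variances are initialized to the distances.  On additive distances the
algorithm recovers the generating tree exactly (topology and branch
lengths), which is the primary correctness oracle.  Negative branch lengths
are clamped to zero with the deficit moved to the sister edge (toggleable).

**LD decay.** r² is the squared Pearson correlation of dosage vectors
(composite genotype r², not haplotype r² — phase is not available without
imputation/phasing, which is out of scope).  All intra-chromosomal pairs up
to 500 kb are binned by distance (10 kb bins); pair-weighted means within
100 kb and 500 kb are reported alongside the curve.  Pairs with a
monomorphic member are skipped and counted.

**Nucleotide diversity.** Per segregating site
`π = c_ref · c_alt / C(2n, 2)`; window values are site sums divided by the
window length in bp.  Windows are 1-based closed, start at position 1,
slide by the step (defaults 100 kb / 10 kb); trailing truncated windows are
emitted flagged and normalized by their actual length.

**Inbreeding F.** Method of moments per sample:
`F = (O_hom − E_hom)/(L − E_hom)` with
`E_hom = Σ_sites [1 − 2p(1−p) · 2n/(2n−1)]` using sample allele frequencies
with the small-sample correction (the convention of the common VCF
toolchain).  Degenerate denominators yield NaN.

**Fst.** Weir & Cockerham (1984) variance components a, b, c per site for
two groups; windowed and genome-wide values are ratios of summed components
`Σa / Σ(a+b+c)`, never means of per-site ratios.  Sites monomorphic in the
combined sample are skipped.  Per-site components can be negative; the
genome-wide value is reported as computed.

## Mixed-model association (`gwas`)

The scan fits

    y = μ + PCs·γ + g·β + u + e,    u ~ N(0, σ_g² K),  e ~ N(0, σ_e² I)

with K the VanRaden genomic relationship matrix (centered dosage
cross-product scaled by `2 Σ p(1−p)`).  Variance components are estimated
once by REML under the null model on the spectral decomposition of K, then
held fixed for every marker test (the P3D approximation used by the
standard CMLM tooling); each marker is then tested by generalized least
squares with a Wald t test.  An exact mode re-estimates the variance
components per marker behind a flag.  Defaults: 3 principal-component
covariates (taken from the kinship eigenvectors — the panel displays three
informative axes), compression off.

Compression clusters samples by average linkage on the kinship-induced
distance `K_ii + K_jj − 2K_ij` and replaces K by the between-cluster mean
kinship; with as many groups as samples this reproduces the uncompressed
model exactly (tested to 1e−9), which pins the implementation down.

Markers with MAF ≤ 0.05 are excluded before testing (strict inequality, per
the panel's filtering convention).  The genome-wide Bonferroni threshold is
`−log10(α/m)`; at m = 78,427 and α = 0.05 this is 6.2 (one decimal), and
significance calls use the stricter adopted cut-off `−log10 p > 7`.
Significant markers inside annotated gene intervals (1-based closed
containment; a marker in overlapping genes counts for all of them) form the
genic subset that enters the epistasis candidate set.

## Candidate marker set (`markerset`)

Homology hits (BLAST tabular) against a curated trait-related gene list are
kept when identity > 80% *and* alignment length > 70 (strict inequalities,
configurable to ≥ for sensitivity analyses), deduplicated per (query,
subject) keeping the best e-value.  The alignment-length unit is taken at
face value in bp even though translated-sequence alignments report residue
columns — a documented discrepancy of the upstream convention.  Retained
subject genes are mapped to on-array markers by interval containment; the
final candidate set is the id-based union of homology-derived markers and
GWAS-significant genic markers, with per-marker provenance and a counts
table whose "related" row excludes the overlap (reported separately) and
whose total row is the union — the inclusion–exclusion identity
`|A ∪ B| = |A| + |B| − |A ∩ B|` is asserted for every constructed set.

## Bayesian multilocus interaction search (`epistasis`)

Candidate markers are partitioned into:

* a **phenotype-associated block** (I = 1) whose joint genotype defines the
  cells over which the trait is modeled,
* zero or more **genotype-dependency blocks** (I = h ≥ 2) capturing
  inter-marker dependence (e.g. LD or structure),
* an **independent background** (I = 0).

The score of a partition is the log marginal likelihood

    P(Y | X_{I=1}) · Π_h P(X_{I=h} | I)

with every block's joint genotype counts integrated against a symmetric
Dirichlet prior (concentration 1.0 per joint-genotype cell), background
markers contributing their single-marker terms.  The product over blocks
includes the associated block, so every marker's genotype is always modeled
and scores are comparable across partitions.  The printed form of this
factorization in the source literature is internally inconsistent
(duplicated conditioning, overloaded product index); the implementation
follows the factored structure above and documents that reading.

The Dirichlet-multinomial marginal is for the *ordered* sample (no
multinomial coefficient); enumeration tests verify it sums to 1 over all
ordered outcome sequences.

**Phenotype likelihood.** DTF is continuous, so `P(Y | X_{I=1})` is a
conjugate Normal-Inverse-Gamma model per joint-genotype cell with defaults
μ0 = sample mean, κ0 = 1, α0 = 2, β0 = sample variance (an empirical-Bayes
scaling that makes the marginal invariant in spirit to trait units).  Empty
cells contribute marginal 1.  A discretized mode (quantile bins scored with
the same Dirichlet-multinomial machinery) is provided for categorical
traits; whether the original analysis discretized the trait is unknown, so
both modes exist and the continuous one is the default.

**Sampler.** Metropolis–Hastings over partitions with three moves: relocate
a marker (to background, the associated block, an existing dependency
block, or a new pair with a background marker), and swap two markers
between blocks.  A dependency block of one marker is indistinguishable from
background, so the state space contains only blocks of ≥ 2 markers and a
relocation that strands a partner dissolves the block.  Pair formation and
pair dissolution each have two generating proposals; the Hastings ratio
accounts for this and for the changing destination counts.  Correctness is
tested two ways: on 3 markers the empirical state frequencies match the
exactly enumerated posterior within 2% total variation over 200,000
retained samples, and on 6 markers the most-visited associated block equals
the enumerated score maximum.

The posterior probability of a marker set is the fraction of retained
(post burn-in) samples in which exactly that set forms a block, tracked
separately for the phenotype-associated block and dependency blocks.  Sets
of ≥ 2 markers at posterior ≥ 0.5 are reported with their block kind.
Production defaults are 1,000,000 iterations with 990,000 burn-in (i.e.
the final 10,000 samples vote); the test and benchmark runs use 50,000
iterations with 45,000 burn-in, which the recovery experiments show is
ample at 30-marker candidate sets.  The maximum block size defaults to 5,
guarding the 3^k cell explosion.  The partition prior is uniform; an
optional size-penalizing prior is available for large candidate sets.

**Two-locus verification.** Each reported group is checked pairwise with
ordinary least squares of y on `[1, g_a, g_b, g_a·g_b]`; the p-value is the
two-sided t test on the product coefficient, and groups carry the (min,
max) over their C(k,2) pairs.  Collinear pairs are flagged degenerate and
excluded from the range with a warning.

## Synthetic data (`simulate`)

The generator emulates the panel the analysis assumes:

* **Two weakly diverged subgroups** ("IC"-like and "LR"-like, 200 + 200 by
  default): ancestral frequencies uniform on [maf_floor, 1 − maf_floor]
  (default floor 0.05), subgroup frequencies Balding–Nichols
  (Beta-distributed around the ancestral frequency) at target Fst 0.0581.
* **Local LD** via a first-order Gaussian copula: one latent AR(1) path per
  haplotype along each chromosome, correlation `exp(−d/scale)` between
  adjacent markers (default scale 100 kb), thresholded at the subgroup
  allele frequency.
* **Extreme inbreeding** (target F = 0.971): per locus, the second allele
  copies the first with probability F, which matches the method-of-moments
  F in expectation.  Per-*individual* copying would concentrate all
  heterozygosity in the few outbred samples and induce identity
  disequilibrium between unlinked loci — real partially-selfing populations
  do show this, and the partition model then legitimately reports pervasive
  dependency blocks; per-locus mixing was chosen so that an effect-free
  panel is genuinely exchangeable and can serve as a specificity null.
* **Phenotype**: subgroup mean (defaults 42.16 and 45.86 days) + additive
  QTL effects × dosage + full 3^k interaction cell tables + Gaussian noise.
  The default two-locus pattern is XOR-like on dominant coding (an effect
  whenever exactly one marker carries an alternate allele), which has no
  additive marginal at balanced frequencies — a pure non-additive signal
  for power tests.  The residual standard deviation defaults to 5 days, a
  fixture choice (no trait variance is published for the original panel)
  representative of field-measured flowering dates.

Benchmark problem sizes — 400 samples × 2,000 markers for structure
statistics, 300 × 2,000 for the association scan, 400 × 30 candidates ×
50,000 iterations for interaction recovery — were chosen as the smallest
panels at which the targeted statistics stabilize (Fst within ±0.02,
calibrated null p-values, ≥ 90% interaction recovery power).

**What passing tests do not show.** The generator has no coalescent
genealogy, no recombination map, no genotyping error, and its LD is
stationary within chromosomes; phenotypes have a single environment and no
genotype-by-environment interaction.  Detection power measured here
therefore bounds what the same settings achieve on real panels, where LD
between candidate markers (the generator's structured mode, Fst > 0)
produces genuine dependency blocks that compete with phenotype blocks, and
where trait distributions are not Gaussian.

## Numerical choices and degenerate inputs

* Missing genotype calls: policy `error` (default; the intended inputs are
  imputed upstream), `drop_marker`, or `mode_impute`.  Non-biallelic or
  non-SNP VCF records are skipped with a logged count (`strict` raises).
* Coordinates are 1-based closed everywhere internally; BED input is
  shifted on read.
* REML maximizes over log-λ (λ = σ_g²/σ_e²) on [−12, 12] with a bounded
  scalar minimizer and an explicit λ → 0 boundary check; variance-ratio 0
  with K = I reproduces ordinary least squares to 1e−8 by construction.
* Association p-values are floored at 1e−300 before the −log10 transform.
* Constant (post-filter) markers are dropped from the scan; collinear
  two-locus designs are flagged rather than tested.
* MCMC caches block marginals keyed by the marker subset, so repeated
  visits cost dictionary lookups; the chain state is reproducible from the
  seed.

## Known limitations

* K2P distances discard heterozygous sites; at inbreeding far below the
  panel's ~0.97 the retained site fraction drops quadratically.
* P3D holds variance components fixed across markers; markers with very
  large effects can see slightly conservative p-values relative to exact
  per-marker REML (available behind `method="exact"`).
* The interaction search scales to thousands of candidates in principle,
  but mixing at that scale needs longer chains than the desk-scale defaults
  exercised here; production-scale runs should monitor acceptance rates and
  use the size-penalizing prior.
* Homology filtering trusts the hit table's coordinate and identity fields;
  no re-alignment is performed.
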