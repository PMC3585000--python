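# Methods

This note documents the statistical models behind each module, the defaults
and why they were chosen, the numerical choices that matter, and what the
synthetic-data validation does and does not establish.

## Genotype data model and formats

A dataset is an N×M matrix of diploid allele-1 dosages (0/1/2, −1 for
missing) plus a SNP map (chromosome, genetic position in cM, physical
position, two alleles) and labelled samples.  PLINK binary (BED v1,
SNP-major, magic bytes `6C 1B 01`; 2-bit codes 00 = hom allele 1,
01 = missing, 10 = het, 11 = hom allele 2, little-endian within each byte)
and PLINK text (PED/MAP) are supported.  The FAM/PED family columns carry
the sample annotation (FID = population, IID = sample id,
father = subgroup, mother = region, `0` = absent), keeping the files
PLINK-conformant while making the sample table round-trippable.

*PED limitation.* PED declares no alleles, so the reader counts dosage
toward the lexicographically smaller observed allele.  A column in which
only allele 2 is observed therefore reads back flipped — an ambiguity of
the format itself, not of this implementation.  BED round-trips exactly for
every dataset.

## QC, pruning, IBS, subsampling

* `qc_filter`: a SNP survives when its missing fraction is ≤ 0.01 (a "99%
  genotyping success rate" read as a boundary-inclusive per-SNP call-rate
  threshold) and, by default, lies on an autosome; samples are never
  touched and retained genotype values never altered.
* `ld_prune`: greedy windowed pruning with defaults r² > 0.4 removed,
  50-SNP windows, 5-SNP steps (the common pairwise-pruning convention;
  window/step are exposed because only the r² cutoff is canonical).
  Windows slide per chromosome over the original map order; within a
  window, the worst-correlated retained pair loses one member — the SNP
  with higher missingness, then the later one in map order — until no
  retained pair exceeds the cutoff.  r² uses pairwise-complete dosages;
  monomorphic SNPs have undefined r², treated as 0 and never pruned.
* `ibs_distance_matrix`: per pair, similarity = (#SNPs sharing both
  alleles + ½·#SNPs sharing one) / #pairwise-complete SNPs; distance =
  1 − similarity.  A pair with zero overlapping calls is an error naming
  the pair.
* `stratified_subsample`: equal-size per-group draws without replacement,
  reproducible by seed — the standard guard against sample-size-driven
  artefacts in structure analyses.

## Structure embeddings

`classical_mds` is Torgerson scaling: double-centre the squared distance
matrix, eigendecompose, scale eigenvectors by √eigenvalue.  Negative
eigenvalues (non-Euclidean inputs) are truncated; asking for more
dimensions than there are positive eigenvalues returns fewer columns with
a warning.

`pca_normalized` centres each SNP by its mean dosage and scales by
√(p̂(1−p̂)) with p̂ = mean/2 — the drift-variance normalisation that makes
eigenvalues comparable across allele frequencies.  Missing genotypes are
mean-imputed before scaling (the simplest policy that leaves the column
mean unchanged); monomorphic columns are dropped.  Each component is
oriented so the largest-magnitude loading is positive, making output
deterministic; eigenvalues are those of the sample covariance (divisor
N−1).

`pca_outlier_removal` iterates: embed, drop samples beyond σ standard
deviations from the mean on any of the top PCs, re-embed.  Defaults
σ = 6, 10 PCs, 5 iterations — the documented convention of the standard
PCA toolkit for genotype data.  It refuses to shrink a cohort below 3
samples and is idempotent once converged.

## Ancestry decomposition

The binomial admixture likelihood is
ℓ(Q,P) = Σ<sub>i,m non-missing</sub> g log π + (2−g) log(1−π),
π = QP (binomial coefficient omitted; it is constant in the parameters).
`fit_admixture` runs the joint EM update of Q and P — the expected ancestry
of each allele copy given current parameters, then closed-form maximisation
— which cannot decrease ℓ; the trace is asserted non-decreasing each
iteration (rounding-scale wiggles below 10⁻⁹·|ℓ| are masked).  The
stationary points coincide with those of the block-relaxation solvers used
by the standard tools; only the path differs.  Choices:

* initialisation: Q rows from a flat Dirichlet, P from observed allele
  frequencies plus seeded Gaussian noise (sd 0.05);
* P clipped into [10⁻⁶, 1−10⁻⁶] to keep ℓ finite;
* stop when the gain drops below `tol` (10⁻⁴, absolute) or after
  `max_iter` (500) rounds;
* components re-ordered by descending total ancestry mass, so output is
  deterministic per seed despite label-permutation symmetry.

`admixture_cv` partitions the non-missing entries uniformly at random into
folds, hides one fold at a time, refits, and predicts the hidden dosages as
2·(QP); the score is the pooled mean squared dosage error — deterministic,
differentiable, and standard for masked-entry validation.  In the
acceptance runs the CV refits use `max_iter` = 150: the held-out error
curve over K flattens long before full likelihood convergence, and the
selected K on the validation cohorts is the same at this cap as the
simulated truth.

`component_fst` offers two ratio-of-averages estimators between component
frequency rows — Hudson (default): Σ(p<sub>k</sub>−p<sub>l</sub>)² /
Σ[p<sub>k</sub>(1−p<sub>l</sub>)+p<sub>l</sub>(1−p<sub>k</sub>)]; Nei:
Σ(p<sub>k</sub>−p<sub>l</sub>)²/2 / Σp̄(1−p̄) — never an average of
per-SNP ratios.  `panel_fst` adds the finite-sample Hudson estimator for
genotype panels (numerator corrected by each panel's sampling variance
p(1−p)/(n−1)), which is unbiased for the population FST and is what the
divergence round-trip uses.

*Known property.* FST between *fitted* components overestimates the
pairwise FST of the source populations whenever ancestry proportions are
not exactly 0/1: the mixture fit compensates for Q-spread by pushing
component frequencies beyond the population frequencies (measured ≈1.5× at
F = 0.1 with 100-sample panels).  Tests therefore bound component FST in a
band around the simulation truth rather than pretending the estimator is
calibrated for this quantity.

## Admixture dating

For SNP pair (x,y) at genetic distance d, the expected admixture LD is
proportional to δ<sub>x</sub>δ<sub>y</sub>e<sup>−nd</sup>, with δ the
allele-frequency difference between the two ancestral populations and n the
generations since (instantaneous) admixture.  `weighted_ld_statistic` uses
reference-panel frequency differences as δ, the Pearson correlation of
dosages across the admixed cohort as the observed LD z, and per distance
bin computes A(d) = Σδ<sub>x</sub>δ<sub>y</sub>z /
√(Σ(δ<sub>x</sub>δ<sub>y</sub>)²·Σz²) — an uncentred correlation between
weight products and LD over the bin's pairs, bounded in [−1, 1] and
invariant to swapping the references.  Defaults: 0.1-cM bins to 30 cM, the
fit window 0.5–30 cM (the customary settings of this family of methods;
all exposed); pairs with fewer than 10 complete observations are skipped;
zero-variance SNP pairs are excluded.  The statistic lives in the
noise-dominated regime — per-pair signal is far below per-pair sampling
noise — which is exactly where its expectation over a bin is proportional
to e<sup>−nd</sup>.

`fit_exponential_decay` is pair-count-weighted nonlinear least squares of
A(d) = A₀e<sup>−nd</sup> (+ offset if requested), rate constrained ≥ 0,
started from a log-linear slope estimate plus a fixed grid of rates (the
first start is preferred on rss ties, which pins the degenerate
constant-curve case to rate 0).  `jackknife_date` refits with each
chromosome's pairs removed (from cached per-chromosome bin sums) and
applies the SNP-count-weighted delete-one jackknife to get the standard
error; dates multiply by a 25-year generation time.

`fst_to_divergence_time` maps FST to generations as t = 2·Ne·FST
(`linear`, the first-order drift approximation, default because it is the
transparent headline formula) or t = −2·Ne·ln(1−FST) (`log`, exact under
pure drift and the inverse of the simulator's `fst_from_divergence`), then
to years over an Ne range.  Log ≥ linear always; both are monotone in FST
and Ne.

## Simulator and what validation shows

`simulate_ancestral_freqs` draws an ancestral frequency uniform on
(0.05, 0.95) per SNP (truncated so reference weights stay informative;
configurable) and population frequencies from the Balding–Nichols Beta with
drift F — mean p, variance F·p(1−p); draws are clipped strictly inside
(0, 1).  Under this parameterisation the *pairwise* Hudson FST between two
populations each at drift F from the ancestor equals F (E[(p₁−p₂)²] =
2F·p(1−p) against E[p₁(1−p₂)+p₂(1−p₁)] = 2p(1−p)), which the tests assert
directly.  `simulate_admixed` makes each haplotype an ancestry mosaic:
Poisson(n·L) breakpoints per chromosome of genetic length L Morgans,
segment ancestries iid Bernoulli(α) — giving ancestry autocovariance
α(1−α)e<sup>−nd</sup>, the exact model the dating statistic fits, so the
recovered rate estimates n with no model mismatch.  Haplotypes are
independent (no phase is consumed downstream) and genotypes are their sum.

Default study conditions (also the pipeline's simulation preset): 10
chromosomes × 1 Morgan × 2,000 SNPs, drift F = (0.05, 0.05), α = 0.2,
n = 30 generations, 400 admixed samples, 2 × 200 reference samples.  The
dating validation repeats this at n = 10 and 100; the ancestry validation
uses F = 0.1 with 150 samples × 5,000 SNPs (two populations) and a
three-population analogue for CV.  These sizes recover the decay rate
within a few percent and keep the full validation suite to a few minutes.

What the simulator does **not** emulate: background LD within ancestral
populations (sites are independent given ancestry), mutation, selection,
continuous migration, phased haplotypes, genotyping error, or array
ascertainment.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions — parameter recovery, not
robustness to the violations real cohorts exhibit.  On real data,
background LD inflates short-range bins (hence the 0.5-cM lower fit bound)
and continuous gene flow makes the fitted date an average over mixture
times.

## Pipeline

`run_pipeline` executes simulate/load → QC → optional pruning → IBS/MDS +
PCA (optional outlier trimming) → optional ancestry (+CV, component FST) →
optional dating, writing per-stage artifacts and a JSON report.  All
randomness derives from one master seed through named per-stage substreams,
so a config + seed pair reproduces the report byte-for-byte.  Validation
runs before any computation.  The CLI (`levantstrat qc/prune/ibs/
subsample/mds/pca/admix/cv/fst/rolloff/divtime/simulate/run`) is a thin
layer over these functions.

## Known limitations

* EM needs hundreds of iterations to reach the 10⁻⁴ likelihood-gain
  criterion; the iteration cap (500) is routinely the binding stop on
  large cohorts.  Parameter estimates stabilise long before the
  likelihood does.
* The dating statistic assumes one instantaneous admixture pulse; multiple
  waves or continuous flow yield a single averaged date.
* Component FST from fitted ancestry components is upward-biased (see
  above); divergence-time conversion additionally assumes constant Ne.
* PED columns observed for only one allele are ambiguous (format
  limitation); use BED.
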