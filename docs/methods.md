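# Methods

## Genotype representation

All methods consume a sample × SNP matrix of additive codes: `aa = -1`,
`Aa = 0`, `AA = 1` (count of alternate alleles minus one) with `-2` for a
missing call. Network inputs are rescaled affinely to the unit interval,
`x = (g + 1)/2`, so observed genotypes become {0, 0.5, 1}. The missing code
passes through the same map to `-0.5` rather than being imputed: missingness
stays a distinct input level, and simulated missingness perturbs network
inputs the same way it perturbs the unnormalized matrix methods. An optional
mean-imputation mode exists (`normalize_unit(..., impute_missing=True)`) but
is off by default. The map is invertible on observed codes, so
reconstructions can be read back as genotypes.

PCA is the exception: there, missing genotypes are mean-imputed per SNP
before centering and scaling, both at fit time and at projection time, which
is the standard treatment for frequency-normalized PCA.

## IBS similarity and degrees

The per-locus similarity of two individuals with alternate-allele counts
a, b ∈ {0,1,2} is the shared-allele fraction `(2 - |a - b|)/2` (1 for
identical genotypes, ½ for one shared allele, 0 for opposite homozygotes);
pairwise similarity averages this over the loci observed in *both* samples
(pairwise deletion). Pairwise deletion is a deliberate choice: similarity
must reflect observed sharing for the degree correction to be robust to
target missingness. A pair with zero jointly observed loci is an error, not
a silent zero. Degrees are plain row sums of the similarity matrix; for the
reference form the self term (s_ii = 1) is included, reading the defining
sum as running over all reference individuals.

## The hybrid model

SAE-IBS couples a fully connected autoencoder (leaky-ReLU activations,
negative slope 0.01; decoder mirrored to the encoder) with a spectral
bottleneck: the encoder features are scaled per sample by d_i^{-1/2} and
factorized by a low-rank SVD, G = ŨΣ̃Ṽᵀ. The latent scores Z̃ = ŨΣ̃ are
exactly orthogonal; the decoder reconstructs from Z̃Ṽᵀ. Targets project as
D̃^{-1} f(Y) Ṽ using their cross-IBS degrees against the reference.

Three design choices deserve emphasis:

**SVD-layer gradient handling.** Ṽ is treated as a constant inside an
epoch; gradients flow through encoder and decoder only. After each epoch's
mini-batches, the SVD is recomputed from the encoder features of the
complete dataset. This is the central architectural decision: it keeps the
bottleneck exactly orthogonal at all times at the cost of a full-data pass
per epoch. Column signs of Ṽ are fixed (largest-magnitude loading positive)
so the axes are comparable across epochs and runs.

**Pre-training.** A plain autoencoder (encoder feeding the decoder
directly, no bottleneck restriction) is trained first, for up to 1000
epochs with early stopping, to give the SVD a well-formed embedding to
factorize. Without it the early SVD axes are dominated by the feature
mean and training is slow to differentiate samples.

**The trivial leading axis.** For any uncentered decomposition — UPCA,
SUGIBS, and the SAE-IBS bottleneck, whose inputs are non-negative-mean
features — the leading singular axis is a near-constant "grand mean"
direction: its singular value is large but its score *range* across samples
is tiny, and it carries no ancestry information. As in spectral embedding
practice, the model internally computes k+1 components and reports the k
non-trivial axes as ancestry scores, while the reconstruction path keeps the
full rank-(k+1) bottleneck so the mean passes through the decoder. Without
this convention, "axis 1" of the uncentered methods is meaningless for
clustering and its near-zero range makes range-normalized deviations
explode. A `drop_trivial_axis` flag (default on) exposes the choice.

## Training

Optimization is Adam (learning rate 1e-3 by default) with L2 weight decay
1e-4 applied to weights only. Weight decay doubles as a contraction knob: a
stronger penalty yields a more contractive encoder and hence more robust
projections, at some cost in latent expressiveness, so it is exposed in the
configuration. The loss is MSE by default; MAE is used for the
relatedness-robustness setting, where its linear (rather than quadratic)
penalty stops a handful of relatives from bending the latent space.
Training uses mini-batches (default 64), a sample-wise validation split
(10%, stratified by population label when labels are present) and early
stopping with patience 50 on the validation reconstruction loss (plus the
β-weighted projection loss when active). Everything is seeded: the same
configuration reproduces bit-identical training curves.

Denoising variants corrupt the training inputs freshly each epoch with the
artifact simulator while reconstructing the clean data. The projection loss
of the "-L" variants is the mean squared difference between the latent
coordinates of the clean and corrupted inputs, weighted by β; with β = 0
they reduce exactly to their non-"-L" counterparts. The exact functional
form of the latent-robustness penalty is this package's choice, motivated by
the observation that denoising the *output* does not by itself guarantee
noise-robust *latent* features.

The implementation is a compact double-precision numpy MLP with manual
backpropagation. At the problem sizes this package targets (hundreds of
samples, thousands of pruned SNPs, hidden layers of a few dozen units) a
full training run takes seconds on one CPU, and exact arithmetic
reproducibility across runs and machines is worth more than GPU throughput.

## Linear baselines

PCA mean-centers each SNP and scales by √(p(1-p)) with p the observed
alternate-allele frequency (monomorphic SNPs fall back to scale 1);
truncated SVD gives scores UΣ. UPCA is the SVD of the raw codes with no
centering or scaling (an optional centering flag exists); missing codes stay
in the matrix, which is exactly the artifact sensitivity the degree
corrections address. SUGIBS decomposes D^{-1/2}X and projects targets as
D̃^{-1}YV, mirroring the hybrid model's projection equation. The
self-projection identity — projected reference scores equal training scores
scaled per sample by d_i^{-1/2} — is checked numerically in the tests.

## Synthetic data generator

The generator emulates the statistical structure of the real-data
experiments at desk scale. Populations follow the Balding–Nichols island
model: ancestral MAF uniform on (0.01, 0.5) (folded so either allele can be
minor), population frequencies Beta-distributed with divergence F, genotypes
binomial. Defaults are K = 3 populations × 100 samples, 1000 SNPs, Fst 0.1
— divergence of the same order as continental human populations and enough
rare variants (MAF < 0.05) to drive the artifact experiments. A Hudson-type
Fst estimate on generated data recovers the nominal F (tested at 20%
relative tolerance). Optional admixed individuals draw each SNP from a
mixture of population frequencies; optional families add full siblings by
Mendelian transmission from two parents sampled out of a source population
(the experiments embed one family of five and one of four, mirroring the
relatedness structure studied at scale).

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent, so LD pruning is exercised on synthetic correlated columns, not
realistic haplotypes), a realistic site-frequency spectrum skewed toward
rare variants, genotyping batch effects, or continuous clines. Passing tests
therefore demonstrate the mechanisms — degree correction, orthogonality,
loss geometry — not calibrated real-data performance.

The artifact simulator applies 5% genotyping errors (a genotype flips to one
of the other two observed codes, uniformly) and/or 5% missingness to the
SNPs with MAF below 0.05, the regime where frequency normalization amplifies
artifacts most. MAF is computed on the unperturbed matrix, missing entries
excluded; already-missing entries are never "perturbed". The rare-SNP
restriction applies to both errors and missingness (a `rare_only` flag
allows genome-wide perturbation). Replicates are seeded from a spawned
seed sequence, so a master seed reproduces the whole replicate set.

## Evaluation

Clustering uses scikit-learn K-means (1000 restarts by default, max 300
iterations, tol 1e-4); accuracy is the maximal label-agreement fraction
over cluster-label permutations, computed via the Hungarian algorithm on
the contingency table and verified against exhaustive enumeration for
K ≤ 6. Classification uses 3-nearest-neighbour majority vote (Euclidean,
uniform weights); an even vote falls back to the single nearest neighbour.
When classifying projected targets against a degree-corrected reference
space, the reference coordinates are taken from the same projection operator
(the reference's own D^{-1}-corrected self-projection) rather than the
training scores Z̃ = ŨΣ̃: the two differ per sample by d_i^{-1/2}, and
mixing the scales distorts nearest-neighbour distances.
Relatedness robustness is the mean Mahalanobis distance of relatives to
their source population's cluster on 8 axes, with a ridge of
1e-8 × (mean variance) on the covariance since 8 axes vs ~100-sample
clusters can be ill-conditioned. Projection robustness is NRMSD: per-axis
RMSD between original and perturbed target scores, normalized by the range
of the original scores on that axis, averaged over the first two axes (the
perturbed scores come from the same fitted model, so axes correspond by
construction and no Procrustes alignment is applied). Method comparisons
use all-pairs two-sample t-tests with Bonferroni correction (for 9 methods:
36 tests, threshold 0.05/36 ≈ 0.0014); the t-tests act on the per-replicate
2-axis mean NRMSD.

The covariance summary of a score matrix is *uncentered* by default
(Z̃ᵀZ̃/(n-1)): SVD scores are orthogonal, not mean-zero, and the exact-zero
off-diagonal structure of the orthogonal methods only exists on this scale.
`center=True` gives the conventional sample covariance.

## Known limitations

- With mean-imputed PCA projection, *random* target missingness is largely
  absorbed by the imputation (an imputed entry equals the reference mean and
  vanishes after centering), so on the synthetic fixtures the hybrid model's
  robustness advantage over PCA shows up under genotyping errors but not
  under random missingness. Structured or informative missingness, which the
  generator does not model, is where imputation misleads.
- The full-data SVD refresh makes training cost linear in the reference size
  per epoch; the implementation targets desk-scale references (up to a few
  thousand samples), not biobank scale.
- Projection requires the training reference (for cross-IBS degrees);
  study designs without reference genotype access cannot use the degree
  correction.
- Hidden-layer sizes and epochs are deliberately modest defaults
  (one hidden layer of 32 units); richer architectures are configurable but
  untested beyond the fixture sizes used in the test suite.
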