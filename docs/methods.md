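# Methods

`pdiff` implements a bioactivity-profile-conditioned latent diffusion model
for high-content cell images together with the full evaluation stack around
it: profile preparation, chemistry-aware data splitting, a synthetic
Cell Painting simulator with known ground truth, segmentation-based feature
evaluation, and Sinkhorn-divergence virtual hit expansion.  This note records
the models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Bioactivity profiles

A compound's profile is a vector of predicted pAC50 values (negative log10
molar half-maximal activity concentration), one per assay, produced upstream
by a massively multitask QSAR model.  Two preparation steps:

**Assay selection** (`profiles.select_assays`).  Assay panels contain many
weak models; the cascade keeps, per annotated protein target, the single
assay whose model has the best held-out r² (squared Pearson correlation of
predicted vs experimental pAC50) above a floor (`r2_min = 0.3`); per
drug-discovery project, the best purely-phenotypic assay above the same
floor; and unannotated assays only above a high-quality bar (`r2_hq = 0.9`).
Categories are exclusive — an assay with a target annotation is treated as
target-annotated even if it also carries a project.  Ties on r² break to the
lexicographically smaller assay id so selection is deterministic.

**Padding and scaling** (`profiles.pad_profile`, `standardize_profiles`).
The selected-assay vector is padded with trailing zeros to the fixed
conditioning width (default 2048; the canonical case pads a 2018-assay
profile with 30 zeros).  Before conditioning the denoiser, profiles are
z-scored per assay over the training compounds and the statistics are stored
in the checkpoint so inference replays the identical transform.  Raw pAC50
columns have assay-specific locations and scales; standardization keeps the
cross-attention inputs on one scale and is invertible.  Raw mode is available
(`standardize=False` in `diffusion.train`).

## Chemistry and the realistically-novel split

Fingerprints are Morgan substructure-count fingerprints of radius 2 folded
into 2048 counts (RDKit).  Similarity for clustering and split reporting is
the Tanimoto coefficient on the binarized fingerprints — the community
default; the count vectors are kept for model conditioning and baselines.

Clustering is Butina leader clustering at a Tanimoto cutoff of 0.6
(configurable).  Determinism rule: candidate cluster seeds are processed in
decreasing order of neighbor count with ties broken by compound id, which
makes the partition independent of input order.  The implementation is
in-package because this exact tie-break is part of the contract; the RDKit
implementation serves as a cross-check in the tests.

The split (`chem.realistic_split`) allocates whole clusters largest-first to
the training set toward a target of `round(train_fraction * N)` compounds;
when the next cluster would overshoot, remaining singletons top the training
set up to the exact target and everything else is held out.  With a
singleton-rich tail the printed 90/10 counts (3375/375 of 3750) are met
exactly.  The held-out set therefore consists of singletons and small series
— chemistry unlike anything in training — and `cross_split_similarity`
reports how novel it is (per-held-out max Tanimoto to training, plus the
median).

## The synthetic data generator

The simulator stands in for a proprietary-scale Cell Painting campaign and
defines the study conditions for every test.  Its generative hierarchy:

* **Chemical series** sizes follow a Zipf-like skew (weights 1/k over
  series, each series guaranteed one compound): a few large series, a long
  singleton tail.  Each series has a fingerprint prototype (64 on-bits,
  counts 1–3); a compound keeps each prototype bit with probability 0.95 and
  gains Poisson(3) random bits.  Within-series Tanimoto lands near 0.8,
  cross-series near 0.02, so Butina clustering at 0.6 recovers the series
  (adjusted Rand index ≈ 1 at default noise).
* **Mechanisms**: series `s` carries mechanism `s mod n_mechanisms`
  (default 3 series per mechanism).  Series and mechanism are deliberately
  decoupled: a held-out series is novel chemistry whose biology is still
  represented in training through other scaffolds.  This is the regime a
  profile-conditioned generator is supposed to handle — with series ≡
  mechanism, every held-out mechanism would be absent from training and no
  conditioning signal could generalize (we verified that the held-out
  correlation is then sign-random).
* **Profiles**: each mechanism has a signature — baseline 4.5 pAC50
  everywhere, 3 signature assays at ~N(7.5, 0.5) — and a compound's profile
  is its mechanism signature plus i.i.d. N(0, 0.3²) noise.  The 0.3 pAC50
  noise is comparable to the replicate error of a good QSAR model.
* **Phenotypes**: mechanisms map to archetypes (neutral, dense, sparse,
  large, elongated, punctate, toxic, small-dense) cycling over the mechanism
  index, with per-compound log-normal jitter (σ = 0.1) on cell count and
  radius.  Archetype geometry is stated at a 64×64 reference canvas:
  e.g. "dense" is 22 cells of radius 4.5 px, "toxic" renders with count ×0.1
  and radius ×0.5 plus debris speckle.
* **Images**: a field of view draws Poisson(count) ellipse cells
  (overlap-avoiding placement with 8 rejection attempts), cytoplasm on the
  red channel (intensity ≈ 0.55), a concentric nucleus disk at 0.45 r on
  blue (0.85), a faint mitochondrial haze (0.15) plus Poisson-count bright
  punctae on green, then additive Gaussian background noise (σ = 0.02),
  clipped to [0, 1].  Everything is a deterministic function of the seed.

What the simulator does **not** emulate: illumination gradients and
vignetting, cell-to-cell texture, out-of-focus fields, plate effects,
channel bleed-through, or realistic morphology beyond ellipses.  Tests
passing here show that the machinery — conditioning, training, sampling,
segmentation, retrieval — behaves correctly under a known ground truth, not
that the model reaches any particular fidelity on real microscopy.

## The diffusion model

Diffusion runs in a latent space chosen by a pluggable codec:

* `IdentityCodec` — latent = image; exact.
* `PoolCodec` — block average-pooling by an integer factor (nearest-neighbor
  decode), centered at 0.5 and rescaled ×4 toward unit variance; the default
  desk-scale choice (64×64×3 → 3×8×8).
* `PCACodec` — a linear autoencoder (top-k whitened principal components of
  the training images, reshaped to a grid) behind the same interface, the
  learned stand-in for a pretrained variational autoencoder.  A trainable
  convolutional autoencoder was considered and rejected at this scale: it
  adds training cost and nondeterminism without exercising any additional
  diffusion-side contract.

The forward process follows the standard discrete formulation
q(z_t | z_0) = N(√ᾱ_t z_0, (1−ᾱ_t) I) with a linear β schedule, defaults
β: 8.5e-4 → 0.012 over T = 1000 steps (ᾱ_T ≈ 1.6e-3, i.e. the chain ends
deep in noise).  The denoiser ε_θ(z_t, t, c) is a compact U-Net: one
downsampling level, residual conv blocks with additive sinusoidal timestep
embeddings, and a single-head cross-attention block at the bottleneck whose
keys/values are the profile projected to 4 context tokens.  The "toy" preset
(base width 24) has ~160k parameters at conditioning width 64 — small enough
to train on one CPU in about a minute at the desk-scale latent.  The whole
network runs on an in-package reverse-mode autograd engine over NumPy whose
every op is verified against central finite differences in the test suite.

Training minimizes the noise-prediction MSE with three standard
refinements, all exposed in `TrainConfig`:

* **min-SNR weighting**: each sample's squared error is scaled by
  min(SNR_t, γ)/SNR_t with SNR_t = ᾱ_t/(1−ᾱ_t); γ = 5.
* **offset noise** (scale 0.1): a per-image-channel constant N(0,1) draw
  added to ε so the model can reach very dark/empty fields — important
  because cytotoxic compounds produce nearly empty images.
* **conditioning dropout** (p = 0.1): the profile is replaced by the
  all-zero null profile so the unconditional branch needed by
  classifier-free guidance gets trained.  The null profile is all-zeros,
  consistent with zero-padding semantics.

γ, the offset scale, the dropout probability and the β endpoints follow the
conventions of the techniques they come from; they are documented defaults,
not fitted values.  Optimization is Adam (lr 2e-3 at toy scale); all
randomness flows through one seeded generator and the checkpoint embeds the
seed, schedule, codec spec and profile-standardization statistics.

Sampling is ancestral DDPM from z_T ~ N(0, I).  At each visited step the
network is evaluated with the compound's profile and with the null profile,
combined as ε̃ = (1+w)ε(z_t, c) − w·ε(z_t, ∅) with guidance scale w = 4 by
default; the sampler may stride the schedule (e.g. 100 of 1000 steps) using
the effective ᾱ ratio between visited steps, and 12 images are generated
per compound by default.  The posterior update uses the conventional
variance β̃_t; with the analytic Gaussian ε-oracle the full-schedule sampler
reproduces the target mean and variance within Monte-Carlo error, which the
suite checks — the closed form is the independent oracle for the whole
sampler loop.

## Evaluation

Generated images are scored by what can be measured on them.  Images are
channel-averaged to grayscale and segmented by a classical pipeline —
Gaussian smoothing (σ = 1), Otsu threshold with an absolute floor of 0.08
(so blank or noise-only fields give an empty mask rather than thresholding
noise), distance-transform watershed seeded at local maxima, objects under
15 px (at 64×64, scaled with canvas area) removed.  The segmenter is a
pluggable callable, so a learned model can replace it without touching the
protocol.  Per image: coverage (fraction of pixels in cells), cell count,
mean cell size (px²; exactly total cell pixels / count).  Features are
averaged over each compound's images and Spearman rank correlations between
real and generated aggregates are computed across compounds.  The
attainable ceiling is estimated by randomly halving each compound's real
replicates (seeded; odd counts split floor/ceil), aggregating each half and
correlating the halves — a generator cannot beat the assay's own replicate
consistency.

## Hit expansion

A compound is represented as the *set* of its per-image feature vectors
(z-scored over all images; the reference statistics come from the real
images and are replayed onto generated ones).  Similarity between compounds
is the debiased Sinkhorn divergence
S_ε(a,b) = OT_ε(a,b) − ½OT_ε(a,a) − ½OT_ε(b,b) with squared-Euclidean cost
and uniform weights, ε = 0.05 on standardized features.  The solver works in
the log domain with ε-annealing (start near half the cost scale, divide by 3
toward the target) and judges convergence of the dual potentials relative to
the cost scale, since potentials inherit that scale and an absolute
criterion is unreachable in float64 for large costs; batched problems drop
out of the iteration individually as they converge.  S_ε(a,a) = 0 by
construction, S_ε is symmetric bit-for-bit (transposed solves perform
identical arithmetic), and as ε → 0 the value approaches the exact
optimal-transport cost — the suite checks a 4-point case against exhaustive
enumeration of all 4! assignments.

Retrieval ranks candidates by divergence (ties break on compound id) and is
scored as percentage overlap of the top-k set with a ground-truth top-k set
defined by real-image retrieval.  Baselines: uniformly random k-subsets
(per-query overlap counts are Hypergeometric(n, k, k); with 375 candidates
and k = 50 the median overlap is 14%), Tanimoto nearest neighbors on
fingerprints, and cosine nearest neighbors on profiles.  Overlap
distributions are compared with two-sample Kolmogorov–Smirnov tests,
Benjamini–Hochberg-adjusted across all method pairs.  Per-image feature
vectors are the default reading of "feature sets"; per-cell vectors can be
fed through the same `FeatureSet` container.

## Desk-scale study sizes

The end-to-end recovery study trains on a 200-compound, 8-mechanism library
at 64×64 (12 training images per compound), with the pool codec (3×8×8
latent), toy preset, 800 Adam steps, and 50-step guided sampling for 12
images per held-out compound — the package's desk-scale configuration, about
three minutes per trained model on one CPU.  Against an identically trained
control whose training profiles were permuted among compounds, the
conditioned model's held-out coverage correlation reaches ≥ 0.5 and beats
the control on a majority of three seeds.  The expansion identity/dominance
study uses 101 queries against 120 candidates with k = 20 and 8 images per
compound.  The split study runs at full library scale (3750 compounds, 600
series) because clustering 3750 fingerprints is cheap.

## Numerical notes and limitations

* Timesteps are 1-based; ᾱ_0 := 1.  `forward_noise` accepts per-sample
  timestep vectors.
* The DDPM variance choice β̃_t slightly under-disperses at coarse sampler
  striding; the Gaussian-oracle check runs the full schedule.
* Watershed over-segments strongly elongated cells; counts for the
  "elongated" archetype run ~40% high.  Rank-based evaluation absorbs this.
* The cross-attention output projection and the final conv use small (not
  zero) initialization so profile sensitivity and gradient flow exist from
  step one.
* Checkpoints are single-file `.npz` archives (weights + JSON metadata) and
  are exactly reproducible from the config seed.
* CLI commands are thin wrappers over the library; exit codes are 0/1/2 for
  ok / user error / internal error.
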