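# Methods

## Scope and model

`sweepnet` studies binary classification of 80-kb haplotype samples as
*neutral* versus *recent hard sweep*, comparing convolutional networks
against haplotype summary statistics under controlled simulation, and
interpreting what the trained networks use. Everything is seeded and
deterministic: a master seed drives per-replicate simulation seeds, split
assignment, initializer draws and mini-batch shuffling.

## Simulation

**Demographies.** The single-population model is piecewise constant:
N = 10,000 ancestrally, 2,000 between 3,500 and 3,000 generations before
present, 20,000 since; μ = 1.5×10⁻⁸ /bp/gen, r = 10⁻⁸ /bp/gen, 80 kb
windows, 128 sampled haplotypes. The three-population capability uses the
Gravel et al. joint YRI/CEU/CHB inference (N_A = 7,310; N_AF = 14,474;
out-of-Africa bottleneck N_B = 1,861 at 51 kya; CEU/CHB split 23 kya with
exponential growth 0.38%/0.48% per generation from 1,032/554; migration
m_AF,B = 15×10⁻⁵, m_AF,EU = 2.5×10⁻⁵, m_AF,AS = 0.78×10⁻⁵,
m_EU,AS = 3.11×10⁻⁵; 25 years/generation; μ = 2.363×10⁻⁸). Neutral
coalescent simulation and mutation are delegated to msprime (infinite-sites,
ancestral/derived 0/1 coding, segregating sites only).

**Sweeps.** Hard sweeps use msprime's structured-coalescent sweep model
(genotype fitnesses 1, 1+s/2, 1+s; we parameterize by the heterozygote
coefficient s_het with dominance 0.5, so s = 2·s_het). Selection begins 600
generations before sampling with the beneficial allele at the region center
and frequency 0.01. Because detection power depends on the frequency the
allele reaches by sampling time, that terminal frequency is drawn per
replicate from a forward Wright–Fisher binomial trajectory (600 generations
at the current population size), conditioned on the allele surviving;
trajectory draws are retried up to 100 times and a surviving draw is
virtually certain from a 1% standing frequency (fixation probability
≈ 1 − e^{−4Ns·x₀} ≈ 1). At s_het = 0.01 the mean terminal frequency is
≈ 0.76; at 0.005 it is ≈ 0.16, which is what makes the weaker-selection
task intrinsically hard (accuracies near 60%). A trajectory that ends at or
below its starting frequency left no genealogical footprint and is
simulated as neutral genealogy (still labeled sweep). The structured
coalescent phase runs between the terminal and onset frequencies with
dt = 1/(40N).

Multi-population sweeps are approximated by collapsing to the target
population's own size history (growth discretized into constant steps, as
the sweep phase requires piecewise-constant sizes) with migration ignored
during the sweep — over 600 generations migrant ancestry is below ~2%.
This capability is validated qualitatively (reduced diversity, elevated
H1), not quantitatively.

**Datasets.** `generate_dataset` simulates n_per_class replicates per label
and splits 80/10/10 into train/validation/test, stratified so every split
is exactly class-balanced; splits are disjoint and seed-reproducible.
Archives store a JSON parameter/provenance record plus compressed arrays.

## Preprocessing

Pipeline order: major/minor polarization (flip columns where the derived
allele is the major allele; exact 50/50 ties keep their coding) → remove
sites with minor-allele frequency strictly below 1% → group identical rows
into haplotype blocks sorted by descending frequency (equal-frequency
blocks ordered lexicographically by bit string, making the sort
deterministic, idempotent and permutation-invariant) → width
standardization:

- **resize** — skimage's resizing (Gaussian anti-alias filter only when
  downsampling, order-1 spline, reflect boundaries) to width 128; pixel
  values stay in [0, 1] but become fractional;
- **zero_pad** — pad to the dataset's maximum width rounded up to the
  nearest multiple of 10, zeros split across both edges (odd column to the
  right);
- **trim** — keep the centered window (the sweep site is mid-region) of the
  dataset's minimum width rounded down to the nearest multiple of 10.

Sorting precedes width standardization; padding placement, trimming
placement and the polarization tie rule are package choices where the
convention is otherwise unspecified.

## Statistics

H1, S and Watterson's θ operate on the filtered (polarized, MAF ≥ 1%) but
width-unstandardized matrices. iHS keeps ancestral/derived coding: per
qualifying core site (minor-allele frequency ≥ 0.05), EHH is computed
outward in both directions until it decays below 0.05 or the region edge,
integrated over bp by the trapezoid rule; the score is ln(iHH_A/iHH_D).
Standardization bins scores by derived allele count using moments learned
from matched neutral simulations; bins with fewer than 20 observations are
pooled with the nearest populated bin; the region-level statistic is
max |z|. Region-edge truncation makes boundary cores conservative. Each
statistic becomes a classifier by an exhaustive midpoint search for the
accuracy-optimal threshold and direction on the training split (ties toward
the smaller threshold).

## Networks and training

Architectures (all ending in a single sigmoid unit):

- **mini-CNN**: one 2×1 valid convolution kernel (a vertical difference
  detector), ReLU, flatten, dense(1) — 16,260 parameters at 128×128.
  Variants: 1×2 kernel; ReLU-free (affine) model.
- **Imagene-style**: three blocks of conv(32, 3×3) + ReLU + 2×2 max-pool,
  flatten, dense(64) + ReLU, dense(1). Block count, filters and units are
  configurable so the reduction ladder down to mini-CNN can be walked.
- **DeepSet**: two conv(64, 1×5) + ReLU row-wise stages, mean over the row
  axis (hence outputs invariant to haplotype ordering up to float addition
  order), flatten, two dense(64) + ReLU, dense(1).

Training: binary cross-entropy plus L1 and L2 penalties (0.005 each)
attached to the convolution kernels — the reference implementations'
convention, and the only placement under which the protocol functions:
penalizing the dense layers as well lets the constant L1 pull (lr·sign(w)
per Adam step) erase every small-initialized weight within ~100 steps and
collapses all models to a constant output. Optimizer: Adam (lr 0.001,
β₁ 0.9, β₂ 0.999, ε 10⁻⁷), batch 64, 2 epochs. Convolution weights initialize from a standard normal
and dense weights from Glorot uniform (DeepSet: Glorot throughout).
Training runs `restarts` independent initializations (restart i seeds with
seed + i) and keeps the restart with the best validation accuracy, ties to
the earliest. The stack is implemented in numpy (float32): convolutions as
chunked im2col matrix products with layer-owned reusable buffers (repeated
large allocations are page-fault-bound on a single CPU), max-pool ties
resolved to the first window position, in-place ReLU. Accuracy uses the
0.5 sigmoid cutoff; for cross-method agreement all methods (CNNs included)
use training-split-optimal thresholds.

## Evaluation and interpretation

Accuracy intervals: p̂ ± 1.96·√(p̂(1−p̂)/N_t). AUC: tie-corrected rank
statistic (scikit-learn). Method similarity: Spearman rank correlation of
continuous scores and pairwise binary agreement fractions, both as
symmetric unit-diagonal matrices over the test split.

Attribution uses expected gradients: for image x and background sample b,
attr = (x − b) ⊙ ∫₀¹ ∇f(b + α(x − b)) dα, averaged over a background set
(default 20 neutral + 20 sweep training images), with the path integral
evaluated by an m-step midpoint rule (default 32). Attributions satisfy
completeness — Σ attr ≈ f(x) − mean_b f(b) — exactly for affine models and
to O(1/m) for ReLU networks (256 steps reach ~10⁻⁴ absolute residual in
float32). Positive values push toward the sweep class. Class-averaged maps
are element-wise means; at desk scale averages use tens of images rather
than 1,000 per class, which preserves the qualitative patterns (top-row
concentration under row sorting; edge-column concentration under zero
padding). Signed mini-CNN dense-weight maps are read directly from the
model.

## Problem sizes and defaults

Paper-scale defaults (50,000 simulations per class, 10 restarts) are kept
on the config objects; the packaged study runner and acceptance script use
a desk-scale protocol chosen for single-CPU runtimes: 2,000 simulations
per class (test split 400, binomial SE ≈ 1% near 97% accuracy), restarts
5/5/2/1/1 for mini-CNN/linear/Imagene/Imagene-unsorted/DeepSet. Validation
(pilot, before freezing): H1 threshold accuracy 98.1% at s_het = 0.01 and
61.9% at 0.005 under this generator, matching the full-scale reference
values to within sampling error. Note that 2 epochs over a 3,200-image
training split is 100 optimizer steps versus 2,500 at full scale; the
multi-block CNN is still improving when training stops, so its desk-scale
accuracy sits a few points below the converged reference, and learning
without the row-sorting cue (which needs far more steps) lands well below
its full-scale value.

At desk scale, per-pixel |attribution| magnitudes are dominated by
high-variance rows (bottom singletons) and are structurally zero at
always-padded outermost columns, so the model-reliance claims are probed
behaviorally instead: shuffling the sorted top block of sweep images
collapses the sweep score while shuffling bottom rows does not, and
extending the zero padding inward pushes scores toward the sweep class.

## What the generator does and does not emulate

Simulated data have a fixed, known mutation rate, no missing genotypes, no
phasing or polarization error, and exactly one sweep position; S is
therefore an unrealistically clean signal (a sufficient statistic for θ),
and zero-padding experiments inherit that optimism — on real data a CNN
reading pad width would be confounded by local mutation-rate variation.
Passing tests demonstrate method behavior under the stated models, not
performance on real genomes.

## Known limitations

- The msms conditioning used for the original simulations is not published;
  the forward-trajectory emulation above was chosen on first principles and
  shifts absolute accuracies only within the stated tolerances.
- Exact supplementary layer counts for the Imagene reference are not
  reproduced; the representative architecture is configurable so a match
  can be dialed in.
- DeepSet invariance is exact up to float32 addition order in the row mean
  (differences ~10⁻⁷).
- iHS is windowed to the simulated region with physical (bp) distances; no
  genetic maps, no genome-scan machinery.
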