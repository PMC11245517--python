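# Methods

This note documents the models and procedures implemented in `fairseg`, the
parameters that matter, the design choices made where the design was open,
and the limits of what the synthetic testbed can demonstrate.

## 1. Phantom radiographs

Real hip/knee radiograph cohorts cannot ship with a software package, so
every downstream stage is exercised on deterministic 2-D phantoms. A phantom
is a piecewise-constant scene of parametric shapes on a square canvas
(geometry defined at a 128-pixel reference scale and multiplied by
`image_size / 128`), plus additive Gaussian noise:

* **knee** — distal femur (rectangular shaft + condylar ellipse), proximal
  tibia (plateau ellipse + shaft) separated by an age-dependent joint-space
  gap, and a patellar ellipse; labels {0 background, 1 femur, 2 tibia,
  3 patella};
* **hip** — acetabular cup (upper-half elliptical annulus) with an iliac
  column, and a proximal femur (head disk, neck capsule, shaft); labels
  {0 background, 1 pelvis, 2 femur}.

Masks are the exact rasterized shapes; with `noise_sigma = 0` a per-pixel
intensity lookup reconstructs the mask perfectly (tested).

Group structure mirrors the anatomical differences that motivate fairness
auditing:

| knob | default | meaning |
|---|---|---|
| `sex_width_factor` | female 1.15, male 1.0 | multiplier on pelvic/condylar width (female pelvises are wider) |
| `race_contrast_offset` | 0, 0 | additive bone-intensity offset per race level (bone-density differences); off by default |
| `age_joint_space` | 7 / 5 / 3 px | joint-space gap by age level, narrowing with age |
| `noise_sigma` | 0.08 | additive Gaussian noise SD (intensity units; image range [0, 1]) |
| `background`, `bone_contrast` | 0.15, 0.45 | background level and bone/background contrast |
| `jitter` | 0.05 | relative geometric variability (below) |
| `bias_delta`, `disadvantaged_group` | 0, (race, black_african_american) | bias injection (below) |

**Geometric jitter.** Each structure receives its own truncated-normal
(±1.5 σ) position and size perturbations (global shift SD = `jitter·n`
pixels, per-structure offsets 0.6 of that, sizes SD = `jitter` relative).
Per-structure variability matters: with near-identical scenes a segmenter
can learn a purely positional solution and image contrast becomes
irrelevant, which would make group difficulty — the whole point of the
testbed — unmeasurable. Truncation exists because unbounded tails
occasionally collided the patella into the femoral shaft, producing
ambiguous scenes that dominated group means as single-image outliers.

**Bias injection.** `bias_delta = δ` multiplies the bone/background contrast
of the designated disadvantaged group by `1 − δ` (floored just above zero);
noise is shared by all groups, so the disadvantaged group's contrast-to-noise
ratio is a factor `1 − δ` of everyone else's. Ground-truth masks are never
altered — the injected disparity is purely one of image difficulty. The
penalty deliberately produces *faint but clean* images: that regime is
learnable given enough exposure, so representation-level mitigation
(balancing, stratified batching) has a mechanism by which to act. An
alternative that also scales the disadvantaged group's noise up makes part
of the difficulty irreducible; under that variant no amount of re-balancing
can close the gap (we verified that stratified batching then fails to reduce
SER), which is not the phenomenon the mitigation strategies target.

**Inter-rater noise.** `inject_rater_noise` emulates annotation disagreement
by dilating or eroding each class (seeded coin flip) by `dilation_px`
4-connected iterations; perturbed regions are nested across `dilation_px`,
so agreement IoU decreases monotonically. On a 50-mask knee fixture at 128
px, a 1-px perturbation yields mean IoU 0.876, matching the 0.873 knee
inter-rater agreement reported for the cohort the built-in composition comes
from (grid-search calibration is provided).

**Cohort composition.** `table1_distribution()` reconstructs a published
766-hip / 707-knee cohort from its printed per-cell percentages (percentage
× joint total, rounded to nearest integer, any residual assigned to the
largest cell). The printed hip patient counts sum to 761, so counts are
always derived from percentages; the knee residual (+1) lands on the largest
cell. `table1_percentages()` keeps the printed percentages themselves
(normalized per joint; the hip column prints to 100.02%), which is the form
in which the published demographic shares (12.4%, 12.2%, 63.25%) are exact.

## 2. Segmentation network

The segmenter is a U-Net-style encoder–decoder with a residual encoder:

* optional stem (7×7 stride-2 convolution, BN, ReLU, 3×3 stride-2 max-pool),
  enabled at full scale, disabled at desk scale so 64×64 inputs are valid;
* four encoder layers of two basic residual blocks each
  (conv3×3–BN–ReLU–conv3×3–BN plus identity/1×1-projection shortcut); the
  first block of every layer downsamples by stride 2; widths default to
  64→128→256→512, all scaled by `width_multiplier`;
* a decoder whose first four blocks each fuse, by channel-wise
  concatenation, the first-block encoder feature map of matching resolution
  with the (transposed-convolution-upsampled) previous decoder output,
  followed by two conv–BN–ReLU stages; remaining stages upsample back to
  input resolution; a 1×1 head emits one score map per class.

Concatenation was chosen for the skip fusion because element-wise addition
is undefined across the differing channel counts involved; transposed
convolutions mirror the strided downsampling. The head's background bias is
initialized to 2.0 — a log-prior-style initialization reflecting that most
pixels are background — which removes a long "learn the prior" phase from
short training runs. The implementation is pure NumPy: im2col convolutions
backed by BLAS GEMMs, with analytic backward passes for every layer checked
against central finite differences in the test suite.

**Prediction rule.** Class probabilities are computed per class from the raw
scores and thresholded at 0.5: a pixel is assigned the foreground class of
highest probability provided it reaches the threshold, ties at the maximum
go to the lowest class index, and pixels where no foreground class reaches
the threshold are background. With softmax-trained scores the package
computes sigmoid probabilities of the foreground scores at prediction time;
because softmax training leaves absolute score levels only weakly anchored,
the library also exposes `masks_from_probabilities` for callers who supply
their own calibrated probabilities.

## 3. Training and mitigation strategies

`train()` implements four data-level strategies — none modify the loss or
the model:

* **baseline**: the full training split;
* **balanced**: every protected-group level undersampled (uniform, without
  replacement) to the minority count;
* **stratified**: mini-batches with ⌊batch/g⌋ records per level and the
  remainder rotating round-robin across batches; within a level, records
  are consumed in seeded shuffled order and recycled with reshuffling, so an
  epoch is ⌈max-level-count · g / batch⌉ batches and minority levels are
  oversampled within it;
* **group-specific**: one model per level, trained and evaluated only on its
  own level's records.

Published defaults: Adam (β = 0.9/0.999), lr 5·10⁻⁴, cross-entropy, 50
epochs, batch 16, threshold 0.5. Losses: mean per-pixel multi-class
cross-entropy, and soft Jaccard / soft Dice (1 − probability-weighted
overlap ratio averaged over foreground classes, ε = 10⁻⁷ smoothing).
Validation-split role is checkpoint selection: the epoch with the best mean
validation IoU is kept. All randomness (init, shuffling, undersampling,
stratified streams) derives from the config seed.

**Desk profile** (`TrainConfig.desk()`): 5 epochs, batch 4, lr 3·10⁻³,
Adam β₂ = 0.99. The batch of 4 trades batch-statistics quality for ~4× more
optimizer steps per epoch, which a 1/8-width model on 64×64 phantoms needs
to learn the patella (a ~5%-of-pixels class) at all; the faster second
moment and higher rate were chosen for stable convergence within ~250 steps.
These are engineering choices for CPU-scale runs, not claims about the
full-scale configuration.

## 4. Fairness metrics

Per-class IoU and Dice use pixel-set counting with the convention that a
class empty in both masks scores 1.0 (correctly predicted absence is not an
error; occurrences are logged). Aggregation is macro-averaged and unweighted
at every stage: class scores → image score (mean over foreground classes),
image scores → group level mean, and the fairness statistics act on the
per-level error rates `1 − s_g`:

* `SER = max_g e_g / min_g e_g`, defined as 1.0 when all groups have zero
  error, and an error (infinite ratio) when exactly one group is perfect;
* `SD` = population (÷ g) standard deviation of the `e_g`. Population
  normalization is what reproduces the published SD column (printed errors
  0.124/0.133 give 0.0045 ≈ printed 0.004; a sample SD would print 0.006).

Replication of the published fairness columns from their printed per-group
scores (96 rows embedded in `fairseg.tables`) reproduces SD everywhere to
print precision and SER within ±0.02 on 95 of 96 rows. The single exception
prints per-level Dice 0.960/0.959 with SER 1.002: its errors recompute from
the 3-decimal inputs to 0.040/0.041 → 1.025. With group errors near 0.04, a
half-ULP (0.0005) input rounding moves the ratio by up to ~0.025, so that
printed value is recoverable only from unrounded scores; the replication
test asserts the ±0.02 band and therefore fails on exactly that row, by
design rather than by bug.

## 5. Significance testing

A single audit yields one SER per model, so replicate SER values are
produced by a within-group bootstrap over test images (default B = 1000):
each replicate resamples images with replacement inside every level,
recomputes level mean errors, and takes max/min. Replicates in which one
level's resampled error is exactly zero while another's is not would be
infinite and are redrawn (logged). Baseline and candidate replicate samples
are compared with a one-sided Welch (unequal-variance) t-test of
H₁: mean SER_baseline > mean SER_candidate at α = 0.05; identical replicate
vectors are defined as p = 1. Under a paired null — two independently seeded
bootstrap samples from the *same* score set — the test rejects at the
nominal rate (measured 5.0% over 1000 repetitions). The bootstrap protocol
is this package's own choice of replication unit; published p-values
obtained under an unreported protocol are not expected to reproduce
numerically, only the decision rule (reject iff p < α) is.

## 6. The bias-injection experiment

`run_bias_experiment` is the end-to-end study: a knee cohort of 240 phantoms
(70/30 White vs Black/African-American, sex and age balanced within race;
~204 train / 36 validation after an 85/15 split stratified by all
attributes), δ = 0.5 applied to the minority race, a 1/8-width stem-free
model trained 5 epochs per strategy, and an audit on a dedicated
composition-balanced test cohort of 40 phantoms (20 per race, rendered under
the same phenotype rules). The balanced test set is a measurement choice: it
makes the two group means equally precise and keeps test-set composition out
of the group difference, so under δ = 0 the SER fluctuates around 1 from
sampling noise only.

At the study seeds (1–5) the experiment gives mean SER ≈ 1.19 for the
baseline under δ = 0.5, ≈ 1.06 for balanced, ≈ 1.12 for stratified, and
≈ 1.05 for the baseline on an unbiased (δ = 0) cohort. Two properties of
these numbers deserve emphasis:

* **SER is ratio-noisy when errors are small.** With group errors around
  e ≈ 0.1 and per-image score SD s, the null SER concentrates around
  1 + 0.25·s/e·√(40/n); well-converged runs (small e) therefore inflate SER
  even without bias. This is a property of the metric, not of the models.
* **The stratified effect is weak at this scale.** Balancing by
  undersampling reduces SER dramatically and consistently (largely by
  retracting the majority group's convergence — the fairness/accuracy
  trade-off). Stratified batching helps on average at the study seeds but
  its effect is within seed-to-seed noise at desk scale, consistent with
  full-scale published results where stratified models are not uniformly
  fairer than baselines either.

## 7. What the testbed does and does not show

Passing tests demonstrate that the metrics, samplers, training loop,
auditing and significance machinery behave correctly and that the full
pipeline recovers an injected, known group difficulty gap and responds to
data-level mitigation. Phantoms are not radiographs: no projection physics,
soft tissue, osteophytes, positioning variation, scanner differences or
annotation ambiguity; the injected bias is one-dimensional (contrast) while
real group differences are structural; and the desk-scale absolute IoU/Dice
values (≈ 0.8–0.95 on phantoms) are not comparable to values reported for
clinical images at full scale. Results on this testbed validate the
*machinery*, not any claim about a particular clinical cohort.

## 8. Problem sizes used by the test suite and acceptance script

Unit and property tests run on 32–64 px phantoms in seconds. The end-to-end
suites use: the 240+40-phantom experiment above, five seeds (20 model
trainings, ≈ 6 minutes on one CPU); 1000 paired-bootstrap repetitions at
B = 200 for the significance calibration; all 65,536 4×4 binary masks for
the metric oracle; and a 4-image, 30-epoch overfit check (batch 1, lr 10⁻²,
Dice loss — the class-balanced loss, so the small patella is learned within
the step budget).
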