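# Methods

`rbcsmear` infers red-blood-cell (RBC) biophysical quality from thin-film
blood-smear images.  The package has two measurement ends.  At one end, a
microfluidic ratchet device sorts RBCs by deformability into twelve outlets
(7.5 µm constrictions at outlet 12 narrowing to 1.5 µm at outlet 1); the
per-sample **rigidity score (RS)** summarizes the sorted distribution.  At
the other end, Giemsa-stained smear scans are tiled into multi-cell patches
and a convolutional network learns to predict deformability labels — and
storage age — from morphology alone.  Because the underlying donor images
and sorting counts are not publicly deposited, a synthetic smear/sorting
simulator with pixel-accurate ground truth stands in for them, and every
claim the test suite makes is a claim about recovery of known synthetic
parameters, not about real blood.

## Rigidity score

For outlet counts $c_1..c_{12}$ with $N=\sum_k c_k$, the cumulative fraction
$F(k)=\sum_{i\le k} c_i / N$ is linearly interpolated through the anchor
$(0,0)$ and the nodes $(k, F(k))$.  The RS is the smallest $x$ with
$F(x)=0.5$.  Consequences of this convention:

* a distribution entirely in outlet $k$ gives $RS=k-\tfrac12$;
* on a segment flat at exactly 50 % the leftmost point is returned (the only
  reproducible choice);
* $RS\in(0,12]$, is invariant to scaling all counts, and never decreases
  when a cell moves to a more rigid outlet.

Deformability classes discretize RS with half-open intervals
$[0,2.50)$, $[2.50,2.75)$, $[2.75,3.00)$, $[3.00,\infty)$.  The printed
two-decimal class labels (e.g. "2.50–2.74") leave the continuum between
2.74 and 2.75 unassigned; the half-open convention is the exhaustive
partition consistent with them.  Binning uses the unrounded score.

## Tiling and filtering

Scans are cut into non-overlapping square tiles anchored at the top-left
corner; the right/bottom remainder is discarded (a 2424 px scan at 256 px
tiles yields 9×9 = 81 tiles with a 120 px margin dropped).  Two filters
follow:

* **empty filter** — a tile is dropped when its mean intensity deviates from
  a calibrated cell-free background reference by less than a relative
  tolerance (default 2 %; the desk-scale runs use 1.5 % because synthetic
  backgrounds are cleaner than real slides);
* **occlusion filter** — a tile is dropped when its largest foreground
  connected component (foreground = pixels darker than an Otsu or
  user-supplied threshold) exceeds 25 % of the tile area, a proxy for
  clumped, overlapping cells.  Both filters are per-tile predicates, so
  their order cannot change the result.

Selected tiles are subsampled per class into train/test splits (reference
quotas 10,000 / 2,000 per class) with 2,000 training tiles rotated through
five validation folds.  One integer seed drives subsampling, fold
assignment, and augmentation.  Augmentation is k·90° rotation plus random
horizontal flip — pixel permutations that preserve the intensity histogram.

**Normalization.** Mean/variance statistics are computed on the training
split only, and tiles are standardized *inverted*: the network consumes
$(\mu_{train}-x)/\sigma_{train}$, i.e. standardized optical density, so
stain carries positive signal and background sits near zero.  With the
conventional sign the stained pixels are the extreme negatives of the input
distribution and first-layer ReLUs systematically silence them, which both
slows learning and pushes input-gradient saliency onto the background; the
inverted sign makes cell pixels the propagating ones.

## Network

Input is one channel at 256×256 (desk scale: 64×64).  Five convolution
blocks — (256, 7×7), (128, 5×5), (64, 3×3), (32, 3×3), (16, 3×3), all
stride 1 with same zero padding, each followed by ReLU, batch
normalization, and 2×2/stride-2 max pooling — reduce the map to 8×8×16,
which flattens to 1,024 features.  Three fully connected blocks follow
(hidden widths 512 and 128, each with ReLU, batch normalization, 20 %
dropout — widths are not dictated by the architecture description, so a
taper from the 1,024-vector was chosen and is recorded in model metadata).
The head is a 3-way softmax (storage weeks), a 4-way softmax (deformability
bins), or one linear output (RS regression).  `channel_scale` multiplies
every channel count and `input_size` shrinks the input (both validated so
channels stay integral and five poolings stay possible); architecture
audits always run at scale 1 / 256 px.

The engine is implemented in numpy (float32, NHWC layout).  Convolutions
are evaluated either as a single im2col matrix product (narrow patch
matrices) or shift-by-shift as k² accumulated (C_in, C_out) products (wide
ones); both routes were verified against finite differences.  The backward
pass propagates gradients to the input, which is exactly what the saliency
module consumes.  The head layer is zero-initialized, so an untrained
classifier emits the uniform distribution and an untrained regressor the
(standardized) target mean; remaining weights are He-normal from the model
seed.

## Training protocol

SGD with 0.90 Nesterov momentum; learning rate within [0.001, 0.01]; 10–30
epochs; batch size 32 or 64; cross-entropy for classification, MSE for
regression (fitted on z-scored targets, predictions mapped back).  Training
stops early when the relative epoch-loss improvement stays below 10⁻³ for
three consecutive epochs.  Values outside these ranges are permitted but
warned about.  After the epoch loop, batch-norm running statistics are
recalibrated with one momentum-1 pass over up to 256 training tiles: after
short trainings the exponential running averages lag the weights badly
enough to corrupt evaluation-mode predictions.  All shuffling/augmentation
randomness derives from the config seed, so a rebuilt model with the same
seeds reproduces its history exactly.

Metrics: accuracy; precision/recall/F1 macro-averaged (the convention under
which the donor-generalization table's aggregate rows are the means of its
per-donor rows); row-normalized confusion matrices; MAE/MSE/RMSE, Pearson r
with p-value, and both R² conventions (coefficient of determination and
squared Pearson r), since the two differ on real tables.  Undefined
statistics (Pearson under zero variance, recall of an absent class) are
NaN-with-warning, never silent zeros.  Donor aggregates use the arithmetic
mean and the sample (n−1) standard deviation.  Regression errors are also
expressed as percentages of the observed RS span 2.30–3.56.

## Saliency

Vanilla input-gradient attribution: the absolute gradient of the target
score with respect to input pixels, max-normalized to [0, 1], computed in
evaluation mode.  For classification the pre-softmax logit is
differentiated (probability gradients saturate).  `cell_concentration_score`
measures the fraction of saliency mass inside the ground-truth cell mask
dilated by 2 px; a spatially uniform map scores the dilated-mask area
fraction, which is the natural chance baseline.  Input gradients of small
CNNs are noisy — max-pool argmax routing makes single-pixel paths — so the
concentration comparison is run over ≥100 tiles.

## Synthetic smears and sorting

Discocytes are discs with a radially symmetric central pallor (Gaussian
absorbance dip, depth 0.6).  Echinocytes modulate the boundary radius as
$r(\theta)=r_0(1+a\cos k\theta)$ — one cosine mode, $k$ spicules, default
amplitude 0.16 — with a 4× reduced pallor; real echinocyte spicules are
irregular, and this fidelity targets class separability, not photorealism.
Cells are placed by rejection sampling (Poisson counts, ~90 % of summed
radii minimum separation, candidates closer than that accepted with the
`overlap_rate` probability); stain intensity varies per cell, the
background level jitters per scan (sd 0.02, emulating illumination
variation between slides — and incidentally denying the classifier a pure
global-intensity shortcut), and Gaussian pixel noise is added.  Ground
truth records every cell's centre/radius/type plus a scan-level coverage
mask.

Sorting is simulated by drawing each cell's latent rigidity from
Normal(µ, σ) and discretizing with `outlet = clamp(ceil(latent), 1, 12)`;
the expected outlet probabilities and the RS of the expected cumulative
curve are available in closed form (clamped normal CDF), giving the
large-sample oracle the tests use.  Storage weeks map to echinocyte
fractions (defaults 0.05/0.35/0.70 for weeks 0/1/2 — the direction of the
storage lesion is established, the magnitudes are this package's choice),
and continuous RS labels follow the monotone link
$RS = 2.30 + 1.26\,p_e$, spanning the observed RS range.

## Desk-scale study conditions

Full-scale training (10,000 tiles/class at 256 px) is out of reach of a
test suite, so recovery experiments run at a fixed reduced scale
(`rbcsmear.desk`): 640×640 scans, 64 px tiles, ~8 cells per tile at ~7 px
radius, 8–16 spicules per echinocyte (fewer, larger spicules than at full
scale so the thorny boundary stays above the pixel sampling limit), a
1/8-width network.  Storage classification uses 300/60 train/test tiles per
class (lr 0.01, ≤15 epochs); RS regression uses five echinocyte levels
0.1–0.9 with 150/40 tiles per level (lr 0.005, ≤20 epochs) — five levels
rather than three because the donor cohort spans the RS range continuously
and a regression target needs that spread.  Under these conditions the
classifier recovers the storage class well above chance, the regressor
correlates with the true synthetic RS at r > 0.8, and trained-model
saliency concentrates on cells relative to both an untrained network and
the uniform baseline.

What passing these tests shows — and does not show.  They validate the
pipeline mechanics end to end: labels flow correctly from sorting
statistics to tiles, the network can extract morphological signal that is
present, and the evaluation arithmetic is right.  They do not certify
performance on real smears: synthetic cells are cleaner, spicules are
regular, staining chemistry, debris, white cells and platelets are absent,
and the storage→morphology link magnitudes are assumed.  The published
headline numbers on donor data (79 % deformability accuracy, r = 0.708,
89 ± 8 % / 78 % / 61 ± 7 % storage accuracies) are therefore treated as
fixed reference tables — their internal arithmetic is reproduced exactly —
not as reproduction targets.

## Numerical and degenerate-input choices

* Flat 50 % crossovers resolve leftmost; bins are half-open (above).
* Zero-count distributions, non-positive radii, quota shortfalls, unknown
  config keys, and wrong input shapes raise typed errors rather than
  propagating garbage.
* The placement sampler raises a saturation error when density and overlap
  limits are incompatible (60 attempts per cell).
* Max-pool ties resolve to the first maximum (argmax), deterministically.
* fp32 throughout; gradient tests use directional finite differences with
  correspondingly loose tolerances.
* Pipeline runs stamp a SHA-256 config hash into every artifact and expand
  the global seed into named per-stage substreams.

## Known limitations

* The numpy engine trains small models only; it is single-threaded BLAS
  matmul bound and has no GPU path.
* Input-gradient saliency is the simplest attribution method; its
  concentration margin over the uniform baseline is modest and
  seed-dependent on desk-scale models.
* Tile-level splits follow the reference protocol; tiles from one scan can
  land in both train and test.  A scan-level split mode would be the
  leakage-safe alternative and is noted as future work.
* The storage→echinocyte-fraction magnitudes and all renderer intensity
  parameters are stated choices, not fitted to data.
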