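# Methods

`renuseg` implements recursive self-training of a U-Net for simultaneous
nuclei detection and segmentation in H&E-stained pathology tiles whose
annotation is *incomplete*: only a subset of the true nuclei carry manual
outlines, and every unannotated nucleus would otherwise be presented to the
network as background. The package contains the full pipeline — synthetic
data generation, training-sample preparation, the network and its loss,
the recursive pseudo-labelling loop, and the evaluation suite — and runs
end-to-end on a single CPU with no external data.

## Training-sample preparation

**Positive patches.** A 64×64 px region of interest is extracted at each
annotated nucleus, centred at the integer-rounded centroid of its pixels,
and augmented by translating the window 16 px (a quarter of the side) up,
down, left and right — five patches per nucleus. Windows near the border
are shifted inward rather than padded, so every patch contains real
pixels. The target mask of a patch is the union of *all annotated* nucleus
pixels inside the window; unannotated nuclei remain background. This is
deliberate: it reproduces the labelling bias that the recursive stage is
designed to correct.

**Negative patches** come from acellular regions found on the red channel.
Eosin-stained extracellular material is brighter in red than
hematoxylin-stained nuclei, so pixels above an adaptive threshold

    t = a · mean(red) / std(red)

are candidate non-cellular foreground; holes are filled, small objects are
removed by a morphological opening (disk radius 20 px), every known
nucleus is excluded with a dilation margin (4 px), and non-overlapping
64×64 windows whose full footprint lies inside the remaining mask are
randomly cropped (targets all zero). In synthetic mode the complete ground
truth drives the exclusion, standing in for a visual review of the mined
regions.

A caveat worth documenting: `t = a·mean/std` is not intensity-scaled, so
with intensities in [0,1] the default `a = 0.5` only lands between the two
class means when the two pixel classes are roughly balanced. For
background-dominated images `mean/std` exceeds 2 and the threshold leaves
the intensity range, which the implementation logs before returning an
empty mask. The constant is therefore data-dependent and exposed in the
configuration; the synthetic study uses `a = 0.3`, chosen (once) exactly
the way one would calibrate it on real material — so that `t` separates
the class means — while the package default remains 0.5.

## Network and loss

The backbone is a conventional U-Net: a contracting path of blocks with
two 3×3 stride-1 convolutions (ReLU) followed by 2×2 max-pooling, feature
maps doubling per block (64→128→256→512 at the defaults); a bottleneck of
two convolutions with dropout (rate 0.5); an expanding path that
bilinearly upsamples ×2, concatenates the matching skip connection and
applies two convolutions, halving the feature maps; and a final 1×1
convolution with a sigmoid yielding a per-pixel nucleus likelihood.
Spatial input sizes must be divisible by 2^(number of blocks); inference
reflect-pads and crops automatically.

The loss is a weighted sum `L = w1·L_Dice + w2·L_BCE` with `w1 = 1`,
`w2 = 0.1`. The Dice term is the *soft* Dice loss evaluated on
probabilities with smoothing `ε = 1`,

    L_Dice = 1 − (2·Σ p_i g_i + ε) / (Σ p_i + Σ g_i + ε),

computed per patch and averaged over the mini-batch; the BCE term is the
per-pixel mean binary cross-entropy with probabilities clamped to
[1e−7, 1−1e−7] before the logarithms. Training uses mini-batches of 4
patches and Adam (moment decays 0.9/0.999, ε = 1e−8). The learning rate
is not prescribed by the method; the package default is 1e−4, and the
desk-scale study uses 1e−3 so that both loss terms decrease within its
short schedule — the same trend-based selection used to pick all training
lengths here.

Because no deep-learning framework is used, the network and its analytic
backward pass are implemented directly on numpy arrays (channels-last
float32, im2col + GEMM convolutions, numba-compiled gather/scatter and
pooling kernels with pure-numpy fallbacks). The gradients are verified
against central finite differences in the test suite. One numerical
subtlety: with zero-initialised biases, a ReLU unit whose entire
receptive field is inactive sits exactly at the kink; the backward pass
uses the conventional subgradient 0 there.

## Recursive pseudo-labelling

After the initial supervised stage (the *I-DL* model), the loop repeats:

1. Run the current model over every training image; binarise the
   likelihood map with Otsu's threshold (256-bin histogram; a constant
   map yields an empty foreground), then apply a morphological opening
   with a 5 px disk.
2. Measure every 8-connected component: area `A`, sub-pixel outer contour
   length `P` (marching squares at level 0.5, one 3-point moving average
   over the closed polyline to remove the ~5 % staircase overestimate —
   pixel-edge counting would give roundness ≈ 0.62 for ideal disks and
   reject circular nuclei), convex-hull area `CA`, roundness
   `Rdn = 4πA/P²` and solidity `S = A/CA`.
3. Accept components with `Rdn > 0.7` and `S > 0.9` as high-quality
   pseudo-labels. Candidates with IoU ≥ 0.5 against any nucleus already
   in the positive set are skipped as duplicates (without this rule the
   pool would refill with copies of its own labels and the termination
   ratio would lose meaning).
4. Each accepted object contributes five augmented patches (targets: its
   own mask united with every current positive nucleus inside the
   window); the negative pool is never touched.
5. If the number of newly accepted nuclei is below 20 % of the current
   positive count the loop stops *without* retraining; otherwise the
   model is retrained on the grown pool and the loop continues, up to a
   hard cap of 3 iterations.

Retraining warm-starts from the current weights by default (a cold-start
mode exists); each retraining gets its own derived seed. The model after
the loop is the *R-DL* model.

## Evaluation

A reference nucleus is *detected* when the best-overlapping segmented
object reaches an overlap ratio (Jaccard/IoU) of `T = 0.5`; the threshold
is applied inclusively (`≥`), with a strict mode available, and ties on
the overlap break toward the smaller object id. Sensitivity is detected
references over all references, pooled over images. Per-object Dice and
Jaccard are averaged (mean ± sd) over matched pairs with IoU ≥ 0.5 only.
The Aggregated Jaccard Index assigns, per ground-truth instance in label
order, the still-unused prediction with the largest IoU, and divides the
summed intersections by the summed unions plus the areas of never-used
predictions. The detection suite reports precision, recall and F1 at each
IoU threshold in {0.50, 0.55, …, 0.95}; since a thresholded likelihood
map provides no confidence ranking, the reported mAP is the mean of the
precision values over that grid. Both AJI and Otsu binarisation are
checked against independent brute-force oracles in the test suite.

## Synthetic data

The generator emulates the aspects of H&E tiles that the pipeline
actually consumes:

- **Colour separation.** Nuclei dark (red mean 0.15), extracellular
  background bright (red mean 0.85), per-channel Gaussian noise
  (sd 0.15), clipped to [0,1]. Hematoxylin uptake varies between cells:
  each nucleus draws an intensity shift (sd 0.15, capped 0.2 below the
  background mean), so a tail of pale nuclei is genuinely hard to
  separate from background — without this heterogeneity the task
  saturates and the incomplete-annotation handicap never manifests.
- **Geometry.** Nuclei are filled ellipses, long axis ~ N(32, 5) px (the
  typical cancer-nucleus diameter at 40×), axis ratio uniform in
  [0.5, 1], random orientation, non-overlapping with a 2 px gap by
  default.
- **Tissue layout.** Nuclei cluster in nests around a few centres
  (~8 nuclei per cluster, spread sd 24 px), leaving acellular stretches —
  this is what gives red-channel negative mining something to find; a
  uniform mode exists.
- **Incomplete annotation.** A seeded uniform subsample of instances is
  kept (round(fraction · n)) and relabelled consecutively.

Not modelled: chromatin texture, stain physics, out-of-focus blur,
overlapping nuclei, whole-slide pyramids. Passing the synthetic study
therefore demonstrates that the *mechanism* works — pseudo-labels recover
unannotated nuclei and feed back into training — not that the printed
accuracies on real breast-cancer tiles are reproduced.

## The desk-scale study

`renuseg.experiments.scaled_recursive_experiment` reproduces the design
of the full-size experiment at laptop size: 20 training tiles of 256×256
px with ~25 nuclei each (≈500 true nuclei), 25 % of annotations kept
(≈120), four mined negative windows per tile (the per-area rate of the
full-size setup), a reduced U-Net (2 blocks, 8 base feature maps), 12
initial epochs and 3 warm-start epochs per recursive iteration — both at
the plateau of the training-loss curve for this problem size — and at
most 3 recursive iterations. Ten held-out tiles with complete ground
truth measure detection sensitivity and matched-pair Dice for the initial
versus the recursively trained model. Every random stream derives from
one integer seed plus a stage tag, so a run is bit-reproducible.

Typical behaviour: the first iteration accepts ≈330–380 pseudo-labels
(most of the unannotated nuclei), the second iteration finds almost
nothing new and the 20 % rule stops the loop; held-out sensitivity of the
initial model lands around 0.88–0.99 and the recursive model matches or
improves it. A known failure mode of self-training is visible at the
margins: once almost every nucleus is a positive, the few remaining
unannotated ones are reinforced as background, which can cost the
recursive model an occasional detection when the initial model is already
near ceiling.

## Known limitations

- The numpy network trains at roughly 25–40 ms per mini-batch on one CPU
  core; the full-size configuration (4 blocks, 64 feature maps, hundreds
  of epochs) is far out of reach, which is why the study above is the
  unit of experimentation.
- The negative:positive patch ratio of the full-size setup (≈10:1) cannot
  be realised on 256² tiles; the per-area mining rate is kept instead.
- Pseudo-label masks are network segmentations, not manual outlines;
  boundary conventions of the two sources differ slightly.
- `t = a·mean/std` requires a data-dependent `a` (see above).
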