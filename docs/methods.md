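# Methods

`oraltils` implements a two-stage procedure for grading tumour-infiltrating
lymphocytes (TILs) in H&E histology of oral squamous cell carcinoma, plus
the evaluation machinery used to compare model variants. This note records
the model, the choices that were genuinely open, the numerical details, and
what the synthetic experiments do and do not demonstrate.

## Stage I — cellular density maps from weak supervision

**Model.** `TILSegMobileViT` maps an RGB tile to (a) per-pixel
probabilities over five classes — background, tumour nucleus, TIL nucleus
(lymphocyte or plasma cell), stromal nucleus, other/ambiguous — and (b) a
predicted distance map. The encoder is a hybrid convolution/transformer
(MobileViT-style): inverted-residual blocks interleaved with transformer
blocks that attend across 2×2-patch positions, emitting features at strides
2–32. The decoder mirrors it with five stages of 3×3 transposed-convolution
upsampling, additive attention gates on the skip connections
(`psi = σ(W_ψ·relu(W_x x + W_g g))`, the gate multiplying the skip), and a
3×3 depthwise-separable convolution (depthwise + pointwise + batch norm +
ReLU) per stage. The main head is a 1×1 convolution with softmax, the
auxiliary head a 1×1 convolution with sigmoid.

**Loss.** `L = λ₁·MSE(d̂, d) + λ₂·(focal + dice)`, λ₁ = λ₂ = 1. Focal loss
uses γ = 2, α = 0.25 (the standard defaults; the source recipe names the
loss without parameters). Dice is macro-averaged over all five classes,
background included (configurable to foreground-only); smoothing constant
10⁻⁶. The distance target is the Euclidean distance transform of the
binarized cellular foreground, normalized by the per-patch maximum — nucleus
centres near 1, boundary pixels near 0 — which penalizes probability mass
that bleeds across touching nuclei. The normalization matches the sigmoid
range of the auxiliary head. (The alternative reading, distance measured
*from* background pixels, contradicts the requirement that cell pixels carry
the signal; the foreground reading is the only self-consistent one.)

**Weak supervision.** After pretraining on a labelled source domain the
model labels the unannotated target domain itself: per pixel the argmax
class is kept only when its probability exceeds τ = 0.95, sub-threshold
pixels fall back to background (keeping dense targets; filtering happens at
patch level), patches with a confident cellular fraction below 1% are
dropped, and distance targets are recomputed from the pseudo-masks so both
heads see consistent supervision. Fine-tuning unfreezes only the last 20
entries of the flattened layer list (counted from the output backwards),
adapting stain statistics without forgetting shape priors. Early stopping
watches validation *total* loss (the metric was an open choice; total loss
is what training optimizes) with patience 8.

**Density maps.** Predicted masks render under a fixed palette: tumour red
(255,0,0), TILs green (0,255,0), stroma dark pink (255,20,147), background
and "others" black. Rendering is bijective on the three scored classes.
Large fields of view are tiled at 256, tiles resized to the network input
(bilinear for intensities), predictions rendered and resized back with
nearest-neighbour interpolation (categorical colours — no invented hues),
and stitched; grid margins stay black.

## Stage II — joint-representation TIL grading

Fields of view are graded into three classes following the lymphocytic-
infiltration nomenclature of Broders-style grading: *none to very less*,
*slight*, *moderate to marked*. Two encoders see complementary views:
`phi_img` the raw tile (tissue architecture), `phi_cell` the rendered
density map (cellular composition). Each is pretrained as a standalone
classifier (GAP → Dense(64) → dropout 0.3 → Dense(3, softmax) head). The
fusion module pools both feature maps globally, aligns the cell vector to
the image width with a 1×1 convolution, sums them (`g_join`), derives
attention weights by a 3×3 convolution + sigmoid, modulates the cell-branch
feature map with those weights, and applies a 256-filter 1×1 convolution
with batch norm. The head on the fused map outputs the three class
probabilities; training is cross-entropy with encoders frozen.

Open choices resolved here: the attention weights are *channel-wise* and
broadcast over the spatial grid — the pooled global vectors admit no other
consistent shape; `phi_cell` consumes the RGB rendering of the density map
(not label indices), so both branches share the same input format; class
weights are inverse frequency, `w_c = N/(K·n_c)`; "rotation (horizontal and
vertical)" augmentation is implemented as flips, applied jointly to both
modalities, while photometric jitter (brightness ±20%, HED-space stain
perturbation σ = 0.02) touches the raw image only — density-map colours are
categorical.

## Evaluation machinery

* **IoU / Dice** per class on pixel sets; both defined as 1 when the class
  is absent from prediction and reference alike. Dice = 2·IoU/(1+IoU) holds
  identically and is property-tested.
* **Generalization test**: a patch is labelled by its most abundant
  predicted nucleus class (ties break tumour < TILs < stroma) and compared
  with region labels; per-class tables report accuracy = recall (the
  one-vs-rest convention in which the per-class "accuracy" of a class is
  the fraction of its samples retrieved), precision, and F1, with micro
  accuracy and support-weighted averages overall.
* **Self-consistency test**: predictions on original versus perturbed tiles
  (horizontal flip — inverted before comparison — or seeded Gaussian
  noise), scored by macro IoU over classes present in either mask and by a
  *single-window* SSIM over the rendered maps: global means, variances and
  covariance with C₁ = (0.01·255)², C₂ = (0.03·255)². The sliding-window
  SSIM variant is deliberately not used; the printed formula is global.
* **Entropy-weighted TOPSIS**: criterion weights from column-share entropy
  (p_ij = x_ij/Σx_ij, w_j ∝ 1−E_j), TOPSIS with vector normalization
  (r_ij = x_ij/‖x_j‖₂), benefit criteria only, closeness C = D⁻/(D⁺+D⁻),
  ties in rank broken by input order. Vector normalization reproduces the
  published ranking scores to three decimals on the bundled reference
  blocks; min-max normalization is available behind a flag but does not.

The package ships the published 12-configuration × 4-criterion metric
blocks (three infiltration categories plus overall) as CSV so the ranking
is reproducible offline; `scripts/acceptance.py` recomputes it end to end.

## Synthetic data: what it emulates, what it does not

No real slides ship with the package, so a seeded generator produces
histology-*like* data: eosin-pink background with Gaussian pixel noise;
tumour (large violet), TIL (small round dark-blue) and stromal (elongated
pale) nuclei as rotated ellipses with mild sinusoidal boundary
perturbation; a 1% "others" class so all five labels occur in training;
exact masks and distance maps. Per-class pixel fractions are controlled to
about one nucleus area (realized error ≤ 0.03, tested over 100 seeds);
overlaps resolve by draw order with mostly-overlapping candidates rejected.
Large fields of view are grids of tiles whose TIL-pixel fraction determines
the grade; band edges default to (0.02, 0.10) of pixels — the grading
literature gives no quantitative definition, so the bands are configurable
and the defaults were fixed once at values that make the three grades
visually distinct.

The *fusion benchmark* embeds a controlled complementarity signal: TIL
fraction is low for class 0 and identically high for classes 1 and 2; a
brightness-stripe texture marks class 2 only; TIL nuclei are painted in the
stroma colour and the stroma fraction is padded so total nucleus area
matches across classes. Consequently the density map separates {0} from
{1,2}, the raw image separates {2} from {0,1}, and only fusion can resolve
all three — the construction under which "fused ≥ best single modality" is
a falsifiable claim rather than an artefact of one modality dominating.

What passing these tests shows: the architecture has the capacity to fit
the task, gradients flow as designed, the weak-supervision loop improves
cross-domain segmentation, and the fusion mechanism exploits complementary
modalities. What it does not show: performance on real H&E slides — the
generator has no stain variability worth the name, no scanner artefacts, no
out-of-focus regions, no nuclear pleomorphism, and its colour-separable
classes are far easier than real nuclei.

## Numerical and engineering choices

The networks run on a small reverse-mode automatic-differentiation engine
over numpy written for this package (`oraltils.nn`): float32 throughout,
im2col convolutions, transposed convolution built compositionally as
dilation + flipped-kernel convolution, batched matmul attention. All
weights draw from one seeded generator after model construction, dropout
generators are spawned from the same seed, and training loops shuffle with
seeded generators — identical (config, seed) runs are bit-identical, which
the suite asserts. Gradients of every primitive are checked against central
finite differences.

Problem sizes in the tests and examples are desk-scale by design: encoder
width presets `tiny`/`micro` (the `xs`/`s` presets approximate the
published width schedule; the builder reports its exact parameter count so
users can calibrate against the published total of 10,497,540, which the
reduced presets intentionally do not match), 64×64 segmentation tiles,
128×128 fields of view, 32×32 classifier inputs, tens-to-hundreds of
samples, and learning rates up to 0.005–0.01 where the published 0.001
would need many more epochs than a demonstration warrants. The YAML config
defaults keep the published recipe (Adam, α = 0.001, batches 8/16,
patience 8); the demo profiles override sizes, not semantics.

## Known limitations

* The encoder follows the published block structure but not a
  layer-for-layer replication of any specific MobileViT release; parameter
  totals differ from the published count.
* Single-window SSIM saturates near 1 for images that share global
  statistics; it is a coarse consistency measure by construction.
* The entropy-weight error raised when *all* criteria are constant is a
  genuine undefined case; a single constant criterion simply gets weight 0.
* WSI pyramid formats (SVS/NDPI) are out of scope; inputs are ordinary
  rasters (PNG/TIFF/JPEG).
* At desk scale the stage-II classifiers sit far from their real-data
  operating point; their absolute accuracies are meaningful only relative
  to each other within one seeded experiment.
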