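# Methods

`skeltube` implements a skeleton-guided 3D convolutional segmentation
method for branching tubular structures (airways, vessels), together
with the loss theory that motivates it, the skeleton ground-truth
preparation it requires, and the centerline-based metrics used to judge
it. This note records the model, the choices that were genuinely open,
and what the synthetic validation does and does not show.

## The segmentation model

The network has two streams operating on a normalized grayscale patch.

**Main segmentation stream.** A 3D encoder–decoder with skip
connections. Each of the three encoder levels applies two 3×3×3
convolutions followed by 2×2×2 max pooling; channel widths double per
level from `base_channels` (default 8 at desk scale; widths are fully
configurable since they are a free design axis). The decoder mirrors
the encoder with 2×2×2 transpose convolutions; after each upsampling
the decoder concatenates the matching encoder features — plus the
skeleton-stream features where available — and applies two more
convolutions. A final 1×1×1 convolution and sigmoid produce the
segmentation likelihood `p`.

**Skeleton-guided stream.** Two skeleton-guided blocks attached to the
two deepest encoder outputs (configurable via `sg_levels`). Each block
applies a residual block (two 3×3×3 convolutions with identity skip)
to its stream input `t_in`, then a skeleton-attention block computes

    A = sigmoid(ReLU(Conv_1x1x1(t) + Conv_1x1x1(f_in)))

from the stream feature and the encoder feature `f_in`, and gates the
stream: `out = A ⊙ t`. Since ReLU output is non-negative, every
attention value lies in [0.5, 1). The gated map is upsampled with a
transpose convolution and propagates to the next block; the stream's
own head (transpose-conv upsampling with a 3×3×3 convolution per step,
then 1×1×1 + sigmoid) predicts the skeleton likelihood `p̂` at patch
resolution.

Decoder ordering follows standard U-Net practice (upsample →
concatenate → convolve); ordering the convolutions before the
upsampling cannot produce a full-resolution output in the last block.

### Stabilization choices

Two choices depart from the plainest construction; both were adopted
after the plain construction collapsed or stalled for roughly one in
three weight initializations when trained jointly with the skeleton
loss on a CPU:

- **Leaky ReLU (slope 0.01) in all conv blocks.** The attention
  equation keeps exact ReLU — the [0.5, 1) bound depends on it — but
  the block activations are a free choice. The strongly imbalanced
  skeleton loss drives large one-sided gradients early in training;
  plain ReLU encoders can die wholesale under them.
- **Per-channel standardization of skeleton features before decoder
  concatenation.** The skeleton stream's feature scale drifts as the
  skeleton loss reshapes it; injecting unnormalized features
  destabilizes the shared encoder for some initializations. Only the
  full model has this path, so the ablation arms stay comparable.

The prediction heads initialize their bias to −3.5, the log-odds of a
~3 % foreground fraction typical of tubular masks; starting near the
class prior removes a long burn-in in which the background term of the
losses dominates.

Normalization inside conv blocks is off by default (`norm="none"`);
instance normalization is selectable and, at batch size one, also
serves as the batch-norm option.

## Loss family and gradient-ratio theory

For likelihoods `p_i ∈ (0,1)` (clamped to `[1e−6, 1−1e−6]`) and binary
ground truth `g_i`:

    L_D  = 1 − 2Σp·g / (Σp + Σg)                      (Dice)
    L_T  = 1 − Σp·g / (αΣp + βΣg),   α + β = 1        (Tversky)
    L_ST = 1 − Σσ(γ(p−0.5))·g / (αΣp + βΣg)           (sigmoid-adaptive Tversky)

The *gradient ratio* R is the magnitude ratio of a foreground voxel's
loss gradient to a background voxel's. Differentiating the quotients
gives exact closed forms for **any** foreground voxel, not only the
symmetric case:

    R_D  = 2/(1 − L_D) − 1
    R_T  = (1/α)·1/(1 − L_T) − 1
    R_ST = γσ'(γ(p_f − 0.5))/α · 1/(1 − L_ST) − 1

(for Dice, e.g., ∂L/∂p_f = −2[(Σp+Σg) − Σp·g]/(Σp+Σg)² and
∂L/∂p_b = 2Σp·g/(Σp+Σg)², whose ratio simplifies to R_D). The test
suite verifies all three against central finite differences of the
implemented losses at 1e−5 relative tolerance; this is the package's
core correctness oracle.

The practical reading: as Dice loss shrinks, R_D → 1 and sparse
foregrounds (a one-voxel-thick skeleton) get eroded by the surrounding
background gradients. Tversky raises the ratio globally via α; the STL
makes it *voxel-adaptive* — the factor γσ′(γ(p_f−0.5)) peaks at
likelihood 0.5, so exactly the uncertain voxels receive the steepest
gradients. Two consequences worth knowing:

- STL never reaches zero: a perfect prediction leaves `1 − σ(γ/2)`
  (≈ 0.0293 at γ = 7).
- STL is not monotone over all of (0,1): for α = 0.1, γ = 10 its
  single-voxel loss curve turns upward near p ≈ 0.96, where
  γ(1−σ)·den < α. The default curve grid spans 0.05–0.95, inside the
  clamped likelihood range, where all three curves are non-increasing.

The training objective is `L_D(p, g) + w·L_ST(p̂, ĝ)` with `w = 1` by
default; `w` is exposed (`skel_weight`) because down-weighting the
skeleton term is the natural lever against false positives.

Default STL parameters are α = 0.01, β = 0.99, γ = 7. The
loss-curve utility defaults to the comparison setting α = 0.1,
β = 0.9, γ = 10.

## Skeleton ground truth and branch decomposition

Skeletons are computed once per case by the deterministic 3D thinning
of Lee et al. (`skimage.morphology.skeletonize`, `method="lee"`),
which preserves topology and yields bit-identical results across runs.
(Foreground/background adjacency conventions for 3D thinning are
stated inconsistently across the literature — 6/26 versus the more
common 26/6; the implementation relies on the thinning algorithm's own
topology-preservation test rather than re-deriving one.) Patches
crop the cached full-volume skeleton; they are never re-thinned per
patch, since re-thinning a
crop would change the supervision stochastically.

Bifurcation points are skeleton voxels with ≥ 3 skeleton neighbors in
the 26-neighborhood. Adjacent bifurcation voxels are merged into one
cluster before removal, so a "Y" yields exactly three branches even
when thinning leaves a two-voxel junction. Branches are the
26-connected components of the skeleton minus bifurcation clusters;
bifurcation voxels belong to no branch, keeping branches disjoint.
Connectivity is evaluated in index space (the metrics are voxel-count
based); anisotropic spacing is carried only for I/O.

## Metrics

- **Tree length detected rate** TR = Σs·p̂ / Σs — the fraction of
  ground-truth skeleton voxels covered by the binarized prediction
  (threshold 0.5, ties map to foreground).
- **Branch detection rate** BD = mean over branches of
  ⌊covered/total⌋ — implemented with the floor taken literally, so a
  branch counts only at full coverage. Because that rule is unusually
  strict, a `coverage` option relaxes it to a fractional threshold
  (0.8 is common practice); the default stays literal.
- **Precision / recall / F-measure** over voxel-wise TP/FP/FN, with
  zero-denominator cases reported as 0.

Branch voxel sets are skeleton-branch voxels, not volumetric regions.
Evaluation is whole-volume after sliding-window stitching, never per
patch. BD ≤ TR is *not* an identity and is not asserted; what does
hold is monotonicity of BD in the detection rule.

## Training and inference pipeline

Per-case min–max normalization to [0, 1] (a constant volume maps to
zeros). Patch sampling is seeded; with probability `fg_bias` (default
0.8) a patch is centered on a random foreground voxel, otherwise its
origin is uniform; no data augmentation. One global seed fans out to
weight initialization and patch sampling.

`TrainConfig` defaults to the stepped-SGD protocol: initial learning
rate 5e−4 halved every 20 epochs, 90 epochs, momentum 0.9, no weight
decay. Adam is available as a config switch and is what the
desk-scale experiments use: the α-weighted background term of the
skeleton loss produces per-voxel gradients around 1e−4, which
plain SGD needs far more iterations to integrate than a single CPU
affords. Optional global gradient-norm clipping (`grad_clip`) guards
multi-case runs; note it is counterproductive for single-patch
overfitting tests, where the true gradient is large.

Inference tiles the volume at the training patch size with fractional
overlap (default 0.5), averaging overlapping sigmoid likelihoods —
stitched values stay in (0,1) and are invariant to tile order. Volumes
smaller than the patch are reflect-padded and cropped back.
Checkpoints are a single `.npz` holding weights, network spec, train
config and seed; a save/load round trip reproduces predictions
bit-for-bit.

The network and its training are implemented on a compact numpy
reverse-mode engine (`skeltube.nn.autograd`) — convolution, transpose
convolution, max pooling, the attention gate and the optimizers are
all first-party code, validated against numeric gradients in the test
suite.

## Synthetic phantoms: what they emulate and what they don't

`PhantomSpec` grows a random binary tree of straight tube segments.
Radii taper geometrically per generation (default root 2.5 voxels,
taper 0.6, floored at 1 voxel), so distal branches are genuinely thin
— the trunk/distal imbalance that motivates the method. Child
directions deviate by 25–50° at random azimuths; segment lengths
shrink with the same taper so depth-3 trees fit a 48³ grid. The image
is bright tube (0.8) on dark background (0.2) with additive Gaussian
noise (σ = 0.15, i.e. tube-to-background contrast of 4 σ); directions
that would leave the grid are re-drawn deterministically, then
shortened, and only then is a geometry error raised. The mask is the
exact union of capsules (voxel centers within the radius), the
centerline is the analytically discretized segment set, and both are
therefore ground truth by construction, not by annotation.

Not emulated: curved or anatomically realistic branches, radius noise,
stenoses, contrast agents, CT reconstruction artifacts, anisotropic
acquisition. Passing the phantom experiments shows the pipeline learns
thin, noisy, branching structures end-to-end and that the metrics
behave; it does not certify clinical-image performance.

## Desk-scale experiment

Training at clinical CT scale (thousands of 128×128×64 patches, 90
epochs on a GPU) is out of reach on one CPU, so `skeltube.experiments` pins one
scaled-down protocol: 8 training and 2 held-out phantoms of 48³,
patches of 24³, 4 patches per case per epoch, Adam at 1e−3 halved
every 12 of 24 epochs, gradient clip 1.0, `base_channels=8`. Under
these conditions the full method reaches TR ≳ 0.94, relaxed-BD ≳ 0.85
and F ≳ 0.93 on held-out phantoms across seeds.

One caveat reported honestly: at this problem size the plain
encoder–decoder ablation arm (`use_skeleton_stream=False`) already
reaches ~0.98 TR, so the skeleton stream's advantage — a sub-point
effect in the reference setting — is smaller than seed-to-seed noise
here, and the full model does not systematically exceed the ablation
arm on phantoms. The ablation arms remain first-class configuration
switches (`use_skeleton_stream`, `skel_loss ∈ {stl, tversky, dice}`)
for study at larger scale.

## Known limitations

- Single-patch (batch-size-one) training only; no multi-GPU, no DICOM.
- The numpy engine is adequate for desk-scale volumes (≈0.5 s per
  24³-patch training step) but is not a route to CT-scale throughput.
- BD with the literal floor is extremely sensitive to single missed
  voxels on long branches; prefer the relaxed coverage for small
  studies and report both.
- The STL adapts gradients only through the scalar likelihood; regions
  of confidently wrong prediction (p ≈ 0 on foreground) receive small
  σ′ weight, which can slow recovery from early mistakes.
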