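# Methods

## Problem and model

The package segments glioma sub-regions from 4-modality 3D MRI (T1,
T1-CE, T2, FLAIR) into the BraTS label set {0 background, 1
necrotic/gangrene core, 2 peritumoral edema, 4 enhancing tumor},
evaluated on the nested regions ET = {4} ⊆ TC = {1,4} ⊆ WT = {1,2,4}.

The network is a V-Net-shaped encoder/decoder ("AGSE-VNet"):

- **Encoder stage** — `convs_per_block` (2 by default) 3×3×3
  convolutions, each followed by instance normalization, ReLU and
  dropout; a residual addition of the stage input (projected by a
  1×1×1 convolution when channel counts differ); a
  squeeze-and-excitation (SE) block; then a stride-2 3×3×3 convolution
  that halves every spatial dimension and doubles the channels.
- **SE block** — squeeze: per-channel global average
  `z_c = mean(U_c)`; excitation: `s = σ(W₂ δ(W₁ z))` with reduction
  factor `m = 4` (`W₁ ∈ R^{C/m×C}`, `W₂ ∈ R^{C×C/m}`, no biases);
  rescale `x̃_c = s_c u_c`.
- **Decoder stage** — a stride-2 2×2×2 transposed convolution that
  exactly doubles resolution and halves channels; an attention-guided
  filter (AG) that fuses the matching encoder feature; concatenation of
  the two paths, `convs_per_block` convolutions, and a residual
  addition of the upsampled feature.
- **Head** — 1×1×1 convolution to 4 channels and a voxelwise softmax.

## Attention-guided filter

The AG module treats the encoder skip feature as a *guidance* image and
the low-resolution decoder feature as the image *to be filtered*. A
learned 1×1×1 projection reduces the skip feature to a single-channel
guidance map `I`; average pooling matches it to the decoder resolution
(`I_l`). An attention block — 1×1×1 convolutions on `O` and `I_l`,
elementwise sum, ReLU, 1×1×1 convolution, sigmoid — yields a
single-channel attention map `T ∈ (0,1)`.

Per window `w_k` of radius `r`, the filter coefficients solve the
weighted ridge regression

    min_{a_k,b_k}  Σ_{i∈w_k} [ T_i² (a_k I_i + b_k − O_i)² + ε a_k² ]

whose closed form (with `w_i = T_i²`, per-window sums `S_·`, and the
per-voxel penalty summed over the |w_k| in-bounds voxels) is

    a_k = (S_wIO − S_wI S_wO / S_w) / (S_wII − S_wI² / S_w + |w_k| ε)
    b_k = (S_wO − a_k S_wI) / S_w .

With `T ≡ 1` this reduces *exactly* to the classical unweighted guided
filter, which reconciles the weighted objective with the unweighted
closed form sometimes quoted for it; the `attention=False` mode selects
the unweighted form explicitly. Per-voxel coefficients `(A_l, B_l)`
average `(a_k, b_k)` over every window containing the voxel; windows
are truncated at volume borders with true in-bounds counts. All window
sums are box filters (`scipy.ndimage.uniform_filter`), so the cost is
independent of `r`. Coefficients are computed per channel of `O`
against the shared single-channel guidance, are upsampled trilinearly
(half-pixel convention) and applied as `Õ = A_h ∘ I + B_h`.

Defaults `r = 16`, `ε = 0.1²`. Inside the trainable layer a floor of
1e-6 is added to `S_w` so saturated attention maps cannot produce a
vanishing denominator in float32; the reference numpy path omits the
floor and is the one checked against the brute-force per-window oracle.

## Loss

Per class `c`, soft Dice with the squared-sum denominator

    D_c = (2 Σ p_i g_i + s) / (Σ p_i² + Σ g_i² + s)

and total loss `−Σ_c w_c D_c` with weights (0.1, 1, 1, 1) over
(background, gangrene, edema, enhancing); a perfect prediction scores
−3.1. The squared denominator is chosen over the plain `|P|+|G|` form
so the loss is exactly the antiderivative of the closed-form per-voxel
gradient

    ∂D/∂p_j = 2 [ g_j (Σp² + Σg²) − 2 p_j Σpg ] / (Σp² + Σg²)² ,

which the tests verify against central finite differences and against
the autodiff tape. The smoothing constant defaults to 1e-5 (empty
classes in a patch); smooth = 0 is retained for the oracle tests, where
an all-empty class is an error rather than silently 0/0. Weights act as
an absolute weighted *sum* (so the printed weight vector is meaningful
as-is); a weighted-mean reduction is available. Batches are reduced by
averaging per-item losses, matching per-case evaluation.

## Numerical engine

No deep-learning framework is used: `agsevnet.autograd` is a small
reverse-mode autodiff engine over numpy arrays (channels-last rank-5
tensors) with exactly the primitives the architecture needs — strided
3D convolution and transposed convolution (offset-loop matmuls), 2×
average pooling, 2× trilinear upsampling, truncated box-window sums
(self-adjoint), channel softmax, instance-norm building blocks,
inverted dropout, and Adam. Every primitive's gradient is
finite-difference tested. Network weights are float32 with He
initialization; oracle computations run in float64.

## Evaluation metrics

Per region: Dice = 2TP/(FN+FP+2TP), Sensitivity = TP/(TP+FN),
Specificity = TN/(TN+FP), and HD95. Surfaces are 6-connectivity
boundary voxels (mask voxels with a background face-neighbor; the
outside of the array counts as background); directed distances are
spacing-scaled Euclidean nearest-neighbor distances (k-d tree), and
HD95 is the max of the two directed 95th percentiles — percentile 100
gives the classical sup-inf Hausdorff distance. Conventions, all
surfaced as flags in the report: both masks empty → Dice 1, HD95 0;
exactly one empty → Dice 0, HD95 = volume diagonal (sentinel); a
reference without negatives leaves specificity at 1.

## Synthetic phantoms

A phantom is a "brain" ellipsoid of normal tissue (air outside, so the
nonzero-masking z-score policy is exercised) containing three
concentric tumor ellipsoids with strictly decreasing radii: edema shell
(2) ⊃ necrotic shell (1) ⊃ enhancing core (4). Ellipsoids are chosen
because their voxel counts and surfaces have brute-force-checkable
ground truth. Default study conditions: 32³ voxels, radii (10, 6, 3),
center jitter ±2 voxels, per-modality tissue means following the usual
BraTS contrast pattern (FLAIR-bright edema, T1-CE-bright enhancing
tumor, T1-dark necrosis; arbitrary units around 100), additive Gaussian
noise sd 5 (5% of tissue intensity). Case `i` under seed `s` is drawn
from `default_rng([s, i])`, making generation bit-reproducible and
order-independent.

K-space noise adds i.i.d. complex Gaussian noise to the full 3D
spectrum of each modality and keeps the real part of the inverse
transform — the way thermal noise enters an MR acquisition. Noise
magnitudes are expressed relative to the root-mean-square spectrum
magnitude of the image (`spectrum_rms`), since absolute spectral units
are size-dependent.

What the phantoms do *not* model: irregular tumor shapes, multifocal
lesions, bias fields, partial-volume effects, inter-case anatomy
variation. Passing the phantom-scale tests therefore demonstrates that
the implementation optimizes and evaluates correctly, not that the
architecture reaches any particular accuracy on real BraTS data.

## Training procedure

Adam on the weighted Dice loss; two-phase constant learning rate
(1e-4 → 3e-5 at 80% of max_steps by default, the published full-scale
schedule). Desk-scale runs in the tests and acceptance script use a
tiny configuration chosen once for CPU budgets: base_channels 4, three
encoder stages, 32³ patches, AG radius 2, dropout 0 (regularization off
for capacity checks), learning rate 1e-3 → 3e-4, 400 steps for the
single-case overfit and 500 steps for the 20-case run. An optional
`halve_per_epoch` flag randomly subsamples 50% of the patches each
epoch (a literal reading of "the dataset is halved every time it is
traversed"); it is off by default because the sentence is ambiguous.
Checkpoints are single-file `.npz` archives holding weights, Adam state
and the data-order RNG state, so a resumed run continues the
uninterrupted trajectory bit-for-bit.

## Preprocessing and I/O

Z-score normalization per modality over nonzero voxels by default
(standard for skull-stripped data; whole-volume statistics via a flag);
a constant channel is an error naming the modality. One-hot channel
order is (background, gangrene, edema, enhancing), label↔channel map
{0,1,2,4}↔{0,1,2,3}. Sliding-window patches are zero-padded at borders
with 0-based half-open origins recorded for exact restitching;
inference averages softmax probabilities over overlaps. The published
patch grid ("175 images" of 64×128×128 per case) is not reproducible
because the stride is unstated, so the stride is a parameter defaulting
to non-overlapping tiles. NIfTI files use the BraTS naming convention
`<case>_<modality>.nii.gz` / `<case>_seg.nii.gz`; internal arrays are
(depth, height, width, channel) and axes are permuted to/from NIfTI
(x, y, z) order with the affine passed through unchanged.

## Open design points (and the choices made)

- Four vs five encoder stages are both quoted for this architecture;
  the default is 4 (configurable).
- Sigmoid vs softmax head: softmax, consistent with one-hot targets
  and the Dice objective over the probability simplex.
- Normalization type is unspecified; instance norm, robust at batch
  size 1 for 3D patches.
- Channel widths are unspecified; base_channels defaults to 16.
- Whether guided-filter coefficients are shared across channels of `O`
  is unspecified; they are computed per channel.
- Transposed-convolution sizing follows
  `o = s(i−1) + k − 2p + output_padding` with output_padding ∈ {0,1}
  chosen to double exactly; the network uses k = 2, s = 2, p = 0.

## Known limitations

Pure-numpy training is single-threaded BLAS-bound: roughly 0.4 s per
optimization step on a 32³ patch with the tiny configuration, and ~23 s
for one full-size (64×128×128, base 16→4-channel head) forward pass on
one CPU. Full-scale BraTS training (hundreds of thousands of steps at
base_channels 16) is supported by the code paths but not by CPU
budgets; published-scale accuracy numbers are therefore out of scope
here, and the test suite makes property-based claims only.
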