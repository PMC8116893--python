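# Methods

## Model

`histadapt` segments 3D brain volumes voxel-wise with a 2.5D patch CNN. A
2.5D sample is the triplet of orthogonal 2D patches (axial, sagittal,
coronal; default 32×32) centred on a voxel — a memory-cheap surrogate for a
3D patch. Each patch is processed by its own convolutional path (five
convolutions, 3×3 kernels, ReLU, then a fully connected layer); the three
path outputs are concatenated with the K atlas probabilities at the voxel
(spatial prior: K = 15 classes for sub-cortical structures, K = 3 tissue
probabilities for white-matter-hyperintensity segmentation) and passed
through fully connected head layers into a softmax classifier (15 classes
for structures; lesion vs. background for lesions). Channel counts
(32, 32, 64, 64, 128 per path; path FC 256; head FCs 512, 256) are package
defaults — the underlying publication line inherits them from an earlier
architecture without restating them — and everything is configurable through
`NetworkSpec`. Desk-scale experiments use `tiny_spec` (3 convolutions of
8/12/16 channels, 11×11 patches).

The network and its training run on a small reverse-mode automatic
differentiation engine over numpy arrays (`histadapt.autodiff`): im2col
convolutions, dense layers, ReLU, fused softmax cross-entropy, a log-cosh
distance with an explicit stop-gradient side, and Adam. Parameters and
activations are float32; losses accumulate in float64. The engine is
deliberately minimal (stride-1 same-padding convolutions, scalar losses) and
fully deterministic given seeds.

## Supervised training

Intensities are normalised per volume to zero mean and unit variance;
statistics are computed over non-zero (brain) voxels by default because the
intended inputs are skull-stripped, with whole-volume statistics available
via an explicit mask. Structure training takes every structure voxel as a
positive and draws negatives only from background voxels within a five-voxel
Chebyshev margin of a structure (the hardest, boundary region). Lesion
training is cascaded: stage 1 uses all lesion voxels against an equal random
draw of non-lesion brain voxels; the stage-1 network then segments its own
training image, and stage 2 draws its negatives from the stage-1 false
positives (false-positive reduction). When stage 1 produces fewer false
positives than there are lesion voxels, the deficit is topped up with random
non-lesion brain voxels to preserve balance.

Samples are split 75/25 into training and validation; optimisation is Adam
at learning rate 1e-2 on batches of 128 for up to 200 epochs, stopping when
validation accuracy has not increased for 20 consecutive epochs
(full-scale defaults; the phantom experiments scale these down). On an
accuracy plateau the training counts the epochs toward patience but keeps
the *latest* plateau snapshot as the restored weights: with the saturated
patch accuracies typical of this task, restoring the first tie would return
an arbitrary early snapshot.

## Transductive adaptation

Adaptation assumes a pre-trained network, one labelled source image and one
unlabelled target image. Each optimisation step draws a source batch and a
target batch of 32 samples, forwards both with activation capture at the tap
layers (last three convolutions per path + all FCs except the classifier),
histogram-matches the pooled source activations of each tap layer onto the
target's, and descends

    L_total = L_ce(source) + λ · L_hist,
    L_hist  = Σ_i LogCosh(A_i, H(A_i, B_i)),

at learning rate 1e-4. λ defaults to 1.0; the method is insensitive within
roughly 1 ± 0.6, while far larger values overshoot and far smaller ones
remove the effect. `H` is a monotone CDF/quantile mapping with 256 quantile
knots by default; with at least as many knots as values (and no ties) it is
exactly the rank substitution sorted(source)[k] → sorted(target)[k]. Source
ties map to the quantile of their first occurrence. The matched matrices are
stored constants: no gradient flows through the target forward pass, so
target labels are never needed (and the types make them unreachable).
Pooling is per layer over the whole batch tensor by default; a per-channel
mode exists behind a flag. Matching is distribution-level by construction —
the loss is invariant to independent permutations of the source and target
batch dimensions.

Where voxels are sampled from the unlabelled target image is fixed by
running the same task sampler on the atlas argmax (a label-free geometry
surrogate); those positions only choose patches and never contribute a CE
term.

Batch-level histogram matching injects step-to-step noise (a 32-sample
empirical quantile function under-represents distribution tails), so the
adaptation loop offers two stabilisers beyond classic early stopping:
tail weight averaging (return the element-wise mean of the last k per-epoch
snapshots) and histogram-loss snapshot selection (return the epoch with the
lowest epoch-mean L_hist whose source validation accuracy stayed within 0.02
of the start — the alignment objective itself is observable without target
labels). Defaults leave both off; the phantom experiment uses tail averaging
over 3 epochs of a 4-epoch schedule.

## Inference and post-processing

Structure mode classifies only voxels inside a region of interest: the union
of non-background atlas channels (p > 0) dilated with a cubic structuring
element (radius 5 by default), then keeps a single largest 26-connected
component per class (size ties go to the component containing the
lexicographically smallest voxel). Lesion mode classifies every brain voxel,
thresholds the lesion probability at 0.5 (a package choice — the threshold
is configurable and logged, as the underlying study does not print one) and
removes candidate components that are outside white matter (fewer than half
of the component's voxels with WM prior ≥ 0.5) or smaller than 3 mm³
(strictly less than; a 1-voxel candidate at 1×1×3 mm spacing is exactly
3 mm³ and survives). Post-processing never adds voxels.

## Metrics

Dice similarity is 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty.
Lesion-wise detection works on 26-connected components: a true lesion counts
as detected if at least one voxel overlaps a predicted component
(TPR = detected / truth lesions); the lesion-wise FPR is the fraction of
predicted components with zero truth overlap — stated explicitly because
challenge conventions differ; F combines precision P = 1 − FPR with recall
R = TPR as 2PR/(P+R). Empty-set conventions: both empty → DSC 1, TPR 1,
FPR 0; empty prediction with non-empty truth → TPR 0, FPR 0, F 0.

## Synthetic phantoms

The generator emulates skull-stripped, atlas-registered brain MRI on a small
grid: ellipsoidal structures with distinct mean intensities (three bilateral
structure classes by default) or sparse bright lesions inside a synthetic
white-matter shell, on a smoothly textured background with Gaussian noise
(sd 0.02 at a background mean of 0.35). Prior atlases are produced by
Gaussian-blurring each class indicator (sd 0.75 voxels) and renormalising —
at this blur the per-voxel atlas argmax recovers ≥ 95 % of object voxels, a
realistic level of informativeness for registered priors. The acquisition
shift applies, in order: gamma on min–max rescaled intensities, a linear
gain/offset, a smooth multiplicative bias field realised as Gaussian-smoothed
seeded noise rescaled to [1−A, 1+A] with a stated correlation length, and
additive Gaussian noise. Gamma ≠ 1 or A > 0 produces a shift that per-volume
affine normalisation cannot remove. All randomness flows through explicit
per-call seeds.

What the phantoms do *not* model: MRI physics (k-space, partial volume),
multi-contrast acquisition, anatomy beyond ellipsoids, registration error
beyond blur, and inter-rater label noise. Passing phantom tests therefore
demonstrates the mechanics and the direction of the adaptation effect, not
clinical performance.

## The desk-scale experiment

`run_experiment_pair` mirrors the full study at phantom scale. Per seed:
four labelled source cases and three target cases (28³ voxels, 1 mm
isotropic) are rendered from the same jittered scene family; the baseline is
trained on three source cases (initial training uses a source *dataset*;
the one-image regime applies to adaptation) with ~1000 patch samples per
case, up to 40 epochs, patience 8; the fourth source case gives the held-out
source Dice. The standard target shift is gamma 1.8 with a residual 10 %
bias field — residual because the emulated preprocessing pipeline includes
bias-field correction, so contrast/gamma differences dominate the remaining
domain shift — plus noise (sd 0.01). Adaptation uses source case 0 and
target case 0, a 4-epoch schedule at learning rate 1e-4 with tail averaging
over the last 3 epochs, and is evaluated on all three target cases. An
identity-shift control shares the seed's baseline and measures what the
procedure does when there is nothing to align; its Dice change stays within
±0.02 on average while the shifted arm improves by ≥ 0.02.

Mechanistically, the recovery concentrates where the shift degrades but does
not destroy the representation; a bias field strong enough to collapse the
baseline to near-random segmentation leaves feature-level alignment nothing
to work with — consistent with the full-scale observation that the hardest,
artefact-laden domains benefit least.

## Numerical choices and degenerate inputs

Constant volumes cannot be normalised (zero variance raises). Histogram
matching of a constant source maps everything to one target quantile. The
log-cosh distance is computed as |d| + log1p(e^(−2|d|)) − log 2, which never
overflows (checked to |d| = 1e4). Component size ties break
lexicographically. Patch windows at the volume border are zero padded —
after normalisation, zero is the mean intensity. Voxel indices are 0-based,
axis order (x, y, z) = (sagittal, coronal, axial).

## Known limitations

The autodiff engine is single-threaded numpy and intended for desk-scale
problems; the full 32×32/five-conv configuration trains only at real-dataset
scale with patience. The adaptation step count is the main stability knob:
batch-histogram noise accumulates a slow contraction pressure on activation
tails, so very long adaptation schedules can degrade a converged baseline
(the identity control makes this visible). The lesion pipeline is exercised
on phantoms with simplified WM geometry; FLAIR-specific intensity modelling
is out of scope.
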