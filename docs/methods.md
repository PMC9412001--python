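# Methods

## Problem and model

`lesionseg` segments *new* multiple-sclerosis lesions: hyperintense
regions present in a follow-up 3D FLAIR volume but absent from the
co-registered baseline of the same patient. The core model is a triplanar
(2.5D) U-Net: a single 2D U-Net consumes a two-channel slice — channel 0
the baseline, channel 1 the follow-up — and emits a per-pixel foreground
probability through a two-class softmax head. One network is trained on
slices from all three orthogonal planes (sagittal, coronal, axial), so
features are shared across orientations; this requires all slices to have
one size, which the preprocessing guarantees by resampling each subject
to an N³ cube.

At inference the volume pair is sliced along each of the three planes,
every slice runs through each cross-validation fold model, and the
softmax outputs are averaged over folds, giving three probability
volumes. These are merged into the final mask by one of four strategies:

* **softmax averaging** — threshold the voxel-wise mean of the three
  volumes;
* **union / majority / unanimous voting** — threshold each orientation
  into a hard mask, take connected components of the voxel-wise union of
  the three hard masks as candidate lesions, count the orientations that
  overlap each candidate in at least one voxel, and keep candidates with
  ≥ 1 / ≥ 2 / 3 votes. A kept lesion's segmentation is the union of the
  positive voxels across orientations, i.e. exactly the candidate
  component.

By construction the unanimous mask is contained in the majority mask,
which is contained in the union mask; recall is therefore monotone
non-increasing and precision empirically monotone non-decreasing from
union to unanimous. Unanimous voting — accept only lesions "seen" in all
three planes — is the default, mirroring the radiological practice of
confirming a lesion on multiple planes before reporting it.

### Vote definition

When is a lesion "detected in" an orientation? We use ≥ 1 voxel of
overlap between the candidate component and that orientation's hard
mask. A minimum-overlap-fraction variant is available
(`MergeStrategy.min_overlap_fraction`) for sensitivity analyses.
Connected components use 26-connectivity by default (6/18 configurable);
the hard-mask threshold is 0.5.

## Network

Encoder levels double the channel width (base × 2^level) and halve the
spatial size via 2×2 max pooling; each level applies two blocks of
(3×3 convolution → batch normalization → ReLU) with "same" padding. The
decoder mirrors the encoder with 2×2-stride-2 transpose convolutions and
skip concatenation, and a final 1×1 convolution maps to 2 class channels
followed by a softmax. The published architecture figure does not state
its width or depth; defaults here are depth 5, base 32 at 256³, and the
desk-scale tests use depth 3, base 8 at 64³.

The layers are implemented directly in NumPy with explicit forward and
backward passes (im2col convolutions dispatched to BLAS). Backpropagation
through every layer type is verified against double-precision central
finite differences to < 1e-4 relative error in the test suite.

## Training

The loss is the sum of a soft Dice loss and a TopK loss over the softmax
probabilities p and one-hot ground truth g, both summed over the two
class channels:

    L_Dice = 1 − 2 Σ g·p / (Σ g² + Σ p²)
    L_TopK = mean of the k% largest per-voxel cross-entropies
             CE_i = −Σ_c g_ic log p_ic          (k = 10 by default)
    L_total = L_Dice + L_TopK

TopK is hard mining: only the k% hardest voxels contribute, and k = 100
recovers plain mean cross-entropy. The TopK selection is over all voxels
of the batch; the selection set is treated as constant in the gradient
(subgradient descent).

Optimization is stochastic gradient descent with momentum 0.9. Batches
hold 20 slices drawn across subjects and orientations. The learning rate
is halved when the validation loss plateaus (patience 5) and training
stops early when it stagnates (patience 10). Cross-validation trains one
model per fold on a random subject-level 80–20 split; the fold ensemble
is what inference uses. Validation loss is the mean slice-level loss on
a fixed random sample of held-out slices.

Training-time augmentation applies one shared spatial transform per draw
(flips across the three planes, rotations ≤ 10°, elastic deformation with
σ = 4 voxels and ~2-voxel peak displacement) to images and mask, and
intensity transforms (gamma contrast in [0.8, 1.2], ≤ 20% low-order
polynomial bias field) to images only. Magnitudes are conventional
defaults; the source protocol names the augmentations without values.

### Desk-scale training settings

The end-to-end demonstration (10 subjects of 64³, depth-3/base-8 net,
5 folds, 3 epochs; `configs/desk_demo.yaml`) departs from the full-scale
hyperparameters in two places, both plain training-configuration choices:

* **learning rate 0.3** instead of 1e-4. The 1e-4 rate belongs to a
  ~50-epoch schedule on full-resolution data; at 231 SGD steps per fold
  it cannot leave the all-background regime.
* **foreground-slice oversampling 0.5**: half the batch slots draw from
  lesion-containing slices of the chosen subject and orientation. Sparse
  spherical lesions occupy ~0.5% of the phantom volume; without
  oversampling the foreground gradient (bounded by 1/|TopK set| per
  voxel) is too dilute for a 3-epoch schedule. No slice is ever excluded
  from sampling, and the option defaults to 0 (uniform).

## Preprocessing

Per subject: (1) optional affine registration to a template volume
(SimpleITK, mean-squares metric, multi-resolution gradient descent;
identity when no template is configured — pairs are assumed
co-registered); (2) crop to the Otsu-foreground bounding box of the
follow-up plus a margin, applied identically to the baseline and all
masks; (3) resample to an N³ cube, images trilinearly, masks by nearest
neighbor; (4) z-score each image over the cropped field of view.
Normalization is per volume and per time point; whether to normalize
jointly across time points is an open choice, and the per-volume reading
is used here. Voxel indexing is 0-based; all volumes are reoriented to
RAS+ at load so the three plane names are well defined.

## Lesion-level evaluation

Detection is scored on lesion objects, segmentation on voxels:

    F1 = 2·TP_l / (FP_l + 2·TP_l + FN_l)     Dice = 2·TP_v / (FP_v + 2·TP_v + FN_v)

A ground-truth lesion is detected when predicted foreground covers at
least `min_overlap_fraction` (default 0.10) of its voxels; a predicted
lesion is a false positive when it overlaps no ground-truth lesion in a
single voxel (so a second prediction touching an already-matched lesion
is not punished; a stricter dialect is configurable). This reimplements
the semantics of the challenge-style segmentation performance analyzer
("Anima-like"); byte-exact equality with that binary is not claimed, and
its exact thresholds are not published in the source material. Cohort
scores are unweighted means across subjects, with empty-ground-truth
subjects excluded from means by default (they are still listed).
Empty-vs-empty comparisons score 1.0 and carry a flag.

## Multi-rater machinery

**Binary STAPLE.** EM estimation of a latent true segmentation together
with each rater's sensitivity p_j and specificity q_j. The E-step
computes the per-voxel posterior foreground probability from the current
(p_j, q_j) and prior; the M-step re-estimates (p_j, q_j) — and the prior,
as the posterior mean. The prior is initialized to the empirical
foreground rate of the rater masks. Re-estimating the prior matters:
with the prior held fixed at the empirical rate, sparse rater false
positives (e.g. 1% of a 64³ volume against 0.1% true foreground) inflate
it several-fold and the EM drifts to a fixed point in which false
positives are absorbed into the latent truth and sensitivities collapse.
Initialization p_j = q_j = 0.9999, tolerance 1e-6 on the posterior,
maximum 100 iterations. Performances are clamped to the open unit
interval throughout.

**Consensus protocol.** Candidate lesions are connected components of
the union of all rater masks. Lesions found (≥ 1 voxel overlap) by at
least `majority_threshold` raters (default 3 of 4) are accepted
automatically; the rest are *disputed* and require an accept/reject
decision — either an explicit decision table or an existing consensus
mask standing in for the senior reader (accept iff the lesion overlaps
it). Each accepted lesion is delineated by STAPLE over the raters who
found it, restricted to a 3-voxel-dilated bounding region around the
candidate; running STAPLE regionally avoids specificity saturation from
the overwhelming background and mirrors fusing only "the concerned
experts'" delineations.

**Unbiased ground truth u_i.** To score rater i fairly, u_i is built
without ever reading rater i's mask: candidate lesions come from the
union of the remaining R−1 masks; a lesion found by ≥ 2 remaining raters
is accepted automatically; a single-finder lesion is accepted iff it
overlaps the original consensus (the senior reader's past decision,
assumed constant across readings); accepted lesions are delineated by
voxel-wise majority vote over the remaining raters. A single-finder
lesion has an empty majority among 3 remaining raters — the protocol as
published does not resolve this — so the finder's own delineation is
used for such lesions. Majority ties (even rater counts) go to
background. Leave-one-out independence is property-tested: arbitrary
corruption of the excluded rater's mask never changes u_i.

## Noninferiority statistics

For per-subject expert scores Y and pipeline scores X with margin
d = 0.05: H0: E(Y−X) ≥ d against H1: E(Y−X) < d by a one-sided paired
Student t-test on (Y−X−d), α = 0.05. Rejection concludes the pipeline is
at most d worse than the expert, possibly better. At d = 0 this is the
standard one-sided paired t-test. Tests run per (pipeline, expert) pair
for F1 and Dice, plus a mean-vs-mean test across the expert-specific
ground truths. p-values are reported raw (no multiplicity correction),
with an optional correction flag left to the caller.

## Synthetic phantoms

Each subject is an ellipsoidal two-intensity "brain" (unit tissue with a
slightly darker shell) in a configurable grid (default 64³, spacing
(1, 1, 1) mm; anisotropic spacings in the 0.5–1.2 mm range are
supported). Spherical lesions (radius 2–4 mm by default, never below
1.5 mm so diameters stay ≥ 3 mm) are placed inside the brain by
rejection sampling, pairwise separated by more than 2 voxels so they
remain distinct 26-connected components. Baseline lesions render
identically in both time points; new lesions appear only in the
follow-up at 1.8× tissue intensity. Volumes are smoothed with a σ = 0.6
voxel Gaussian, modulated by a random quadratic bias field (20%
amplitude) and degraded with Gaussian noise (σ = 0.05). The ground truth
marks the new-lesion spheres before smoothing.

Simulated raters operate on the lesion level: each lesion is missed with
probability 1 − sensitivity; surviving lesions are rigidly jittered
(σ = 0.5 voxel) and optionally dilated/eroded; false-positive blobs
arrive as a Poisson count of small spheres disjoint from the truth.

What the phantoms do **not** emulate: white-matter geometry, FLAIR
texture, partial-volume and flow artifacts, scanner differences,
confluent or enlarging lesions, and raters whose errors correlate with
anatomy. Passing the end-to-end tests therefore demonstrates that the
machinery — slicing, ensembling, voting, matching, fusion, statistics —
is implemented correctly and that the training loop can learn a
high-contrast change-detection task; it does not certify clinical
performance on real MRI.

## Numerical choices and degenerate inputs

* Hard-mask and posterior thresholds are strict (`> 0.5`).
* Lesion labels follow volume scan order (deterministic; lexicographic
  by each component's first voxel).
* TopK with k selecting zero voxels is a configuration error; k = 100
  always selects all.
* Empty-vs-empty mask comparisons score 1.0 with a flag; an empty
  prediction against a nonempty truth scores recall 0.
* All-empty rater sets fuse to an empty mask without failure;
  zero-variance paired differences raise a degenerate-data error rather
  than reporting a meaningless p-value.
* A single global seed fans out to stage seeds via
  `numpy.random.SeedSequence.spawn`; equal seeds reproduce runs
  bit-for-bit on one platform.

## Problem sizes in the shipped configuration

The desk demo trains 5 folds × 3 epochs × 77 steps (batch 20, 64² slices)
on 8 subjects and evaluates on 2 held-out subjects; the STAPLE experiment
uses 5 voxel-wise raters on a 64³ phantom; the voting validation compares
against a brute-force component oracle on random 8³ mask triples. These
sizes were chosen so the whole suite runs on a single CPU at interactive
timescales while still exercising every code path at full fidelity.

## Known limitations

* The NumPy training engine is single-threaded and CPU-bound; full-scale
  256³ training is configurable but not practical without a GPU port.
* Registration quality is validated on phantoms (self-registration and
  known translations), not on real multi-scanner data.
* The metric dialect approximates the challenge analyzer's published
  semantics; its unpublished thresholds may differ.
* With only two held-out subjects the demo's noninferiority tests have
  n = 2 and are reported for completeness, not power.
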