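# Methods

`lafmkit` implements a complete desk-scale toolchain for studying flexible
membrane proteins in (simulated) atomic force microscopy: image simulation
by tip dilation, localization super-resolution reconstruction (LAFM),
similarity metrics adapted to topographs, and unsupervised conformational
clustering with and without rigid drift.

## Simulated AFM by tip dilation

A topograph records, at each lateral grid position, the height of the
lowest point of the tip when it first touches the sample.  This is a
grayscale morphological dilation of the surface by the tip shape.  The tip
is a cone of half-angle θ (default 18°, a typical experimental value)
terminated by a spherical apex of radius R.  Atoms are hard spheres with
van der Waals radii; the membrane is a flat background plane and atoms
whose sphere top does not clear it are invisible.

For one atom (center height z, radius r) at lateral distance d from the
tip axis the contact height has a closed form, obtained by dilating the
tip by r:

- apex-sphere contact (d ≤ (R+r)·cos θ): `h = z + sqrt((R+r)² − d²) − R`
- cone-flank contact (d > (R+r)·cos θ): `h = z + (R+r)/sin θ − R − d·cot θ`

The two branches join continuously at the critical distance.  A pixel's
value is the maximum contact height over atoms, minus the background,
clipped at 0.  The closed form is validated in the test suite against an
independent brute-force oracle that densely samples the physical tip
surface and lowers it to first contact (agreement < 10⁻³ Å; the per-atom
analytic path agrees with the vectorized renderer to < 10⁻⁶ Å).

Numerical conventions: pixel centers (not corners) are sampled, with
`x = x_min + (i + 0.5)·P`; background is exactly 0; rendering is
O(atoms × pixels).

## LAFM reconstruction

Thermal motion makes topographic peaks sample slightly different positions
across frames; localizing each peak on a finer grid and accumulating
detections beats the acquisition pixel size.  The pipeline per frame:

1. bicubic expansion by an integer factor f (default 3; a 4 Å/px scan
   becomes ≈1.3 Å/px).  Expansion is corner-aligned (expanded sample j
   interpolates input coordinate j/f) so original samples survive exactly
   and refinements are nested; interpolation overshoot is clipped at 0.
2. peak detection: strict 8-neighbor maxima above a configurable floor
   (default 0 Å); borders excluded; plateaus are not peaks (interpolated
   data is generically plateau-free).
3. each peak is rendered as a Gaussian of width `kernel_sigma` (default
   f/2 expanded pixels) and amplitude = detected height / global stack
   maximum.  Within a frame overlapping Gaussians combine by per-pixel
   maximum, keeping the frame map a detection-probability surrogate in
   [0, 1] (summation would break that bound).

The per-frame maps are averaged into a peaking-probability image, and the
final LAFM image is that probability times the per-pixel mean of the
expanded real-space frames.  Frames are accumulated in a content-sorted
canonical order so the result is bitwise invariant under frame
permutations.  An all-zero stack degenerates to an all-zero image rather
than an error.

## Masked SSIM and the weighted reconstruction loss

Topographs are mostly flat zero background, which a plain SSIM rewards
trivially.  The masked score computes a standard Gaussian-window SSIM map
(window 11, σ 1.5, K1 = 0.01, K2 = 0.03, data range = the pair maximum —
LAFM images have no fixed dynamic range) and averages it over the pixels
where **either** image exceeds 5% of the pair maximum.  The union mask is
deliberate: a feature present in only one image must count against the
score, not vanish with the background.

The autoencoder training loss combines both views:

    L = 1 − (α·SSIM + β·SSIM_masked) / (α + β)

normalized by α+β so equal weights at any scale agree; defaults α = β.
L ∈ [0, 2] and is 0 iff the reconstruction is SSIM-perfect globally and on
the mask.

## Deep spectral clustering (DSC)

Frames are rescaled to [0, 1] by the global stack maximum and fed to a
compact convolutional autoencoder written in numpy: three stride-2 3×3
convolution blocks (16/32/64 channels), a dense latent layer (64 units by
default), and a mirrored decoder using nearest-neighbor upsampling +
convolution with a sigmoid output.  Training is Adam (lr 10⁻³) on the
weighted 1−SSIM loss above; the gradient of the SSIM map is computed
analytically — every local statistic is a Gaussian filtering, and with
zero-padded boundaries that filter is self-adjoint, so backpropagation is
again Gaussian filtering.  The analytic gradient is checked against finite
differences in the tests.  All randomness (weight init, batch order)
derives from a single seed; runs are bit-reproducible.

The encoder's latent feature vectors are compared with the self-tuning
locally scaled affinity `A_ij = exp(−d²(i,j)/(σ_i σ_j))`, Euclidean d,
with σ_i the distance to the k-th nearest neighbor (k = 7, the self-tuning
convention).  Frames with ≥ k exact duplicates fall back to their smallest
positive neighbor distance; an all-duplicate stack is a degenerate error.
Spectral clustering (normalized cuts, k-means assignment, seeded) of A
yields the labels; n = 1 and n = N are short-circuited.

## Hierarchical DSC (HDSC)

A trajectory-like stack holds metastable conformations plus transient
frames.  HDSC peels stable clusters iteratively: cluster the residual at
n = 2 and compare the two per-cluster LAFM images; if their masked SSIM
reaches the stability threshold (default 0.8) the split was spurious —
merge and halt.  Otherwise recluster the same affinity submatrix at n = 3
and cross-compare the n = 3 LAFM images with the n = 2 ones (greedy best
pair; each n = 2 image certifies at most one n = 3 cluster).  Matched
clusters are emitted and their frames removed; the loop repeats on the
reduced stack until nothing matches or too few frames remain.  Emitted
clusters at or above the minimum cluster size (default 5% of the stack)
are stable conformations; smaller ones are transients.  The CAE and
affinity are computed once on the full stack and submatrices are reused
(per-round retraining is available behind a flag).  Each productive round
removes at least one cluster, bounding the round count.

## Rigid registration

Drifting molecules are aligned with rotation + translation only — the
transform parameterization structurally forbids scale and shear.
Estimation: the Fourier magnitude is translation-invariant, so a log-polar
correlation of the two spectra proposes the rotation (its 180° ambiguity
is resolved by trying both candidates); phase cross-correlation proposes
the translation; a Powell refinement of the sum of squared differences
polishes all three parameters.  Resampling is bilinear about the image
center with zero fill (the membrane background), preserving non-negative
heights.  On noise-free fixtures known transforms are recovered within
2° / 0.5 px; round-trip apply/invert residuals stay below 1% of the
maximum height on ≥ 64×64 images (bilinear smoothing dominates on coarser
grids).

## REC and IREC

For unaligned stacks, registration and clustering are coupled.  One REC
pass registers every frame to a reference, runs DSC on the registered
stack, retains the cluster containing the reference (those frames
registered well), and promotes the member with the highest silhouette
score (computed in latent space; ties break to the lowest frame index,
singletons fall back to the medoid) as the refined reference.  The
single-reference bootstrap keeps all n clusters with per-cluster
references, which is what the iterative stage needs to start.

IREC iterates REC over the reference set until the references reproduce
themselves (set equality), a previously seen set recurs (cycle — the
best iteration by mean retained-cluster silhouette is returned), or an
iteration cap (default 10) is reached; the termination reason is always
recorded.  Retained clusters from different references may overlap — in
the final partition a contested frame goes to the reference it registered
best to (least sum of squared differences), and frames claimed by no
cluster are reported as unassigned.

To choose the cluster count, IREC is run for n = 2, 3, …; the per-cluster
LAFM images (each cluster's frames registered to its own reference) are
mutually registered and compared with masked SSIM.  The comparison uses
the retained clusters *before* overlap resolution: two references that
converged onto the same conformation retain near-identical member sets,
and that redundancy is exactly the stopping signal.  The first n at which
any pair reaches the similarity threshold (default 0.9) is one past the
optimum.  For stacks mixing grossly different morphologies the procedure
is applied hierarchically: partition first, then recurse within each
cluster until n = 1 is selected or the sub-stack is too small.

The default initial reference is the stack's medoid frame (maximum mean
pairwise SSIM over a subsample); it is overridable by index.

## Synthetic study conditions

The generator emulates the statistical structure of an MD-derived stack of
a flexible membrane protein: 2–4 discrete conformers of unequal occupancy,
per-frame Gaussian jitter of atom positions, and (for unaligned stacks)
rigid in-plane drift modeled as a random walk so misregistration is
temporally correlated.  Conformers are rigid domain arrangements sharing
an asymmetric three-lobe core and differing in the placement of one mobile
arm — the smallest structure that makes clustering nontrivial.  The core's
asymmetry is deliberate: a rotationally ambiguous pseudo-protein would let
rigid registration alias one conformer onto another, which real proteins
do not permit.  The stock three-state recipe uses occupancies
0.45/0.45/0.10 (two metastable states plus a transient), jitter 0.5 Å, and
drift steps of 0.4 Å / 0.8° per frame when unaligned.  State sequences are
contiguous blocks by default, or a persistent Markov chain.

What the generator does **not** emulate: continuous conformational
interpolation between states, tip wear and scan-line artifacts, feedback
dynamics, or correlated (non-white) pixel noise.  Passing tests therefore
demonstrate correctness of the algorithms under clean, well-separated
conditions, not performance on experimental data.

## Problem sizes and defaults used in validation

Validation runs use 32×32-pixel frames (64 Å field at 2 Å/px, 20 Å tip):
400 frames for two-state DSC recovery, 200 frames for HDSC and its 5%
noise-robustness check, 120–150 frames for IREC cluster-count selection,
and reduced autoencoder settings (latent 16, channels 8/16/32, 12–15
epochs) where the full default is unnecessary for separation.  These sizes
keep a full validation pass in the tens of minutes on one CPU core while
leaving clustering margins wide.

## Known limitations

- The CAE is intentionally small; very subtle conformational differences
  (or stacks much larger than ~10⁴ frames) would warrant a GPU-backed
  implementation with the same interfaces.
- Rigid registration assumes the molecule stays in-plane; tilt and
  out-of-plane rocking are not modeled.
- IREC's reference refinement can oscillate between near-equivalent
  references; cycle detection and the iteration cap make termination
  unconditional, but the returned iterate (best mean silhouette among
  those seen) is not a proven optimum.
- IREC's cluster-count selection is reference-biased: when the iteration
  fails to place a reference in a rare state (a ~10% occupancy conformer
  on an unaligned stack, at some seeds), that state is absorbed into a
  major cluster and the selected count undershoots.  Hierarchical
  application mitigates but does not eliminate this.
- Cluster-count selection inherits the similarity threshold's
  calibration: thresholds near 1 over-partition, small thresholds merge
  distinct but similar states.
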