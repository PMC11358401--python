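# Methods

This note documents the models, parameter choices and numerical decisions
behind `hemilabel`, and what the phantom-based tests do and do not show.

## Data model and coordinate conventions

All images are 3-D scalar (`Volume`) or integer (`LabelMap`) arrays with a
4×4 voxel-to-world affine in millimetres. World axes follow RAS+ (x to the
subject's Right, y Anterior, z Superior); voxel indices are 0-based; the
mid-sagittal mirror is the world plane x = 0. Label ids are structured:
0 background, 1–5 hypothalamic subregions (anterior superior, anterior
inferior, tuberal superior, tuberal inferior, posterior), 6–10 their
mirrored counterparts, and ≥101 unsupervised context classes. NIfTI I/O
goes through nibabel; sform is preferred over qform when both are present,
and both are written consistently. Intensities are always resampled with
linear interpolation and labels with nearest-neighbour — ids are
categorical and may never be averaged. Isotropic resampling uses output
shape `ceil(extent / target_spacing)` with the grid origin preserved, so
anatomy is never cropped; reorientation only permutes/flips voxel axes and
leaves every voxel's world coordinate unchanged.

## Pre-processing

Stage order is fixed: reorient → background mask → resample → bias
correction. The working resolution defaults to 0.3 mm isotropic, a
compromise between detail and the memory/compute cost of training-scale
volumes.

*Background removal* is an Otsu threshold followed by keeping the largest
6-connected component. Ex vivo specimens are scanned in a packing bag that
appears as dim detached structures; the largest-component rule discards
them. This is a deliberately simple masking model with the same contract as
contrast-adaptive Bayesian segmentation (clean background, one connected
brain): the method here is the package's own choice, selected to be exactly
testable.

*Bias-field correction* models the scanner inhomogeneity as a smooth
multiplicative field. The log-intensities inside the mask are smoothed by
normalized convolution with a Gaussian of FWHM `bias_fwhm` (default 60 mm,
the scale of coil inhomogeneity in head-sized fields of view), the
exponential of the smoothed log-field is normalized to mean 1 inside the
mask (preserving global brightness), and the image is divided by it. The
estimator assumes scale separation: tissue features much smaller than the
field, the field varying within the FOV. Phantoms at desk scale (15–30 mm
FOV) violate this, so the correction tests use either a constant-tissue
phantom (isolating field recovery, where a linear ramp is removed almost
exactly) or scale `bias_fwhm` to the phantom FOV. On real head-scale data
the default applies. An intensity floor `bias_epsilon` (10⁻³) keeps the log
transform finite.

## Context clustering

Non-hypothalamic tissue needs no anatomical semantics — context labels
exist only to give the synthesis stage realistic intensity structure. We
therefore run 1-D k-means (scikit-learn, k-means++ initialization) on the
bias-corrected in-mask intensities for every k in 4..9, producing six maps
per volume whose variability itself is a form of augmentation. Determinism
and stable ids are imposed on top of k-means: each (volume, k) run is
seeded as `seed + k`, and cluster ids are relabeled in ascending order of
cluster mean intensity, offset by 100 (id 101 = darkest class). The offset
guarantees context ids can never collide with subregion ids 1–10.

## Label fusion and closing

Manual subregion labels always win over context labels: they are the
targets the final segmenter must learn, while context is scaffolding.
After the overlay, the union hypothalamus mask (ids 1–5) is
morphologically closed with a spherical structuring element of radius
1.2 mm — 4 voxels at the 0.3 mm working spacing (`round(radius/spacing)`,
clamped to 1 voxel with a warning below that). Closing is computed on a
frame padded by the element radius, which makes it equal to the
unbounded-domain operator and therefore exactly idempotent. Voxels the
closing adds to the hypothalamus need a subregion id the operation cannot
provide; they take the id of the nearest pre-existing subregion voxel
(Euclidean distance in world mm, computed per label with ties broken
toward the lowest id — deterministic and local). Closing is applied to the
whole-hypothalamus mask rather than to individual subregion pairs; this
repairs gaps (e.g. along the fornix) and removes slivers (e.g. toward the
third ventricle) without attempting per-structure logic.

## Hemisphere mirroring

The hemisphere is placed against a virtual mirror at x = 0 by a rigid
transform T (intrinsic x-y-z Euler angles in degrees + translation in mm,
acting on world coordinates) minimizing

    cost(T) = Σ_{i∈Ω} δ[x(v_i;T) > 0] · x(v_i;T) − α Σ_{i∈Ω} x(v_i;T)

over the brain-mask voxel set Ω. The first term penalizes crossing (which
would make the real and reflected hemispheres overlap), the second rewards
proximity (preventing a mid-sagittal gap).

**Choice of α.** For a pure x-shift t the cost is piecewise linear with
slope `n_crossed(t) − αN`, so its minimum sits where a fraction α of Ω has
crossed the plane — *not*, in general, at the flush position. A fixed α
would therefore push any flat-faced hemisphere through the mirror by an
amount depending on its face area, violating the no-overlap requirement.
The trade-off genuinely is per-image, and the default here computes it
adaptively: α = half the fraction of mask voxels lying within one voxel
layer of the medial extreme, clipped to (10⁻⁴, 0.5). With that choice the
first voxel layer to cross already carries more slope than the α term, so
the flush position is provably the 1-D optimum and the optimizer keeps
crossing at zero. An explicit α ∈ (0,1) can still be supplied; since
1 − α > 0, a voxel crossing the mirror always costs more than sitting on it.

**Optimization.** The cost is nonsmooth (kinks at every voxel crossing), so
a derivative-free simplex (Nelder–Mead; Powell available) is used over the
selected degrees of freedom (`tx`, `translation`, or full `rigid`),
initialized at identity rotation with the x-shift that brings the medial
extreme exactly to the plane — a feasible flush start. The cost is
evaluated on a deterministic stride-based subsample of Ω capped at 50 000
voxels (stride, not random, so the cost is reproducible without seeding).
After convergence a feasibility projection shifts the result left by any
residual full-mask crossing the subsample could not see (at most a fraction
of a voxel). The fit fails loudly if mask voxels remain beyond the crossing
tolerance (default 0.5 mm) or if the hemisphere ends more than 2 mm from
the mirror.

**Composition.** The output grid is symmetric about x = 0 (voxel centres at
±(j+½)·spacing), so reflection is an exact voxel-to-voxel map and labels
need no interpolation. The transformed hemisphere is resampled
nearest-neighbour onto the grid, its mirror image is the axis-0 flip,
mirrored subregions are relabeled 1→6 … 5→10, and mirrored context voxels
keep their ids (tissue appearance is assumed left-right symmetric for
synthesis purposes). Where both hemispheres claim a voxel the original
wins; overlap farther than the crossing tolerance from the plane is an
error reporting the voxel count.

## Synthetic image generation

Each training image is drawn from a full-brain label map in three stages
sharing one random stream per seed:

1. *Geometric augmentation*: a random affine (rotation ±15° per axis,
   scale 0.85–1.15, shear ±0.012, translation ±10 mm) about the volume
   centre, composed with a smooth random elastic displacement (per-axis
   std 3 mm, Gaussian-smoothed at 20 mm FWHM), applied to the labels by
   nearest-neighbour inverse warping. The sampling field can be returned
   and re-applied, so image and target are warped identically by
   construction. Ranges are config, not constants; they suit head-scale
   maps and should be scaled down for small volumes.
2. *Intensity model*: per label id, a mean ~ U(25, 225) and standard
   deviation ~ U(5, 25) are drawn, and every voxel of that label receives
   an independent normal draw. The image is min-max normalized to [0, 1];
   the drawn (μ_l, σ_l) and the normalization constants are returned with
   the image so its statistics can be verified. Optional bias/gamma
   augmentation stages are not included; contrast randomization plus
   resolution simulation are the core of the model.
3. *Resolution simulation*: per axis, a slice thickness ~ U(1, 9) mm is
   emulated by Gaussian blur with σ = 0.85·thickness/(2·spacing) voxels —
   with the native-resolution baseline removed in quadrature so that
   thickness = spacing is an exact identity — followed by centre-aligned
   linear down- and re-upsampling.

Training targets keep only ids 0–10: context classes condition appearance
but are collapsed to background in the target, since they are not
segmentation targets.

## Agreement metrics

Dice is 2|A∩B|/(|A|+|B|) over voxel sets; two empty sets score 1.0 (perfect
agreement on absence), empty-vs-nonempty scores 0. The Average Hausdorff
Distance is the symmetric mean of nearest-neighbour distances, Euclidean in
world mm, over **all** labeled voxels (not surfaces) — tools using surface
point sets will report different numbers, and AHD is treated as undefined
(error) when either set is empty. Reports group the five subregions as
Whole {1–5}, Anterior {1,2}, Tuberal {3,4}, Posterior {5}; a group absent
from both raters is reported as missing, never as zero. The KD-tree path is
verified against an all-pairs brute-force oracle to 10⁻⁹ mm in tests.

## Phantoms

The phantom generator emulates the real inputs' geometry, not their
physics: a half-ellipsoid "hemisphere" entirely on one side of x = 0 with
its flat medial face one half-voxel from the plane, filled with 4–9
concentric constant-intensity shells (means evenly spaced over 40–210,
darkest innermost), optional additive Gaussian noise (default σ = 2) and an
optional multiplicative bias ramp; and a 5-label medial block laid out like
the hypothalamic subregions (anterior/tuberal/posterior along y, the first
two split superior/inferior at the block's mid-height). Default cohort
size is 10 hemispheres at 96³ voxels, 0.3 mm, with every third member
right-sided to exercise the left-right flip. Everything is seeded and
bitwise reproducible.

What passing tests show: grid geometry, label bookkeeping, the optimizer's
agreement with exhaustive search, closing and metric exactness, and the
statistical contract of the synthesis model. What they do not show:
performance on real ex vivo contrast (fixation effects, partial volume,
genuinely curved midlines), the adequacy of Otsu masking on real packing
artifacts, or manual-rater reliability — those require the real scans.

## Problem sizes and determinism

Tests and the acceptance script run phantoms at 48³–96³ voxels and
clustering cohorts of 10 volumes; these sizes give every structural claim
(map counts, id sets, overlap, oracle agreement) full coverage while
keeping a laptop-scale footprint. All randomness flows through explicit
seeds (numpy `default_rng`; k-means seeded per (volume, k)); the entire
pipeline is bitwise reproducible run-to-run, and the test suite asserts it.

## Known limitations

- The masking and bias models are intentionally simple; strongly
  inhomogeneous or low-SNR scans may need an external mask
  (`mask_method: provided_mask`) or a dedicated correction tool.
- Oblique acquisitions are reoriented only if each voxel axis has a
  dominant world axis; truly oblique affines are rejected rather than
  resampled.
- Mirroring assumes the medial face should sit flush at x = 0 and that
  tissue appearance is left-right symmetric; anatomically asymmetric
  synthesis is out of scope.
- The AHD is a voxel-set metric here; surface-based variants (HD95, ASSD)
  are not provided.
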