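# Methods

This note documents the models, conventions and numerical choices behind
`perifocal`, in the order the pipeline applies them, and what the phantom
experiments do and do not demonstrate about real data.

## Geometry and data model

All volumes live on a `VoxelGrid` (shape, voxel size, NIfTI affine,
RAS+, 0-based indices). Every cross-volume operation requires identical
grids, so the first pipeline step re-slices everything to a common 1 mm
isotropic grid in pre-surgical space. Labels and binary masks are
resampled nearest-neighbour — the only label-safe interpolant; no label
resampling can emit a value absent from the input — and PET uptake
trilinearly. Linear interpolation replicates edge samples across the
half-voxel margin at the field-of-view boundary; nearest-neighbour
resampling fills truly outside voxels with background. Rigid transforms
(proper rotation + translation in world mm) are *applied* only; estimating
registrations is out of scope and transforms are inputs.

## Resection-cavity estimation

The cavity estimate is `open(close(pre_bin) \ close(post_bin))`. The
subtraction is oriented pre-minus-post: tissue present before surgery and
absent after is the only physically meaningful cavity, even though the
operation is often described as a set difference the other way round.
Closing fills unassigned voxels left by segmentation; opening removes
thin spurious difference caused by imperfect pre/post co-registration.

Structuring elements: Chebyshev balls (a 3×3×3 cube at radius 1, i.e.
26-connectivity), the smallest element that fills or strips single-voxel
features in any direction; closing and opening default to radius 1 and
both radii are configurable. Closing is implemented dilate-then-erode
with the erosion treating the outside of the array as foreground, which
keeps closing extensive even for objects touching the array border;
opening is intersected with its input, keeping it anti-extensive. An
optional largest-connected-component filter exists but is **off** by
default, since the subtraction chain alone defines the method.

Post-surgical VOI volumes are measured on a *derived* post-surgical label
volume (pre-surgical labels zeroed inside the cavity) rather than by
re-segmenting the resected brain, whose anatomy violates segmenter
assumptions. The VOI itself is defined once on the pre-surgical labels;
its post volume is therefore exactly `pre − |VOI ∩ resVol|`.

## VOI construction

Two VOIs per hemisphere: the mesial gathering (amygdala, hippocampus,
parahippocampal gyrus) and the whole temporal lobe (superior, middle,
inferior temporal, fusiform, temporal pole, transverse temporal,
entorhinal, parahippocampal, hippocampus, amygdala). Where a VOI contains
cortical areas — the temporal-lobe VOI — subcortical white matter within
5 mm of the cortical ribbon is included. The band is computed as a
Euclidean distance transform in world mm over same-hemisphere
white-matter voxels, threshold inclusive (≤ 5 mm); the metric and
inclusivity are conventions of this implementation. The mesial VOI adds
no white matter even though it contains parahippocampal cortex; whether a
band should apply there is genuinely ambiguous and the narrower reading
was chosen and is stated here rather than silently generalised.
Hemisphere membership always comes from the label dictionary, never from
voxel coordinates, so tilted real-world volumes behave identically to the
axis-aligned phantom.

## Asymmetry classification

For each tracer and VOI, the reference Ū is the plain arithmetic mean of
uptake over the anatomically intact contralateral homotopic VOI from the
pre-surgical labels (abnormal-looking contralateral voxels are *not*
excluded; the reference is a plain mean by design). An ipsilateral VOI
voxel is abnormal iff `u < (1 − f)·Ū` with f = 0.10 by default. The
comparison is strict: "10 % less than the mean" is read as *exceeding* a
10 % deficit, so a voxel at exactly 0.9·Ū is normal. The threshold is a
parameter for sensitivity analyses. No PET smoothing is applied before
classification (a hook exists, default off). Dynamic FMZ is collapsed to
a static volume by overlap-weighted frame averaging over 600–1200 s of
the scan before classification.

Only ipsilateral-lower asymmetry is detectable by construction: a
bilaterally symmetric deficit raises and lowers Ū identically and yields
an empty mask. Cohorts analysed this way must therefore exclude bilateral
homotopic abnormalities, and the pipeline makes no attempt to detect
them.

Non-resected abnormality is the exact set difference `abn \ resVol`; its
percentage of the abnormality volume is undefined (an error, not 0) when
no abnormality exists. Percentages are computed per patient first and
averaged across patients for cohort tables; group means of percentages
are not ratios of group mean volumes.

## Phantom generator

The phantom is a 96³ voxel, 1 mm isotropic bilateral brain built from
boxes and ellipsoids: six lateral temporal neocortical slabs, a
contiguous mesial block (amygdala, hippocampus, entorhinal,
parahippocampal), temporal white matter filling the envelope between
them, and an extra-temporal filler. The right hemisphere is painted
explicitly and reflected through the midsagittal interface, so homotopic
structures have *identical* voxel counts — any downstream asymmetry is
the planted one. Overlapping explicit structures are an error.

Simulated resections remove the lateral structures within a configurable
distance of the temporal tip (default 40 mm) plus, optionally, the whole
mesial block en bloc; the cavity is verified to be a single 26-connected
component. Co-registration error is modelled as a deterministic rind of
configurable thickness stripped from the outer pre-surgical brain surface
of the post volume; the `seed` field of the resection spec is reserved
for stochastic jitter variants. PET uptake is baseline 100 over the
brain, reduced by the deficit fraction (default 0.20, against the 0.10
classification threshold, so noiseless recovery is exact) inside the
planted region, with independent additive Gaussian noise per voxel and
frame (the default cohort uses sd 5, i.e. 5 % of baseline); background is
zero. Dynamic scans replicate the clean volume per frame with independent
noise. Engel outcomes are drawn from a logistic model over mean-centred
covariates; the default cohort uses a *null* model at the reference
class-I rate of 25/32 with a 20:12 left:right split, II:III:IV in 1:2:4.

In the default simulated cohort the FDG deficit spans the mesial block
plus up to ~90 % of the lateral lobe and the FMZ deficit a thinner
anterior slab, while resections remove only the anterior 30–45 mm — so
temporal-lobe abnormalities are partially non-resected, whereas mesial
deficits are almost entirely resected (mesial resections are en bloc).
Patient cohorts show substantial non-resected mesial fractions; the
phantom does not emulate that, and tests passing on phantoms demonstrate
the *correctness of the set algebra and classification*, not the clinical
distribution of the volumetrics. The phantom also omits PET physics
(scatter, attenuation, partial volume), MRI artifacts and anatomical
realism; results on phantoms bound what the pipeline can recover under
ideal geometry, nothing more.

## Statistics

Paired and independent-samples *t* tests are computed from their textbook
closed forms (the independent test pooled-variance by default, matching
generic single-line "independent samples t test" reporting; Welch by
option), with 95 % CIs from the t distribution. Logistic fits use
maximum likelihood (Newton/IRLS, tolerance 1e-8, 100 iterations); the
odds ratio is per unit of the predictor on its native scale (mm³ or
percentage points, hence ORs printed near 1.0000 for mm³-scale
predictors; a rescaling option exists for readability). The C-statistic
is the AUC of the fitted probabilities, which for a univariate monotone
model equals rank concordance of the raw predictor — a property the test
suite checks against a brute-force all-pairs count. Complete separation
is reported as a non-converged result carrying the rank C-statistic, not
an exception. Only the point estimate of the C-statistic is reported, no
CI. Alpha is 0.05 two-sided with no multiple-testing correction; the
report counts the tests it ran. Degenerate zero-variance group
comparisons (possible on perfectly symmetric phantoms) are flagged, not
raised, so a cohort run survives them.

## Problem sizes and determinism

Phantoms are 96³; the simulated reference cohort is 32 subjects;
calibration experiments use 1000 null replicates (type-I error), 200
replicates at n = 500 (Wald coverage) and 100 randomized mask pairs at
48³ (conservation). These sizes make every property checkable exactly or
to tight Monte-Carlo bounds while keeping a full run to about a minute.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give bit-identical volumes,
cohorts and reports. In cohort simulation, per-subject seeds derive from
the cohort seed, and a drawn cohort leaving fewer than two subjects in an
outcome group is rejected by the statistics stage (subgroup tests are
undefined there) rather than papered over.
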