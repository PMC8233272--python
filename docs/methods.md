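# Methods

This note records the models, parameter choices, and numerical decisions
behind `lsfmatlas`, and what the synthetic phantoms do and do not show
about real light-sheet data.

## Conventions

All volumes are indexed `(z, y, x)`, 0-based, voxel-centered; the physical
position of index `i` is `i × spacing_um`.  Registration runs in voxel
units (volumes are handed to the backend with unit spacing), so transform
parameters and displacement fields are in voxels of the fixed image.
Transforms map fixed-image coordinates into moving-image coordinates — the
pull-back convention used for resampling — and this is stated on every
interface because it is the single most common source of silent atlas
bugs.  Region id 0 is reserved for background everywhere.  The canonical
on-disk intensity type is 16-bit unsigned; in-memory computation widens to
float.

## Preprocessing

*Down-sampling* resamples to an isotropic target grid (default 20 µm) with
anti-aliased linear interpolation; per-axis factors accommodate anisotropic
native acquisition (finer in-plane than axial).  Upsampling is refused.

*Bias correction* estimates a smooth multiplicative field in the log
domain: the log image is smoothed by a wide Gaussian (normalized
convolution over the foreground, default σ = 16 voxels), the zero-mean part
of that surface is divided out, and the output is rescaled to the input
foreground mean.  This is a deliberate design choice over a faithful N3/N4
port: the contract that matters — recovering an injected low-frequency
gradient (Pearson r ≥ 0.9) and halving the coefficient of variation on
flat regions — is enforced by tests, and the simple estimator is fast,
deterministic, and has one interpretable knob.

*Histogram normalization* is quantile mapping onto a reference intensity
sample (during template building, the current average's histogram), and
*CLAHE* uses 8-voxel tiles with clip limit 0.01 — deliberately mild
defaults, both configurable.  A single-valued volume passes through
unchanged.  The pipeline order is fixed: downsample → bias → normalize /
equalize.

## Registration

The engine delegates to SimpleITK's multi-resolution
`ImageRegistrationMethod` with a 32-bin Mattes mutual-information metric.
Affine runs use a geometry-centered initializer and regular-step gradient
descent with physical-shift scaling.  B-spline runs use a control grid
whose final spacing is 8 voxels, doubling per coarser level (default 3
levels, i.e. 32→16→8), optimized by LBFGS2 with the line search capped at
12 evaluations per iteration (uncapped line searches dominate run time on
flat optima such as self-registration).  Metric sampling is random at 25%
with a caller-supplied seed, making every registration deterministic;
requesting a fraction ≥ 1 switches to dense evaluation.

Every accepted registration must not worsen the mutual information;
otherwise the identity transform is returned with a warning.  Inversion is
closed-form for affines and fixed-point dense-field inversion otherwise;
convergence is judged on the domain interior (margin = peak displacement)
because the inverse is undefined where the forward map leaves the domain.
A 99th-percentile round-trip residual above one voxel raises an error
reporting the residual.

## Template construction

Register-then-average: iteration 1 registers every subject to a chosen
reference subject and averages; iteration k ≥ 2 registers every *original*
subject to the previous average.  The default schedule is one affine
followed by five B-spline iterations.  Averaging is the arithmetic mean of
histogram-normalized registered volumes.  Manual orientation steps used in
practice on real data (coronal-slab rotation) are out of scope; an
orientation reference can be supplied upstream.

Symmetrization mirrors one hemisphere onto the other with a logistic blend
(default 4-voxel transition width, a declared choice).  The weight array is
built so that `w(mirror(x)) = 1 − w(x)` holds bit-exactly (the upper half
is assigned `1 − w` of the lower half, and an integer midplane gets
exactly 0.5), which makes the output exactly invariant under mirroring —
tested as bitwise equality, not approximate.

## Annotation transfer

Whole-brain affine+B-spline first; then one B-spline per parental block
with the metric restricted to the block's mask, dilated by 5 voxels so the
block registration sees boundary context (hard crops create edge
artifacts).  Block label volumes are recombined by: uniquely claimed voxels
keep their label; conflicted or unclaimed in-mask voxels take the label of
the nearest uniquely claimed voxel (exact Euclidean distance transform,
per-label, scanned in ascending region id so distance ties deterministically
go to the smaller id).  Manual corrections near the ventricular system are
supported only as a user-supplied label-patch overlay applied last.
Hierarchical collapsing sums leaf counts (or re-maps leaf labels) to
analysis-level ancestors and conserves the total count exactly; the
leaf→ancestor map is data, not something inferred from the ontology.

## Cell detection

The stage order is: slice-wise channel alignment → per-slice disk top-hat
(default radius 7 voxels — larger than a cell so point sources survive) →
autofluorescence veto → 5×5×3 local-maximum seeding (z-extent 3 because
axial resolution is coarser) → seeded watershed above the 800 intensity
cutoff → size filter keeping [8, 194] voxels inclusive.  The cutoff is
applied to the *corrected* specific channel, since the watershed follows
the background and autofluorescence corrections; the convention is recorded
in `DetectConfig` so the alternative (raw-intensity cutoff) is also
reproducible.  A cell's coordinate is its seed (peak), not the segment
centroid.  Plateau maxima tie-break to the lexicographically first voxel,
which is deterministic and oracle-checkable.

Channel alignment is per-slice 2-D registration with Mattes MI, in two
stages: a translation fit, then an affine refinement accepted only if it
improves the metric *and* stays within 3 voxels of the translation solution
at the slice corners.  The cap exists because an unconstrained affine on a
near-featureless slice can drift several voxels while nominally improving
mutual information; genuine rotations/scalings of acquisition pairs move
corners far less.  Slices are processed independently (permuting z permutes
the output identically).

The autofluorescence veto is `clamp(spec − s·auto, 0)` on the
background-subtracted channels.  The scale `s` is estimated from voxels
bright in *both* channels (above each channel's 99th percentile): marker
cells are absent from the autofluorescence channel and tissue texture is
absent from the specific channel, so the shared-bright intersection is
dominated by genuinely shared structures, whose spec/auto ratio is the
quantity wanted.  `s` is the 90th percentile of that ratio rather than the
median: the veto should err toward removal, and over-subtraction is
harmless where the autofluorescence channel is dark — exactly where real
cells live.  Both the selection quantile and the ratio quantile are
configurable, and a fixed `s` can be supplied.

## Heatmaps

Uniform spheres (default radius 20 µm) are stamped around atlas-space cell
centers; sphere membership is voxel-center distance ≤ radius (closed ball),
which makes the digital ball at radius = spacing exactly the 7-voxel
face-neighborhood.  Spheres clip at borders, overlaps sum, and rendering is
order-invariant.  Group contrasts are voxelwise differences of group-mean
maps; no kernel smoothing is applied.

## Evaluation metrics

Deformation magnitude is the per-voxel Euclidean norm of the displacement
field in voxel units.  Intensity variance follows the NIREP definition:
unbiased (n−1) voxelwise variance across registered volumes, averaged over
each region's voxels (mean-of-voxelwise-variance, not variance of region
means — the two readings differ and this one is declared).  Landmark
distances are spacing-aware Euclidean distances in µm; two atlas conditions
are compared per landmark with a two-tailed Welch t-test using the
Welch–Satterthwaite degrees of freedom.

## Count statistics

Per region, counts follow a negative binomial GLM with log link on group
indicators; coefficients are log fold changes versus the designated
control, reported in log₂ units.  The dispersion θ (variance μ + μ²/θ) is
estimated per region — no information sharing — by Pearson-χ² matching:
iterate GLM fits, re-solving for the α = 1/θ that makes the Pearson
statistic equal its residual degrees of freedom.  Plain maximum likelihood
is noticeably biased toward under-dispersion at the 5–8 animals per group
typical of imaging cohorts, which makes Wald tests anticonservative;
moment matching restores calibration.  Wald statistics use the t reference
with residual degrees of freedom and an HC1-style √(n/(n−p)) standard-error
inflation; with these choices the empirical type-I error at α = 0.05 sits
inside the exact binomial band in null simulations at n = 6 per group.

Dunnett's many-to-one adjustment uses the joint multivariate-t distribution
of the contrast statistics with the model's estimated correlation,
integrated by seeded Monte Carlo (200 000 draws); with a single treatment
group the adjustment reduces exactly to the unadjusted two-sided p.
Benjamini–Hochberg FDR is applied across regions within each treatment
comparison, after the Dunnett step — the within-model/across-region order
is declared explicitly.  Diagnostics per region: Cook's distance flags at
4/n, a Shapiro screen on deviance residuals at α = 0.01, and a low-count
flag when any group mean is below 10; flagged regions are reported for the
manual validation step, never dropped automatically.  The visual
"spillover from a neighboring region" check is inherently manual and is
left to the analyst; the diagnostics columns are there to support it.

## Synthetic phantoms

The phantom generator is the package's test bed and defines its study
conditions.  A phantom brain is a smooth ellipsoid (default 96×128×128
voxels at nominal 20 µm) partitioned into adjacent regions (nearest-seed
partition, each ≥ 100 voxels), with autofluorescence = smooth base profile
+ mild per-region offsets + spatially correlated texture (Gaussian-filtered
noise, σ = 6 voxels, sd 1500) + white noise (sd 100).  The texture matters:
a featureless symmetric blob gives mutual information no tangential signal
and makes deformable registration ill-posed; its correlation length is
chosen larger than the detector's opening disk so anatomy does not leak
through the top-hat.  Cells are isotropic Gaussians (peak 3000, σ = 1.5
voxels) on a 200-intensity background with a 20% autofluorescence bleed —
the residual tissue signal that makes real channel pairs alignable.
Artifacts are brighter shared Gaussian blobs placed away from implanted
cells, because an artifact directly on a cell would make the ground-truth
cell/artifact distinction meaningless.  Deformations are Gaussian-smoothed
random vector fields rescaled to a chosen peak magnitude, applied by
pull-back interpolation, with the exact field returned as truth.  Counts
are negative binomial in the same (mean, θ) parameterization the GLM
estimates.  All generators are pure functions of (parameters, seed), using
one named stream per operation so stages never share draw counts.

What the phantoms do **not** emulate: light-sheet stripe and shadow
artifacts, depth-dependent attenuation, vasculature and fiber tracts,
clearing-induced nonuniform shrinkage, and real cross-modality contrast
differences between an LSFM template and a serial-two-photon atlas.
Passing tests therefore demonstrate the pipeline's correctness and
robustness under controlled truth, not its accuracy on any particular real
cohort.

## Problem sizes

Tests and the acceptance script run registration-heavy checks at reduced
but non-trivial sizes chosen as the package's own working points:
full-size (96×128×128) phantoms for single-registration recovery, 32×48×48
phantoms for the multi-registration template runs (a 6-iteration build of
3–4 subjects is ~25 registrations), and 200-replicate simulations for
statistical calibration.  These sizes keep a complete verification run in
tens of minutes on one CPU while leaving every contract at full strength.

## Known limitations

No diffeomorphic or LDDMM registration models and no GPU paths; no
groupwise simultaneous registration (strictly the reference-then-average
iteration); no machine-learned cell classifiers or intensity-based cell
subtyping; no voxelwise statistical parametric mapping; no overlap metrics
(Dice) in the evaluation module — deformation, intensity variance, and
landmarks only.  B-spline field recovery degrades on very small volumes
(few texture features per control cell); the template variance-reduction
contract is unaffected.  The Pearson-matched dispersion is estimated per
region with 10–16 observations and is itself noisy; only its effect on
test calibration is controlled, not its per-region accuracy.
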