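# Methods

`spheromotion` quantifies the dynamics of multicellular salivary
stem/progenitor ("hS/PC") microstructures embedded in hyaluronate
hydrogels: their coordinated rotation, the coverage of their surface by
basement-membrane markers, the "popping" growth cycles of their basement
membrane, and the live/dead and cluster composition of encapsulated
cells. Because no primary imaging is available to distribute, every
quantification is validated against a synthetic-scene generator whose
ground truth is known exactly; this note records the models, the
conventions, and the choices that were genuinely open.

## Synthetic scenes and what they emulate

**Rotating movies.** A microstructure is rendered as a soft-edged disk
(diameter drawn near 34 µm, the observed mean) holding a fixed set of
Gaussian "cell" blobs; rigid rotation is applied analytically to the blob
positions and to the phase of a low-order boundary-roughness harmonic, so
the per-interval rotation is exactly ω·360·Δt/60 degrees — the ground
truth is the applied transform, not an estimate. Frames carry linear
translational drift (default 1 µm/h), additive Gaussian noise (default
σ = 2% of signal amplitude) and a ±5% per-frame intensity jitter chosen
to stress the intensity-invariance of the estimator; none of these are
measured properties of the source recordings, which state no noise
statistics. Acquisition defaults follow the imaging protocol: 5-min frame
interval, 15-h recordings, with a stand-in pixel size of 0.5 µm (the
magnification of the originals is unstated). Scenes do not model
photorealistic optics (PSF, bleaching) or out-of-plane rotation axes; the
movies, like the original analysis, are strictly 2D. An optional per-cell
jitter term produces *uncoordinated* structures for exercising the
inclusion rule.

**Marker shells.** A thin spherical shell (default thickness 2 µm) is
marker-positive over a configurable fraction of its solid angle, split
into a configurable number of equal spherical caps spread quasi-uniformly
and randomly oriented. One continuous cap emulates the continuous
("scrambled-control-like") coverage; many small caps emulate the patchy
("knockdown-like") phenotype. Because caps are equal and disjoint at the
configurations of interest, the marker's true solid-angle fraction equals
the configured coverage fraction exactly.

**Live/dead volumes.** Two channels mark viable and dead cells. Dead
cells are placed only as single cells, matching the observation that
ethidium-positive cells neither divide nor join clusters. Viable cells
are partitioned into clusters by a configured cluster-size distribution
using a deterministic largest-remainder allocation, so the cell-level
clustered fraction sits at the configured operating point for every seed;
only positions are random. Cells of one cluster sit on a small sphere
around the cluster center (cell radius 5 µm), and structures are packed
with a minimum separation (default 25 µm).

**Popping series.** Major/minor-axis series are built in volume space:
each cycle is a slow contractile drift (default −12%/h, small enough to
sit clearly below the pop-detection threshold but above the phase
dead-band) followed by a two-sample tensile ramp. Plateau levels are
solved so that the *median* volume of the contractile phase after a pop
exceeds the one before by exactly the cycle's expansion percent — the
same statistic the detector measures — making the truth and the
measurement commensurable. Axes derive from the volume at a fixed aspect
ratio (1.15) with small multiplicative noise (0.2%).

## Benchmark calibration

The packaged cohort benchmarks pin the ground-truth distribution of
per-structure angular speeds at the reported group operating points:
untreated 0.28 rev/h (n = 49, sd = SEM·√n = 0.14), ITGB1 knockdown
0.04 rev/h (n = 37, sd ≈ 0.061), CD49a-blocked 0.11 rev/h (n = 32,
sd ≈ 0.057). The scrambled-siRNA and non-blocking-antibody control means
were never printed; they are back-solved from the printed reductions
(84% against 0.04 → 0.25 rev/h; 73% against 0.11 → 0.407 rev/h) and
carry the untreated group's coefficient of variation. Speeds are drawn
from a normal law truncated at zero whose location parameter is solved
(Brent) so the *truncated* mean equals the target, and sampling is
stratified (quantile midpoints in random order): the cohort's empirical
truth mean then sits at the calibrated operating point for any seed,
which is what recovery is scored against. An `iid` sampling mode is
available for studying cohort-to-cohort variability. Rotation direction
(CW/CCW) is assigned at random per structure, as both occur within one
gel.

## Rotation estimation

Frames are segmented (Gaussian pre-smoothing of 2 px, Otsu threshold
with fixed override, hole filling), and each frame is resampled to polar
coordinates about its own centroid — which removes translational drift —
over 720 angular bins. Consecutive polar images are phase-correlated
along the angular axis with 20× upsampled refinement, giving per-interval
steps with a noise floor near 0.1°. Angular velocity is
ω = |Σ steps| / (n·Δt) / 360 rev/h, reported as a magnitude with a
separate CW/CCW direction; positive steps are counterclockwise with x
right and y up (image row order inverts the on-screen intuition). Steps
are bounded by ±45° per interval, far above any observed rate
(0.28 rev/h is 8.4° per 5-min interval), purely to prevent aliasing wrap.

A structure enters group statistics only when *coordinated*: median
border solidity ≥ 0.9, at least 0.8 of resolvable (>0.3°) steps sharing
the majority sign, and median rigid-registration residual ≤ 0.15 of the
normalized polar-image energy. Structures whose cells move independently
fail the residual arm (the generator's jitter mode produces residuals
near 1); structures that wobble without net rotation fail the sign arm;
near-static structures are judged by the residual alone, since the sign
of a sub-resolution step is meaningless. These thresholds were fixed on
synthetic fixtures and are exposed as parameters. Axisymmetric
(featureless) structures raise an explicit "unresolvable" error rather
than returning zero: the angular anisotropy of the polar image (ratio of
angular-profile variation to total variation) must exceed 0.05.

## Coverage index

I_C = A_marker / A_s with A_s = 4πr², where r is half the
volume-equivalent diameter of the segmented structure and A_marker is
the summed triangulated isosurface area of the thresholded marker
channel. Marching cubes is used instead of exposed-voxel-face counting,
which overestimates curved areas by up to ~50%; the binarized mask is
additionally anti-aliased (Gaussian, σ = 0.8 voxel) before triangulation,
which cancels most of the residual staircase bias (a full thin shell then
reproduces the closed-form inner+outer sphere area within ~1% at voxels
of r/10–r/20). A closed shell contributes inner *and* outer faces, so
I_C exceeds 1 for continuous coverage — an accepted inflation, since
relative group comparisons run every stack through the same procedure.
Plaque *rim* faces inflate patchy fixtures the same way: eight half-
coverage patches measure ~15% above half the full-shell area, so the
exact factor-2 ratio between full and half coverage holds only for
rim-minimal layouts (a single hemispheric cap). The default marker
threshold is background + 2 SD (the background baselines for laminin,
collagen IV and perlecan are 188, 221 and 48 A.U.), overridable because
the original surface-generation threshold is unstated. Intensity binning
subtracts the baseline I_b before assigning values to the {=0, >500,
>1000, >3000} groups — whether the original analysis subtracted or
thresholded at I_b is unstated, so the subtraction convention is explicit
and overridable; a sub-threshold-but-nonzero remainder bin keeps counts
conservative.

## Popping morphodynamics

Volumes use the prolate convention V = (4/3)π(a/2)(b/2)² from the two
measured axes (an oblate alternative is provided; the original volume
formula is unstated). The volume series is median-smoothed (window 3),
the relative rate taken by central differences, and samples classed
tensile above a dead-band of 8%/h — near-zero rates resolve to
contractile, an arbitrary but fixed tie-break. A pop is a tensile
segment whose mean relative rate exceeds 30%/h (calibrated on synthetic
fixtures so 0.67-h cycles with ≥20% expansion are detected at 5-min
sampling); flanking volumes are medians over the neighbouring
contractile plateaus, and cycles run pop-to-pop. The peripheral statistic
for proliferation markers reports the fraction of positions in the outer
25% radial shell — "periphery" has no stated width, so the shell fraction
is a parameter.

## Viability and clustering

Cells are detected as peaks of the smoothed channel sum and classified by
dominant channel with a 2:1 net-intensity margin; ambiguous cells are
reported as unclassified rather than forced, since the original
classifier is undescribed. Viable cells are grouped by single linkage at
a contact distance of two cell radii plus a 2 µm surface gap (the
original cluster-membership criterion is unstated). Cluster-size
histograms are half-open — bin k covers [k, k+1), including k and
excluding k+1 — and a box-ROI option supports evaluation over regions of
equivalent volume.

## Statistics

Groups are summarized as mean ± SEM. Two groups are compared by an
unpaired Student's t-test (Welch off by default, available by flag);
more than two by one-way ANOVA with a Tukey HSD post-test (the post-test
family is unstated in the source; Tukey is documented and swappable).
Significance is flagged at α = 0.001. A permutation oracle (exact
enumeration for n ≤ 8 per group) cross-checks the parametric p-values in
the tests, and ω is reported to two decimals, percent reductions to whole
percents. The modulus utility converts storage modulus to Young's modulus
by E = 2G′(1+ν) with ν ∈ [0, 0.5].

## Problem sizes and limitations

The packaged benchmarks use the reported group sizes (49/25/37/14/32
movies of 181 frames at 0.5 µm/px), 20 popping series of 3 cycles, and a
150-cell day-5 viability volume; together they run in a few minutes on
one core. Passing recovery on these scenes shows the estimators are
unbiased and robust at the stated noise, drift and intensity-jitter
levels — it does not certify performance on real recordings with optical
blur, focus drift, out-of-plane motion or segmentation failure modes the
generator does not model. Per-structure agreement with the original
manually measured ω cannot be claimed (the manual protocol is unstated);
only recovery of generator truth and of the calibrated group-level
operating points is demonstrated.
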