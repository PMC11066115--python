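# Methods

## Virtual angiography model

The enhancement assumes the cine frames are co-registered and the
non-vascular background is static, so that frame-to-frame intensity
changes are dominated by speckle decorrelation from moving blood cells.
Under that assumption the mean absolute temporal difference

    I_VA = Σ_t |I_{t+1} − I_t| / (T−1)

is exactly zero at static pixels and positive wherever intensity
fluctuates — i.e. inside perfused lumens. The estimator has useful exact
symmetries that the tests assert: adding a constant to every frame leaves
I_VA unchanged (differences cancel offsets), scaling all frames by α ≥ 0
scales I_VA by α, and a static loop gives an identically zero angiogram.
It is order-sensitive by construction (adjacent differencing), and no
permutation invariance is claimed.

Both the batch form and the streaming update
`I_VA,t = ((t−1) I_VA,t−1 + |ΔI_t|)/t` are provided; `t` counts the
differences consumed, so after all T−1 updates the stream equals the batch
mean. All accumulation is in float64 regardless of input depth, which
keeps the two routes within 1e−9 per pixel (empirically ~1e−16) even for
32-frame loops.

No motion correction is applied. If the embryo or transducer moves, the
background assumption is violated and the moving structures leak into the
angiogram; users should trim such segments before processing.

### Display mapping

The angiogram's dynamic range is dominated by a few strong-flow pixels.
For display (and as snake input) it is clipped at an upper percentile
(default 99.5) and rescaled linearly to [0, 1]; the mapping is monotone
below the clip and an all-zero angiogram maps to zero. The clip level is
recorded so renderings are reproducible.

## Annotation

**Splines.** Closed boundaries use a periodic cubic interpolating spline
through the ordered points, open curves a natural cubic spline (a straight
segment for exactly two points). Interpolating — not approximating —
splines were chosen so every annotated point lies on the returned curve.
Curves are resampled uniformly in the knot parameter; boundary sample
counts are a multiple of the knot count (so knots are among the samples)
and at least 8.

**Snake.** The CAM-vessel boundary evolves from the outer contour of the
ROI's largest connected component, resampled to `n_points`. The evolution
minimizes the classic internal energy (elasticity α, rigidity β) plus an
edge energy from the Gaussian-smoothed (σ) display image; the engine is
scikit-image's `active_contour`, driven in 25-iteration chunks so that the
stopping rule — mean point displacement per iteration below `tol` — and
the `converged` flag are under this package's control. Non-convergence at
`max_iter` is reported in metadata, not raised. Defaults
(n_points=200, α=0.015, β=10, σ=2 px, w_edge=2, max_iter=2500,
tol=0.1 px) were calibrated on the disk phantom: with them the snake
recovers disks of radius ≥ 10 px at contrast ≥ 0.5 to within 10% area
error and well under 1.5 px mean radial error. Known limitation: on flat
(gradient-free) regions the contour contracts very slowly under internal
energy alone and the displacement test can report convergence while the
curve is still creeping; the snake needs a seed within the edge's capture
range (a few σ), as is normal for this algorithm family.

**Skeletonization.** Masks are thinned to an 8-connected one-pixel
skeleton (Zhang thinning via scikit-image). Two cleanup passes make the
topology usable for counting: (1) *spur pruning* removes endpoint-to-
junction paths shorter than `prune_px` (default 5 px), iterated to a fixed
point, followed by re-thinning; (2) *redundant-corner removal* deletes
degree-2 pixels whose two neighbors touch each other — staircase triangles
that thinning leaves at oblique tube tips and that would otherwise fake
junctions. Junction pixels are skeleton pixels with ≥ 3 skeleton
neighbors; adjacent junction pixels merge into one junction node (branch
point). The skeleton is decomposed into polylines broken at junction
nodes, each ordered endpoint-to-endpoint with steps of at most √2 px.
Objects that thin to a single pixel yield no curve.

## Quantification

Per-curve length is the Euclidean polyline length (1/√2-weighted steps).
Skeleton-derived curves are first corner-smoothed with a 5-point moving
average of vertex positions: raw pixel staircases overestimate oblique
straight runs by up to ~8% (worst near 15–30°), and the smoothing brings
length estimates within ~2% of the unrotated value at any orientation.
Analytic/manual curves are measured raw.

Diameter at a centerline point is `2·EDT − 1`, where EDT is the Euclidean
distance transform of the vessel mask sampled bilinearly at the point.
The −1 px correction accounts for the object boundary lying half a pixel
inside the nearest background pixel *center* that the EDT measures; with
it, tubes of half-width w ∈ {2, 3, 4, 6} px are recovered within ±1 px of
diameter 2w. Without a mask, diameters are reported as 0 and flagged.

Branch points are the merged skeleton junction nodes; for manually drawn
curve sets they are inferred as endpoint clusters (within √2 px) shared by
at least three curve ends. Pruning precedes counting, so `prune_px`
affects branch counts — by design, since boundary-noise spurs would
otherwise each add a junction.

Pixels are the primary unit; all lengths/diameters are mirrored in mm only
when `pixel_size_mm` is supplied.

## Synthetic cine simulator

The simulator reproduces the contrast mechanism the method relies on and
nothing more: a frozen background (mean 0.25 + Rayleigh speckle σ = 0.08,
blurred 1 px, clipped to [0, 1]) and, per vessel, scatterers seeded by a
Poisson process (default 4 per 100 px² of lumen) that advect along the
centerline at `flow_px_per_frame` (wrapping at tube ends so density stays
stationary) and render as Gaussian blobs of sd = half-width/2, amplitude
0.5, truncated at 3 sd. The truncation makes the no-jitter angiogram
*exactly* zero outside the tube dilated by 3 sd, giving a sharp
containment oracle. Optional additive Gaussian frame jitter (sd 0.01 in
the noisy benchmarks) emulates electronic noise. One seed per scene is
split deterministically between speckle, per-vessel scatterers and jitter,
so rendering is bit-reproducible and changing the frame count leaves the
background unchanged.

Three frozen 256×256, 64-frame benchmark scenes (`single_tube`,
`bifurcation` with 1 branch point, `tree3` with 3) use half-width 4 px and
flow 2 px/frame throughout; the single tube is 200 px long. These sizes
keep every end-to-end check under a few seconds while leaving tubes long
enough that end effects (~one tube radius per tip) stay well inside the
length-recovery bound (width + 2·prune_px).

What the simulator does **not** model: acoustic point-spread functions,
attenuation/TGC, out-of-plane motion, cardiac/embryo bulk motion, and
realistic fully developed speckle statistics inside vessels. Passing
recovery tests therefore demonstrates the pipeline's correctness under
its stated assumptions (static registered background, flow-induced
intensity fluctuation), not its robustness to motion artifacts in real
recordings.

## Automatic pipeline choices

The interactive workflow seeds the snake and skeleton manually; the
`pipeline` command needs an automatic path for reproducible end-to-end
runs and uses Otsu thresholding of the display image followed by standard
mask cleanup — closing (radius 2 px), filling holes ≤ 64 px, removing
objects ≤ 32 px — before skeletonization. Without the cleanup, speckle-
sized holes and tip blobs in the thresholded mask create skeleton loops
and fake junctions. These sizes assume vessels wider than ~2 px and
thinner than ~60 px at the default scene scale and are exposed as
function parameters.

## I/O conventions

Coordinates are 0-based (row, col), row 0 on top, pixel centers at
integers; all processing is float64 on [0, 1]; integer files are divided
by their dtype maximum (255/65535) on read, never min–max stretched, so
normalization is idempotent and intensity ratios are preserved across
files. Multi-frame TIFF is the lossless reference format. AVI support is
a single codec-free flavor — uncompressed 8-bit grayscale RIFF/DIB —
written and parsed directly, hence lossless and bit-stable; compressed
AVIs are rejected with a clear error. Writing quantizes [0, 1] to 8/16
bits with round-half-away-from-zero. Annotations (ordered points, closed
flag, run-length-encoded masks) persist as JSON with full float
precision.
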