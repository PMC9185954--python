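# Methods

This note documents the models, conventions and numerical choices behind
myotubekit. It is the reference for *why* each default is what it is; the
README covers *how* to run things.

## Problem setting

Differentiated satellite-cell (adult muscle stem cell) cultures are imaged
per field of view as a blue nuclear channel (Hoechst), a red myotube channel
(anti-myosin-heavy-chain, MyHC) and optionally a green nuclear-marker
channel (e.g. MYOD). From these the package quantifies six outcome
parameters per image set:

| parameter | definition |
|---|---|
| fusion index | nuclei inside MyHC-positive myotubes / all nuclei |
| number of clusters | nucleus-centroid clusters of ≥ 4 members under a 14 µm single-linkage cutoff |
| average RMSE | unweighted mean over clusters of orthogonal-regression RMSE (µm) |
| number of myotubes | connected objects in the curated myotube mask |
| branching points | merged junction pixels of the myotube skeleton, summed over myotubes |
| myotube coverage | % of image pixels inside the myotube mask |

plus local myotube diameters at caller-chosen sample points, and the
ICC/SEM/MDD statistics used to establish inter-rater reliability of all of
the above.

## Conventions

* Intensities are floats in [0, 1]; integer rasters are divided by their
  dtype's maximum on load (255 for 8-bit, 65535 for 16-bit).
* Coordinates are (row, col), 0-based, pixel-center. Lengths convert to
  microns through one `PixelCalibration` (µm per pixel edge) shared by all
  steps.
* Foreground connectivity is 8-connected, background 4-connected (the
  standard dual pair). Both the myotube count and the hole-filling border
  rule depend on this choice; it is fixed rather than configurable per call
  so that counts are comparable across analyses.
* PNG and JPEG are the accepted input formats. TIFF is rejected explicitly
  rather than silently mis-read.

## Preprocessing

`adjust_levels` maps the window [low, high] linearly onto [0, 1] with
clipping — plain intensity windowing. It is monotone, idempotent for the
full window, and never produces values outside [0, 1]. Adjusted images are
persisted as 8-bit PNG (`*_adjusted.png`, overwritten on repeat); 8-bit
output is a choice, not a requirement of the windowing itself, and is noted
here because the source bit depth is not preserved.

## Mask construction and editing

Segmentation of the red channel is a *manual* global threshold (strict
`>`; pixels exactly at the threshold are background). No automatic
threshold is attempted because MyHC staining intensity varies with
expression level and acquisition settings; reproducibility comes from
recording the threshold in the run log, not from estimating it.

Cleanup operators:

* `remove_junk`: drop foreground components with area < 1000 px (area in
  raw pixels, deliberately not µm²; the boundary is inclusive — 1000 px
  survives). Implemented via connected-component labeling and an area
  census, keeping the strict-inequality boundary explicit.
* `fill_holes`: background components that do not touch the image border
  become foreground (4-connected background).

Both are idempotent; `remove_junk` never adds and `fill_holes` never
removes foreground.

Manual corrections are replayed from an `EditScript` (JSON): polygons to
add/remove regions, polylines to separate/join myotubes, plus in-sequence
junk removal and hole filling. Separation lines default to 2 px wide — a
1-px 8-connected line does not sever 8-connected foreground, so the default
guarantees that a drawn separation actually splits the object.

## Nucleus detection

The blue channel is smoothed with a normalized disk filter of radius equal
to the nucleus radius (10 µm diameter default, converted to pixels and
rounded, minimum 1 px; a calibration at which the diameter is ≤ 1 px is an
error). Regional maxima of the smoothed image above a foreground threshold
(Otsu's value by default, configurable) seed a watershed of the thresholded
foreground; maxima closer than one nucleus radius are merged so a flat or
noisy smoothed peak cannot split one nucleus into two. One centroid per
watershed object is returned.

Classification is a centroid test: a nucleus is "in a myotube" iff its
centroid pixel carries a positive myotube label, and "marker-positive" iff
its centroid falls on the thresholded green mask (default threshold 0.5 on
the adjusted channel). Centroids are the only nucleus geometry kept, so no
area-overlap rule is defined. The fusion index is in-myotube / total and is
an error — not 0 — for an empty nucleus set.

## Nucleus clustering and linearity

Single-linkage agglomerative clustering on centroid-to-centroid distances
in µm, merging while the nearest-pair distance is ≤ cutoff. The cutoff is
nucleus diameter + maximum edge-to-edge gap = 10 + 4 = 14 µm by default; a
pair at exactly 14 µm merges. The edge-to-edge narrative is encoded
entirely in that sum — distances themselves are center-to-center. Groups
smaller than 4 get label −1. By the chaining property, the result equals
the connected components of the ≤ 14 µm threshold graph; this identity is
exact, makes the outcome independent of merge-order tie-breaking, and is
the primary correctness test (union-find oracle). Clusters are numbered by
first member index for input-order stability.

Linearity per cluster is orthogonal regression (total least squares): the
principal axis of the centered scatter, scored by RMSE = √(λ_min/n) where
λ_min is the smaller eigenvalue of the 2×2 scatter matrix. RMSE is reported
in µm (consistent with the µm cutoff; stated in output headers). It is
invariant under rigid motions and point reordering, scales linearly with
isotropic scaling, and never exceeds the OLS vertical-residual RMSE.
Numerics: λ_min below 1e−12·λ_max is snapped to 0 (eigensolver noise on
exactly collinear input would otherwise surface as ~1e−8); isotropic
scatter breaks the axis tie toward the x-axis (arbitrary, documented);
coincident points are a degenerate-cluster error. The per-image "average
RMSE" is the unweighted mean over clusters (not nucleus-weighted) and is
reported as missing — never 0 — when there are no clusters.

## Myotube morphology

The mask is thinned to a 1-px topology-preserving skeleton
(`skimage.morphology.skeletonize`). Branch candidates are skeleton pixels
with ≥ 3 skeleton neighbors (8-connectivity); adjacent candidates merge
into one point (centroid snapped to the nearest skeleton pixel), since
thinning yields 2–3 adjacent junction pixels at one real branching.
`min_branch_length` (default 0) optionally strips endpoints that many times
before detection, consuming spurs up to that length; the default leaves
spur suppression to editing, mirroring the manual-deletion workflow the
tool replaces. Closed loops and through-paths survive pruning.

Coverage is 100 × foreground/total pixels, with per-myotube contributions
that partition the total exactly.

Diameter at a sample point: snap to the nearest skeleton pixel (Euclidean),
read the Euclidean distance transform of the mask there, double it, convert
to µm. Snapping removes the error of an off-center click; near junctions
the distance is no longer perpendicular to the tube axis, so sample-point
choice remains the analyst's responsibility and no automatic sampling
protocol is provided (deliberately — subjective sampling was the reason the
diameter parameter resisted standardization). Recovery on synthetic
constant-width ribbons is within ±2 px for widths 8–30 px; a ±1 px parity
effect exists for even widths because a discrete ribbon stamped from a 1-px
centerline is always an odd number of pixels across.

## Reliability statistics

McGraw–Wong single-measure forms from the ANOVA mean squares of the
n×k ratings matrix (MSR between subjects, MSC between raters, MSE residual,
MSW within subjects):

* ICC(1) = (MSR − MSW)/(MSR + (k−1)MSW) — one-way random.
* ICC(C,1) = (MSR − MSE)/(MSR + (k−1)MSE) — consistency; blind to a
  constant rater offset.
* ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) — absolute
  agreement; ICC(C,1) > ICC(A,1) flags systematic rater bias.

95% CIs are exact F-based (Satterthwaite df for the A,1 denominator).
Degenerate inputs (zero between-subject variance) warn and still report.
Estimates and intervals are cross-checked in the test suite against an
independent direct-summation ANOVA oracle and against `pingouin`.

SEM defaults to pooled SD × √(1 − ICC), as a percentage of the grand mean
(matching "% of mean observation" reporting); √MSE is available via
`method="error_ms"` — the two differ whenever MSC ≠ MSE, and no claim is
made about which variant produced any previously published table.
MDD = SEM × 1.96 × √2 identically.

## Synthetic scenes

The generator renders ribbons (pixels within width/2 of a polyline;
constant width, round caps), nuclei as anisotropic Gaussian blobs truncated
at 2σ with peak ≥ 5× the background noise SD at default settings, optional
green re-renders of marker nuclei, and Poisson-plus-Gaussian noise behind a
single `noise_level` knob (0 = noiseless). Ground truth (exact mask and
labels, nucleus table, junctions, widths, coverage) is returned alongside.
`make_cluster_scene` plants k line-aligned clusters at 12 µm spacing
(within the 14 µm cutoff) with ≥ 2× cutoff separation between structures,
perpendicular jitter σ controlling true RMSE, plus isolated nuclei.
Identical spec + seed is bit-reproducible.

Limitations of the emulation: no PSF/optics, no uneven illumination, no
debris or overlapping nuclei beyond what spacing permits. Tests passing on
these scenes demonstrate algorithmic correctness under the stated
conditions, not robustness to real acquisition artifacts.

## Pipeline and problem sizes

Steps (`adjust → mask → nuclei → clusters → branch_points → diameters →
summary`) each read prerequisites from and write artifacts to the output
directory, so `resume_step` re-runs any step plus everything downstream;
missing prerequisites raise a dependency error naming the artifact. CSVs
are the canonical, byte-stable output surface; the Excel workbook mirrors
them with one sheet per step. Every run writes a `run_log.json` with all
parameters and the package version.

Verification problem sizes (the package's own choice of test scale):
100 random point sets of ≤ 200 points for the clustering-oracle identity,
50 synthetic 256×256 fields for detection recall/precision and end-to-end
fusion index, 1000 random sets for the TLS ≤ OLS inequality, and 500
replicates of n = 200 two-rater simulations for ICC(1) recovery.

## Known limitations

* The nucleus detector assumes roughly uniform nucleus size; strongly
  varying sizes would need a per-image diameter.
* Mask thresholding is global; uneven illumination must be handled upstream
  or with edit scripts.
* The myotube count follows the mask-object definition (no ≥ 2-nuclei
  post-filter by default; `nuclei_per_myotube` in the per-myotube table
  lets a caller apply one).
* Branch-point counts on noisy masks are sensitive to skeleton spurs;
  use `min_branch_length` or edit scripts.
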