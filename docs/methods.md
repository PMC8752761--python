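# Methods

`neurovasc3d` quantifies the three cellular compartments of the
neurovascular unit — endothelium, pericytes and microglia — from
multi-channel 3D fluorescence z-stacks, and validates every stage on
synthetic phantoms whose ground truth is known analytically. This note
documents the models, the parameters that matter, the numerical choices,
and what the phantom validation does and does not establish.

## Conventions

Arrays are ordered (z, y, x). The physical position of a voxel is
`index × spacing` in µm, with the origin at the centre of the first voxel.
Topology (connectivity, thinning) is computed on the voxel grid; every
length, distance, area and volume is computed in physical units, so
anisotropic acquisitions (e.g. coarse z sampling) are handled throughout.
Stacks are read and written as TIFF/OME-TIFF; a stack without a voxel
calibration in its metadata is an error unless an explicit spacing or a
YAML sidecar is supplied — densities are meaningless without it. The 2D
merge of a z-stack is a maximum-intensity projection, the standard choice
for sparse bright structures in epifluorescence.

## Vessel and pericyte segmentation

A voxel is classified as vessel when its intensity strictly exceeds
`threshold_factor ×` the mean intensity inside a spherical window of
physical radius `local_window_radius` (default 40 µm) centred on it; at
image borders the mean is taken over the in-bounds part of the window.
Connected components (26-adjacency) with physical volume below
`min_component_volume` (default 500 µm³) are then removed. The pericyte
channel is segmented with the identical rule so the two masks are mutually
compatible for the coverage analysis.

The window mean is computed exactly by FFT convolution of the image and of
a ones-image with the ball footprint (numerator and in-bounds counts);
ties between a voxel and its own window mean are broken *against*
foreground up to an intensity-scaled epsilon (~1e-9), so a constant image
yields an empty mask rather than FFT round-off speckle.

Two parameters deserve care on noisy data:

- `threshold_factor` (default 1.0, the literal reading of the rule). With
  additive sensor noise the literal rule marks roughly half of all
  background voxels, far above the ~0.1 site-percolation threshold of the
  26-neighbourhood: background speckle then merges into one giant
  component that the volume filter cannot remove. The factor should place
  the threshold at about the background level plus 3–4 noise standard
  deviations.
- `smoothing_sigma_um` (default 0). An optional Gaussian denoising of the
  image before thresholding. Uncorrelated noise also roughens the mask
  surface, which the skeletonisation turns into spurious side branches;
  ~1 µm of smoothing suppresses both effects at the cost of dilating the
  mask by roughly one voxel.

All phantom validation in this package runs with `threshold_factor = 2.0`
and `smoothing_sigma_um = 1.0`, which for the default synthetic conditions
(background 10, structure amplitude 150, noise σ = 15) puts the threshold
at ≈ background + 4 effective-noise SD. These were chosen from that
signal-to-noise argument, mirroring the practice of calibrating
segmentation parameters per acquisition protocol.

## Medial axis and morphometry

The vessel mask is reduced to a curve skeleton with 3D parallel thinning
(scikit-image's `skeletonize`, Lee's 6-subiteration topology-preserving
algorithm): a one-voxel-wide subset of the mask with the same connected
components, no new cavities or tunnels. Parallel thinning can erase a very
small blob outright; any mask component left without a skeleton voxel is
restored as its innermost voxel (maximum of the Euclidean distance
transform), keeping the component count invariant.

**Adjacency pruning.** Skeleton voxels are connected under the
26-neighbourhood, but a digitised oblique curve carries redundant chord
edges: in a staircase corner a–b–c, a and c are themselves 26-adjacent. An
edge is pruned when its endpoints share a common skeleton neighbour
reachable by two strictly shorter steps (in µm). Pruning cannot disconnect
the graph (the detour uses strictly shorter edges, by induction on edge
length) and leaves each true adjacency counted exactly once. Without it,
chord edges both inflate arc-length and raise corner voxels to degree 3,
which would masquerade as branching points.

**Classification.** On the pruned adjacency, voxels with ≥ 3 neighbours
are branching points, voxels with exactly 1 neighbour termination points,
the rest regular. Thinning a wide junction can leave a small cluster of
high-degree voxels; 26-adjacent branch voxels are merged into a single
junction before counting, so branch density does not scale with
resolution.

**Arc-length and length density.** The skeleton graph is decomposed into
maximal chains between junction/termination voxels (cycles split
arbitrarily). The raw polyline through the voxel centres of a chain
zigzags around the true centerline by up to half a voxel, overestimating
the length of oblique segments by 5–15% — beyond the 5% recovery target
this package holds itself to. Chains are therefore smoothed with a short
moving average (window 5 voxels, endpoints fixed) before summing segment
lengths; on phantoms this reduces length errors to 1–2% while leaving
curvature at scales above a few µm intact. Length density is total
arc-length (mm) over image volume (mm³). Pericyte coverage, a ratio of
arc-lengths, uses the raw (unsmoothed) edge sums: the digitisation bias
cancels between numerator and denominator.

**Tortuosity.** Every skeleton voxel is assigned a segment: all skeleton
voxels of the same connected component strictly within 20 µm (Euclidean,
physical units). A total-least-squares line — the first principal
direction through the segment centroid — is fitted, and the mean
perpendicular point-to-line distance is that voxel's tortuosity (µm); the
image value is the plain mean over voxels with a fittable (≥ 2-point)
segment. Orthogonal regression is used because "voxel-to-line distance"
is a perpendicular distance and coordinate-wise regression would be
axis-dependent; restriction to the connected component keeps a nearby but
disconnected vessel out of the fit. The continuous-curve oracle
(`reference_tortuosity`) evaluates the same statistic on a densely sampled
parametric curve with no voxelisation and serves as the convergence
target; phantom agreement is within ~5% for arcs and helices. Note the
statistic is an index, not a dimensionless ratio: it grows with local
curvature and saturates once the curve's deviation inside a 20 µm ball
saturates.

**Pericyte coverage.** Axis voxels outside the pericyte mask are removed;
coverage is the arc-length of the remaining sub-axis (edges with both
endpoints retained) over total axis arc-length, in [0, 1].

## Microglia detection and interaction

The microglia channel is convolved with a Laplacian-of-Gaussian kernel of
σ = 5 µm expressed in physical units (per-axis second derivatives scaled
by 1/spacing²), negated and σ²-normalised so bright soma-scale blobs give
positive peaks; the truncated derivative kernels are DC-corrected so a
constant image maps to exactly zero. For a Gaussian blob of amplitude A at
the matched scale the peak response is 3A/2^{5/2} ≈ 0.53 A. Candidates are
26-neighbourhood local maxima with response > 15 (the threshold is
configurable because the response scale follows the input bit depth; the
synthetic scenes render somata at amplitude 150, response ≈ 75).

Each candidate defines a sphere of radius 5√3 ≈ 8.66 µm. The overlap
fraction of two equal spheres is their lens intersection volume over one
sphere volume — the only symmetric choice for equal radii. Pairs with
overlap > 0.2 are processed in ascending order of centre distance (ties
broken by candidate order), and one member of each still-alive pair is
removed, chosen uniformly by a generator seeded from `rng_seed`: removal
is "random" as specified, yet a run is bit-reproducible, and a single
pass over the sorted pairs suffices because removals never create new
overlaps.

Per-cell distance to the vasculature is the exact Euclidean distance from
the detection centre (a point) to the nearest vessel-mask voxel centre
(KD-tree over foreground voxel coordinates in µm). A cell closer than
5 µm is a contact. Sphere radius is deliberately *not* subtracted: the
rule applies to detected cell positions, and subtracting 8.66 µm would
make contact nearly universal. Reported per image: mean distance, contact
ratio, and 3D density (cells/mm³). With zero detections the mean and the
ratio are reported as missing (NaN), never as 0.

The planar branch computes, from projected cell positions: density
(cells/mm²), per-cell nearest-neighbour distance (NND, µm) and the
spacing index `density × NND²`. The spacing index keeps those mixed units
(mm⁻² · µm²) exactly as defined rather than silently rescaling; values
are therefore comparable only within a fixed unit convention.

## Synthetic phantoms

`generate_scene` renders three channels from a continuous scene
specification: vessels as tubes of constant radius around polyline or
parametric centerlines (exact point-to-segment distance, rounded end
caps), pericyte sleeves as flat-ended annuli over arc-length intervals of
a tube (flat ends so a sleeve covers exactly its interval), and somata as
3D Gaussian blobs (σ = 5 µm). Optical blur (Gaussian, default σ = 1 µm),
an optional background gradient, and additive Gaussian noise are applied
afterwards, then clipped at zero. Defaults mirror the target acquisition:
54 planes at 1 µm z-step with ≈1 µm in-plane sampling, structure amplitude
150 over background 10, noise σ = 15 (soma SNR 10).

Ground truth — total centerline length, declared junction count, sleeve
coverage fraction, analytic cell-to-wall distances and the < 5 µm contact
flags, per-tube cylinder volumes and continuous-curve tortuosity
references — derives from the continuous specification only, never from
the rendered voxels, so generator and analyser share no code path.

What the phantoms do **not** emulate: a realistic PSF (z-elongation),
photobleaching, vessel radius variation and branching angle statistics of
real cortical networks, pericyte morphology beyond sleeves, microglial
processes, autofluorescence, or intensity-dependent (Poisson) noise.
Passing the suite therefore demonstrates correctness of the measurement
chain under controlled degradation, not end-to-end accuracy on tissue;
segmentation parameters in particular must be recalibrated per real
acquisition protocol.

## Group statistics

Per metric and region: two-sided iterative Grubbs outlier removal
(α = 0.05) within each diet × sex group — repeated single-point removal
while G = max|x − mean|/sd exceeds the t-based critical value, skipped for
n < 3 or zero variance; a Shapiro–Wilk gate that declares the parametric
branch appropriate only if every group has p ≥ 0.05 (a constant group
fails safe to nonparametric); and, for gated data, a two-way Diet × Sex
ANOVA. Sums of squares are Type II via nested least-squares model
comparisons with sum-coded factors — identical to Type III on balanced
designs and the conventional robust default under the mild imbalance that
litter-based sampling produces. When the interaction is significant all
six pairwise group comparisons are emitted as pooled-MSE t-tests on the
residual degrees of freedom with Bonferroni adjustment
(min(1, 6·p)). Non-normal datasets are flagged and left unfitted; a
mixed-effects fallback is out of scope by design, but the logged per-group
Shapiro p-values tell the user exactly when the parametric branch was
inappropriate. The implementation is validated against an independent
from-scratch sums-of-squares oracle and statsmodels' `anova_lm` (Type II),
and calibrated by simulation: null rejection rate 0.05 ± 0.01 over 2000
balanced tables, Grubbs false-removal rate ≈ α on clean normal samples.
Note the joint pass rate of four independent Shapiro tests on normal data
is ≈ 0.95⁴ ≈ 0.81, so the gate legitimately reports "nonparametric" for
roughly one in five fully normal datasets at n = 5–6 per group.

## Pipeline

The batch runner reads a YAML manifest (image paths, channel assignment,
region from a configurable vocabulary, animal metadata), executes
segment → thin → morphometry → detect → interact → planar per image, and
applies the statistics stage per metric × region. Per-image seeds derive
from the master seed and the image id (CRC32, kept below 2³¹), so batch
order cannot change results; a fixed master seed yields byte-identical
output tables. Stage failures are logged per image without aborting the
batch. Every output value is traceable through the JSON-lines run log to
its stage, parameter set and input file.

## Problem sizes used in validation

The validation suite (and the reproduction script) uses: a 64×256×256
voxel tree phantom with 3 junctions for length/branch recovery; 54-plane
scenes of 80–240 px laterally for tortuosity, coverage, detection and
contact checks; 200 random cells for the NND brute-force comparison; 2000
simulated tables for the statistical calibrations; and a 4-image batch
for determinism. These sizes were chosen to match the acquisition scale
the package targets while keeping the full suite runnable in a few
minutes on one CPU.

## Known limitations

- Vessel radius/diameter, artery–vein classification and flow are not
  measured.
- The skeleton-chain smoothing slightly shortens genuinely kinked vessels
  (curvature radius ≲ 2–3 µm).
- The tortuosity index depends on voxel density along the axis; comparing
  values across different voxel sizes requires identical resampling.
- The LoG threshold (15) is meaningful only relative to the input
  intensity scale; images with other bit depths need a rescaled threshold.
- The statistics stage treats animals as independent (no litter random
  effect).
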