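# Methods

This note documents the models, algorithms and numerical conventions
behind `octamorph`, the design choices made where several reasonable
options existed, and what the synthetic validation does and does not
demonstrate about clinical data.

## Geometry and units

All images are 2-D (row, col) grids with pixel centres at integer
coordinates. Physical scale is the pixel pitch in µm/px; the reference
protocol is a 3 × 3 mm macular field sampled at 512 × 512
(pitch ≈ 5.859 µm/px). Smaller rasters of the same physical field are used
throughout the tests (`GrowthParams.scaled(n)`) to keep runtimes modest:
topology, length and calibre recovery behave identically at 256 px, and
FAZ work is done at 384 px where the avascular zone spans enough pixels to
dominate every other gap. All metric code is resolution-independent
through the pitch.

## Vessel binarization — local adaptive region growing

Seeds are pixels at or above the 95th global intensity percentile. The
foreground then grows in synchronous rounds: every background pixel
8-adjacent to the current foreground is accepted when its intensity
reaches `μ_bg + w·(μ_fg − μ_bg)` with `w = 0.5`, where `μ_fg`/`μ_bg` are
the foreground/background means inside a 31 × 31 window around the pixel
(computed with box filters, so a round costs four uniform filters).
Rounds repeat to a fixpoint (cap 500). Ties are accepted (`≥`) and the
round-synchronous update makes the result order-independent, hence
reproducible. The criterion adapts per window: faint vessels keep growing
where the local background is dark, and a bright background does not leak
in where both levels are high. The mask is a superset of the seeds by
construction.

A sharp illumination *step* whose bright-side background equals the
dark-side vessel level can stall the frontier (no local evidence
distinguishes them); smooth illumination gradients of the same magnitude,
the realistic case, are handled (verified against truth masks, Dice 1.0
on noise-free rasters, ≥ 0.9 at speckle σ = 0.05).

Despeckling (removal of components below an area threshold) is **off by
default**: isolated short segments are exactly what the fragmentation
metrics count, so silently deleting them would bias FVSC downward. It is
exposed as a flag for noisy clinical inputs.

## FAZ extraction

1. *Topography*: Euclidean distance transform of the complement of the
   vessel mask — each pixel's distance to the nearest vessel. The FAZ
   centre is the global maximum.
2. *Watershed candidate*: the inverted map is flooded after shallow-minima
   suppression by greyscale reconstruction (h-minima) with
   `h = 0.3 × max(dist)`; the basin containing the global distance maximum
   is the candidate. The basin count is non-increasing in the suppression
   depth, which is the over-segmentation control.
3. *Active-contour refinement*: a region-based morphological Chan–Vese
   contour (50 iterations, smoothing 2) initialised at the candidate.
   The contour runs on a Gaussian-smoothed (σ = 2) vessel-indicator
   image rather than on the distance map: two-phase variance minimisation
   on the distance map places the boundary near half the peak distance and
   systematically erodes the FAZ, whereas on the smoothed vessel image the
   boundary settles at the capillary ring. If the evolved phase does not
   contain the distance-map peak the phase is flipped; a collapsed contour
   falls back to the candidate with a warning flag.
4. Vessel pixels are removed, the rim lost to feature smoothing is
   recovered by (smoothing + 1) dilation steps constrained to avascular
   pixels, the connected component holding the distance peak is kept, and
   holes are filled. The result is simply connected, contains < 1% vessel
   pixels, and is deterministic.

The FAZ is delineated per layer; the fovea centre downstream is its
centroid.

## Regions

Two concentric circles of diameter 1.5 mm and 2.5 mm are centred on the
FAZ centroid. Fovea = inner disc minus FAZ; parafovea = annulus between
the circles minus any escaped FAZ pixels (an abnormal FAZ must not dilute
vascular metrics). Membership is pixel-centre distance ≤ radius. An empty
FAZ degenerates to fovea = full inner disc.

## Skeleton and radius

Thinning uses homotopy-preserving iterative boundary-pixel removal
(scikit-image `thin`), which keeps 8-connectivity and component count. A
repair pass guarantees the one-pixel-width invariant in the rare case a
fully set 2 × 2 block survives (even-width X-crossings): a block corner is
removed when its punctured neighbourhood stays connected, otherwise the
corner is removed and a lateral bridge pixel inside the vessel mask
re-attaches its diagonal arm.

Thinning wide-vessel junctions also emits short twig artifacts — endpoint
chains of one or two pixels running straight into a branch pixel — which
would inflate both node and endpoint counts. Junction twigs of up to 2 px
are therefore pruned (configurable, 0 disables); at the supported calibres
no real vessel is that short, and removal cannot change the component
count. Thinning, block repair and spur pruning iterate to a joint
fixpoint, which is what makes `skeletonize` idempotent.

The per-pixel radius is the Euclidean distance transform of the vessel
mask restricted to skeleton pixels ("pointwise product"); diameters
(2 × radius) are formed at metric time. The image border counts as
background for the EDT, so vessels touching the border carry small radii
there; padding is available if undesired.

## Lengths

VL is geodesic over the skeleton adjacency: each 8-adjacent pixel pair
contributes one step of 1 px (lateral) or √2 px (diagonal), and a diagonal
step is skipped when the two pixels share a lateral skeleton neighbour
(the corner is already covered by two lateral steps). Steps straddling a
region boundary belong to the region containing the rounded step midpoint,
which makes per-region lengths add up exactly.

The generator emits polylines as 8-connected lattice chains, so truth
polyline length and the geodesic convention agree by construction for
straight runs; residual VL error then measures thinning and junction
geometry, not digitisation mismatch (observed < 1% on noise-free rasters).

## Topology

Skeleton pixels are classified by 8-neighbour count: 1 endpoint,
2 ordinary, ≥ 3 branch, 0 isolated. Thinning leaves several adjacent
branch pixels at one anatomical junction, so **one node per 8-connected
branch-pixel cluster** (centroid as location) is the default BNN
convention; raw pixel counting is available (`count_mode="pixel"`) for
sensitivity analysis. Isolated single pixels count as one endpoint each —
they are degenerate terminal fragments. Classification runs on the
full-image skeleton first and points are then assigned to regions, so
region boundaries cannot manufacture endpoints. BND = BNN/VL and
EPD = EPN/VL per region, reported per millimetre of VL; densities are
missing (NaN) when a region has no skeleton.

## Fragmentation

An *isolated segment* is an 8-connected skeleton component containing no
branch pixel — a free-floating unbranched snippet (a bare ring also
qualifies). Without the no-branch-pixel refinement an entire plexus would
be one "segment". A strict mode returning every component exists behind a
flag. A segment is *fragmented* when its geodesic length is below
k × VAD, both in µm, making k dimensionless across resolutions; k defaults
to 30, and the VAD reference is the layer-level VAD of the analysed image
(a stable calibre reference; per-region VAD is possible but noisier).
FVSC counts fragmented segments per region (centroid membership); FVLR is
their summed length over the region's VL. Both are non-decreasing in k.

The multiplier sweep recomputes the fragmentation feature for
k = 2 … 100 and scores group separation by the pairwise-averaged
leave-one-out accuracy of a univariate threshold classifier — a simple,
assumption-free stand-in for an unspecified classification criterion.

## Statistics

Groups are summarised as mean ± SD and compared with the unpaired
two-tailed Student *t*-test with pooled variance (Welch behind a flag);
p < 0.05 / 0.01 / 0.001 map to * / ** / ***. No multiple-testing
correction is applied; eyes are treated as independent samples. Cells
with fewer than two observations per group are marked not-computable.
Degenerate zero-variance cells return p = 1 when means agree and p = 0
otherwise.

## Synthetic angiogram generator

**Growth.** A perifoveal capillary ring (a closed digital circle split
into arc segments) encloses the avascular disc (radius 0.3 mm); trees
sprout outward from ring joints and inward from border roots, advancing in
compass-rounded unit steps with small heading jitter, bifurcating with
probability 0.85 per segment (roots always bifurcate) down to generation
8, with calibres decaying geometrically from 5 px to a 2 px floor
(DVP preset: narrower roots). A spatial hash enforces clearance between
unrelated vessels — junction-incident segments are exempt near their
shared joint, but hard overlap is always rejected, so the stored polyline
adjacency is exact: nodes are coordinates where ≥ 3 segment ends meet,
endpoints where exactly one does. Gap-filling passes seed small filler
trees wherever an avascular pool rivals the FAZ (threshold 0.6 × FAZ
radius) — emulating the homogeneous capillary spacing of a real macula and
guaranteeing the FAZ stays the deepest basin, with margin left for
degradation; components that never bifurcate are dropped and their pools
refilled.

**Degradation.** Terminal pruning removes a fraction of the removable
segments leaves-first (a prefix of a fixed removal order, so node count is
monotone in the fraction, and fraction 1 strips a tree to its root path).
Flow-dropout gaps are cut into internal segments (both halves stay
attached), each adding two terminals and removing perfused length.
Isolated fragments (digital straight chains, 12–36 px at 512, scaled with
raster size) are planted with clearance from everything. With
`balance_endpoints`, extra gaps are cut until the terminal count returns
to within one of its pre-degradation value, separately inside and outside
the fovea-scale zone — realising the clinical observation that terminal
counts stay level while vessel length falls, so EPD rises while EPN does
not.

**Rasterization.** Strokes are disks of radius (w−1)/2 stamped along
resampled polylines (round caps); at zero noise the intensity support
equals the truth vessel mask exactly. Noise adds a smooth background
texture plus per-pixel Gaussian speckle, clipped to [0, 1]; truth masks
never depend on noise. The truth FAZ is the avascular cavity enclosed by
the capillary ring (morphological closing of the vessel raster, then the
cavity holding the FAZ centre) — the region an expert annotator would
outline — rather than the bare geometric disc, which the vessels only
approach to within half a stroke width.

**Cohort presets.** Three groups emulate healthy controls, diabetics
without retinopathy, and mild retinopathy: pruning 0 / 0.12 / 0.25,
planted fragments 0 / 4 / 9, endpoint balancing on for the degraded
groups, speckle σ = 0.03, 20 eyes per group, DVP layer at 384 px.

**What this does and does not show.** Passing the synthetic suite shows
the measurement chain recovers known geometry and topology and that the
statistical pipeline reproduces the qualitative group pattern under the
stated degradation model. It does not calibrate absolute clinical values:
real OCTA speckle is multiplicative and flow-dependent, real plexuses
anastomose (the generator grows trees, so cycles arise only via the ring),
and projection artefacts between layers are not modelled.

## Numerical conventions and degenerate inputs

- Ties at the segmentation threshold: accepted.
- Even 30 × 30 density window: spans [−15, +14] around the centre pixel;
  at borders the window shrinks and normalises by its in-image area.
- Empty region → VD error; region without skeleton → VAD/densities NaN,
  never 0.
- Constant image → "no contrast" error; all-seed image → warning,
  all-true mask.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical inputs give
  bit-identical outputs.

## Known limitations

- BNN is inflated by a few percent on dense plexuses where thinning splits
  one anatomical junction into nearby clusters that are not 8-connected;
  the cluster convention bounds this well inside the ±10% validation band.
- The watershed "most prominent basin" rule assumes the FAZ is the largest
  avascular gap; severe dropout could break that assumption on real data
  (it is preserved by design in the synthetic conditions).
- Sub-pixel centerlines, spline vectorisation, tortuosity and fractal
  dimension are out of scope.
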