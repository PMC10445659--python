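# Methods

## Outline extraction

Cell outlines are measured on 2D standard-deviation Z-projections (sample SD,
ddof = 1) of the membrane channel, reproducing the semi-automated macro
workflow used for membrane-labelled astrocytes. The projection is
auto-thresholded (Otsu by default; isodata, Li, mean and triangle are
selectable — the reference workflow states only "automatically thresholded",
so the method is configuration, not contract). Connected particles are
8-connected components with hole-filled area at or above the minimum particle
bound (default 3 μm²); interior holes are 4-connected background components
fully enclosed by a particle — the standard connectivity duality that avoids
topological paradoxes. The final complex outline is the symmetric difference
(XOR) of a selected set of particle and hole regions. Selection is a
human-in-the-loop step in the original workflow; for synthetic pipelines the
automated selector takes the particle containing a seed point (a point
interior to the cell, standing in for the user's click) plus all holes it
encloses.

The GFAP channel is binarised with the Phansalkar local threshold,

    t(x) = m · (1 + p·e^(−q·m) + k·(s/r − 1)),

with m, s the mean and SD over a circular window (radius 15 px by default)
after min–max normalisation to [0, 1], and constants k = 0.25, r = 0.5,
p = 2, q = 10 — the published defaults; the reference workflow names only the
radius. Borders are handled by symmetric reflection, and the brute-force test
oracle uses the same convention so agreement can be asserted exactly.

## Shape metrics

All metrics are measured on the outline's pixel mask with an isotropic
μm/px calibration.

* **Area** — pixel count (holes excluded).
* **Perimeter** — length of the sub-pixel marching-squares boundary contour
  (level 0.5) after a 3-point circular moving average of its vertices, summed
  over the outer boundary and hole boundaries. The smoothing converts pixel
  staircases into straight diagonals; the estimator stays within ~3% on
  digitised disks, ellipses and 2–3 px wide bars alike. Raw chain-code
  tracing overestimates a digitised circle by ~5% (which would push disk
  circularity to ~0.91), and Crofton estimators underestimate 2–3 px wide
  processes by ~6%; neither meets the package's recovery bounds on cells that
  mix a smooth body with fine processes. For supersampled-oracle comparisons
  (4× masks) a 5-point window is used, since the narrowest structures are
  then ≥ 8 px wide; there the estimator agrees with exact polygon perimeters
  to < 0.5%.
* **Circularity** `4πA/P²` and **roundness** `4A/(π·major²)`, both capped at
  1.0 (discretisation can push crude estimates above the ideal bound; the cap
  documents the contract).
* **Fit ellipse** — moment-matched ellipse from second central moments with
  the 1/12 pixel-extent term, rescaled so the ellipse area equals the pixel
  area; full axis lengths are reported. Truly collinear regions (zero point
  second moment) report minor = 0 with a warning.
* **Convex hull** — taken over the corners of boundary pixels, so a W×H
  rectangle has Feret diameter √(W²+H²). CVH area is the pixel count of the
  rasterised hull, which makes solidity = FO area / CVH area hold exactly;
  CVH perimeter and centroid come from the hull polygon. The maximum Feret
  diameter is found by rotating calipers over antipodal hull-vertex pairs
  (verified exactly equal to the O(n²) pairwise maximum); the minimum Feret
  is the smallest projection width over hull-edge orientations. FO and CVH
  Feret are identical by construction.
* **Center of mass vs centroid** — the center of mass is the
  intensity-weighted centroid of the projected membrane channel inside the
  outline; the CVH centroid is geometric. Their distance is one of the 20
  features.
* **Marker coverage** — percent of outline pixels positive in the
  Phansalkar-binarised marker channel.

## Vessels and contacts

Vessel masks are skeletonised (medial axis); per-node radii are
distance-transform values. The pixel graph connects 8-neighbours but drops a
diagonal edge whenever a 2-step orthogonal path exists (staircase corners
would otherwise create spurious 3-cycles), and terminal twigs shorter than
the local vessel radius are pruned — thinning artifacts at rounded ends and
junctions that would otherwise each register as a branching event.

Unique vessels follow the rule that a branching event yields one continuing
and one new vessel. At each degree-3 node the two incident segments with the
most collinear tangents merge as the continuing vessel (diameter similarity
is a configurable alternative; the continuing-vessel concept itself has no
stated criterion); higher-degree nodes pair greedily by collinearity, and
every unpaired segment starts a new id. Cyclic components fall back to one
vessel per inter-branch segment with a logged warning. For trees this makes
the unique-vessel count exactly 1 + the number of branch events.

A cell contacts a vessel where its mask dilated by the contact tolerance
(default 1 px — membrane and vessel labels abut rather than overlap)
intersects the vessel mask; each contact pixel is assigned to the unique
vessel of the nearest centerline node, and only unique vessels are counted.
Contact diameters are twice the node radius over the contacted nodes.
Nearest-vessel distance is the background distance transform sampled at the
hull centroid.

Connection classification computes (i) the on-vessel mass fraction f = the
fraction of cell pixels within a 2 μm shell of the vessel surface, and
(ii) a wrap statistic ψ: at every centerline node of a contacted vessel that
lies inside the contact footprint (cell pixels reach the vessel surface
there), the occupied 10° angular bins of cell pixels in the shell between the
vessel radius and twice the radius; ψ is the median over sampled nodes.
Pixels over the vessel footprint itself are projection overlap, not wrap, and
are excluded. Enveloping: ψ ≥ 300° and f ≥ 0.5; mural: ψ ≥ 120° and f ≥ 0.5;
otherwise non-enveloping. The thresholds are package defaults exposed in
configuration and echoed in output — the original classification was visual.
The classification is total: a cell touching no vessel is non-enveloping
(with a warning).

## Retinal coordinates

The flattened retina is modelled as an azimuthal-equidistant projection of a
hemisphere: latitude = (r/R − 1)·π/2 for planar distance r from the ONH and
rim distance R, so the ONH sits at −90°, the rim at 0°, and latitude is
monotone in eccentricity. Longitude is the planar polar angle rotated so the
dorsal reference direction is +90° (temporal = 0° for left eyes, nasal = 0°
for right eyes). Right eyes are harmonised into left-eye space by mirroring
longitude about the dorsal–ventral axis (λ → π − λ), an involution that
fixes dorsal and preserves latitude. Full elastic flat-mount reconstruction
(relief-cut stitching) is out of scope; the downstream analyses consume only
latitude/longitude. The reconstruction rim angle φ0 (22°) is carried in the
configuration for provenance but does not enter the simplified mapping.
Eccentricity trends are ordinary least-squares quadratics in latitude;
curvature magnitudes below 10⁻⁶ of the value scale are reported "flat" so
noise cannot masquerade as curvature.

## Association statistics and embedding

p(structure | motif) is the exact percentage of motif instances flagged as
contacting each structure (axon, RGC soma, neighbouring astrocyte); flags are
not exclusive, so rows may sum past 100%. The quoted error is the binomial
standard error of the mean flagged proportion at that motif's instance count
(a Wilson-interval half-width is the configurable alternative; outputs are
labelled with the method used). The denominator is per instance by default,
per cell as an option. The 20-feature matrix uses a fixed column order
(FO area … number of unique vessels contacted) and rejects missing values by
cell and column name. Features are z-scored before UMAP (mixed units — μm²,
radians, percent — make unscaled distances meaningless); UMAP runs with
n_neighbors = 15 and the library-default min_dist, recorded in metadata, and
the embedding is density-clustered with HDBSCAN (min_samples = 3,
min_cluster_size = 10; noise is label −1). The correlation dendrogram is
average-linkage clustering of features at distance 1 − |Pearson r|, exported
as Newick.

## Synthetic retina

The generator emulates the study conditions rather than photorealistic
optics: 0.3 μm/px XY sampling and 0.3 μm Z-steps; cells of 300–900 μm²
projected area placed on a jittered grid; a planar vessel tree whose
branching events each spawn one new unique vessel (radius decay 0.8–0.9,
daughters truncated before they would collide with another tube so the
centerline stays a tree); and a planted GFAP-like subset covering 21.1% of
each cell's area (the regime where GFAP misses most of the membrane), built
as the cell pixels nearest the mask skeleton so it looks filamentous and the
fraction is exact to rounding. Astrocytes are deformed core polygons plus
buffered process polylines with planted motifs: bristles ≤ ~5 μm (the
smallest 0.7–2.5 μm) with ~0.9 μm width, beads on thin stems, polygonal
sails, pads (rounded endings directed away from vessels), end-feet
(terminating on a vessel surface without wrapping), tubes and interior
holes. Because membrane above and below a wrapped vessel overlaps in an
en-face projection, enveloping cells are rendered as solid bands covering
the vessel footprint, and mural cells as one-sided bands hugging the vessel
— the projected appearance of full and partial wraps. Motif sizes the study
does not constrain (sails, pads) are exposed as configuration ranges.
Tangential unions of parts are closed at 0.3 μm (~1 px) because narrower
crevices are unmeasurable at the imaging scale.

Connection classes are planted at 8% enveloping, 7% mural, 85%
non-enveloping, and every non-enveloping cell receives an end-foot so the
population reproduces the regime in which 100% of astrocytes touch at least
one vessel. Each cell also gets a retina-level position (uniform over the
hemisphere disc, rim at 1600 μm) from which its true latitude/longitude
follow. Per-motif structure-contact flags are Bernoulli draws at the
association table's conditional probabilities (sail 65/41/6, bead 76/22/3,
pad 43/43/20, bristle 41/34/20 percent for axon/soma/astrocyte); flagged
motifs get a corresponding structure planted through them (axon streaks and
RGC-soma blobs in the axon channel, neighbour processes in the GFAP
channel), so every planted flag references real voxels. Statistical cohorts
(contact counts 1 + Poisson(1.57) for a planted mean of 2.57 unique
contacts; eccentricity cohorts with a mid-retina maximum; annotation cohorts
at study-scale instance counts of 48/89/14/10) supply the population-level
regimes without rendering.

Ground truth is computed from the exact shapely polygons (area, perimeter
including hole boundaries, hull-pair Feret, solidity), deliberately
independent of the raster measurement code; a 4× supersampled-mask
recomputation agrees with the stored truth to < 0.5% and is asserted as a
test invariant. Stacks are rendered with a deterministic per-plane Z profile
(so SD projections are informative), optional additive Gaussian noise
(default σ = 0.05 of signal; no PSF blur by default — segmentation tests
need controllable difficulty), and a fixed seed makes stack and truth
bit-identical across runs.

What passing tests on these scenes shows — and what it does not: the
pipeline recovers known geometry, topology and planted statistics under
controlled noise; real confocal data add optical blur, depth-dependent
attenuation, labelling heterogeneity and segmentation ambiguity that the
generator deliberately omits, so accuracy on real tissue must be validated
separately.

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale problems chosen as
representative rather than exhaustive: 100-cell shape-recovery batteries,
50-blob and 64×64 oracle-equivalence checks, 100 random vessel trees,
rendered scenes of 12–20 cells on 1024×1280 to 1280×1600 px fields, cohorts
of ~1,000 cells for contact statistics, and 100 Monte-Carlo replicates at
n = 500 for trend recovery. Thresholds and tie-breaks that matter: Otsu on
non-constant images only (constant images are rejected as degenerate);
particle bounds applied to hole-filled areas; GFAP subset pixels ordered by
(distance-to-skeleton, row, column) for deterministic tie-breaking;
hull rasterisation by `skimage.draw`-style scan conventions through
`convex_hull_image`; UMAP seeded through `random_state` (single-threaded,
reproducible). Degenerate inputs (empty masks, empty selections,
single-plane stacks, rank-deficient trend designs, cells without vessel
contact) raise or warn explicitly rather than returning silent defaults.

## Known limitations

* Measurements are 2D (projections); no 3D surface or volume metrics, no
  Sholl or skeleton branching statistics.
* The unique-vessel "continuing" rule is operationalised by tangent
  collinearity; real junction anatomy may disagree near complex junctions.
* Connection-class thresholds (300°/120°/0.5) are package defaults, not
  measured constants; borderline mural/enveloping cells are
  threshold-sensitive.
* The azimuthal-equidistant retina model ignores relief-cut elastic
  distortion; latitudes are exact only under that model.
* The generator's vessel trees are planar and acyclic; real retinal plexuses
  contain loops, which the partition handles only via the per-segment
  fallback.
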