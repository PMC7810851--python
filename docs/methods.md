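# Methods

This note documents the models, parameter choices and numerical
conventions behind `veinnet`, and what the synthetic-scene validation
does and does not establish about real dish photographs.

## Segmentation

Photographs are calibrated by a dish circle (centre, radius, px/mm) in
the run configuration; pixels outside the circle (minus an optional rim
margin) are ignored by every stage. A Hough-style automatic dish finder
was deliberately not included: dish geometry is constant per experiment
and a two-number config entry is more reliable than circle detection on
a reflective rim.

**Contrast enhancement.** Frames are unsharp-masked per channel with a
3×3 four-neighbour Laplacian at gain `k = 1`. The Laplacian is taken of
a Gaussian-smoothed copy of the channel (`presmooth_sigma = 1` px)
rather than the raw pixels: a raw 3×3 Laplacian multiplies per-pixel
sensor noise roughly five-fold, which floods the adaptive threshold
downstream with speckle; the Laplacian-of-Gaussian keeps the edge
enhancement while leaving the noise floor almost unchanged. Setting
`presmooth_sigma = 0` recovers the plain kernel.

**Intensity.** sRGB is converted to CIELAB (D65 illuminant, 2°
observer) and reduced to `L − b`. The yellow cell has high `b` and so
maps to low values; the pale agar maps high; min–max normalisation over
the dish puts the field in [0, 1] with the cell as dark foreground.
Note that `b` here is the standard CIELAB blue↔yellow opponent axis.
A nearly constant field is returned as all zeros rather than
normalised: if the robust (1st–99th percentile) raw spread is below
15 L units and the full spread below 30, there is no real contrast to
stretch — this is what keeps a cell-free dish from dissolving into
amplified noise. The thresholds sit between the measured noise-only
spread (≈ 13 L units robust at the default noise level) and the
smallest cell contrast the renderer produces (≈ 50).

**Binarisation.** Bradley's adaptive method for dark foregrounds: a
pixel is foreground when its value is below `(1 − s)` times the local
mean over a square window, with sensitivity `s = 0.10` and window
defaulting to one eighth of the dish diameter. The local mean is
computed over in-dish pixels only, so the rim does not bias it. Two
practical guards: the pixel must also sit an absolute `0.10` below the
local mean (a fraction of a relative margin is within the noise in
flat regions, and this floor is what makes a contrast-inverted field
come back empty), and 8-connected components smaller than 0.05 mm² are
removed as sensor speckle.

**Ridge detection.** Thin fading veins that the threshold misses are
recovered by a watershed on the negated Gaussian-blurred field
(σ = 2 px): veins are intensity valleys, so on the negated field their
centrelines are the crest lines separating catchment basins. Basins
are seeded from h-minima with depth `h = 0.02`, which merges basins
created by residual noise (post-blur noise amplitude is about 0.005 on
the normalised scale) while preserving genuine vein-separated regions.
The 1-px watershed lines, restricted to the dish, are united with the
Bradley mask; small components are removed once more after the union.

## Morphology

Covered area CA is the foreground pixel count over px/mm²; print area
PA adds the enclosed empty regions, found by filling 4-connected
background holes per component. The empty-region statistics (count,
total, mean size, ratio to CA) follow directly. The skeleton is the
Lee 3D-thinning medial axis; the exact Euclidean distance transform
sampled on it is half the local vein width. Total network length is a
step-weighted trace: orthogonally adjacent skeleton pixels contribute
1 px, diagonal pairs √2 px, and a diagonal adjacency whose two pixels
share a 4-neighbour on the skeleton is not counted (the path already
runs through the shared pixel; counting it would double diagonal
staircases). Mean vein width is defined as CA divided by total length,
so `mean_width × total_length = CA` holds exactly by construction.
Thinning implementations resolve end-pixel ties anisotropically, so a
90° image rotation can change the traced length by a couple of pixel
steps; tests allow for that.

Pseudopods are the regions surviving a morphological opening with a
disc of radius 1 mm (rounded to pixels): veins thinner than the disc
vanish, the thick fans remain.

## Graph construction

Skeleton pixels with ≥ 3 neighbours (8-connectivity) form junction
blobs that are clustered into single nodes at their centroids; pixels
with one neighbour are end nodes; traced pixel paths between node
pixels become edges. Edge length is the step-weighted path length,
width is twice the mean half-width along the path, the chord is the
distance between node centroids, and drag is length/width⁴. Isolated
cycles (rings with no branch or end pixel) receive one anchor node at
their topmost-leftmost pixel so the component stays representable.
Nodes closer than 2 px after tracing are merged (junction-blob relics);
terminal edges shorter than 2 px and thinner than 1 px are pruned as
thinning artifacts. After node merging the chords are recomputed from
the final coordinates and each edge's length is floored at its chord,
which guarantees `l ≥ e` pairwise and hence tortuosity ≥ 1 and
LE ≤ 1 — without the floor, junction-centroid motion of a pixel or two
can make a short traced path marginally shorter than its chord.

Simplification removes self-loops and collapses parallel edges keeping
the minimum-drag one (the best conductor dominates flow-like metrics);
the operation is idempotent. Node types are assigned by position:
`initial_cell` (inside the frame-0 footprint dilated by 0.5 mm) takes
precedence over `pseudopod`, the rest are `vein`.

## Network indexes

All path-based indexes are computed on the largest connected component
(the component count is surfaced as a warning). The MST is taken over
the graph's own edges by length or drag; the Delaunay triangulation of
the node coordinates, weighted by Euclidean length, serves as the
maximally connected planar bound and is weight-independent. Collinear
node sets, where the triangulation is degenerate, fall back to the
path graph along the line. NNL clips numerical overshoot into [0, 1]
and raises when the two bounds coincide.

Edge betweenness splits equal-cost shortest-path ties fractionally
(standard weighted betweenness), removing any dependence on edge
enumeration order; values are percentages of all node pairs and μ is
their mean. Fault tolerance removes edges in uniformly random order
and reports the maximal removable fraction with the largest component
still holding at least p % of the nodes (inclusive threshold); the
estimate is the mean of 30 realisations, evaluated efficiently by
re-adding edges in reverse with a union-find. One random stream drives
the graph and both its bounds (common random numbers), which reduces
the variance of the normalised value and maps a tree exactly to 0 and
a Delaunay edge set exactly to 1. The normalising MST is the
length-weighted one, consistent with NNL. The decay curves rank edges
once by drag betweenness and remove the top (worst case) or bottom
(best case) ⌈k % · E⌉; the worst ≤ best dominance is an empirical
property of loopy vein networks — static-rank removal can violate it
at high removal fractions on small arbitrary graphs, and the tests
assert it on generated vein ensembles only.

## Fusion analysis

Fusion time is the earliest frame in which the two cells (seeded from
the two largest components of the first frame, each represented by its
deepest interior pixel) belong to one connected component; an optional
guess only accelerates the search. The fusion region starts from the
masks right before fusion (BF) and the nearest frame at least 5 min
after (AF): new-growth components AF∖BF are added back to BF in
decreasing-area order (ties broken by lexicographic centroid) until
the cells connect; the added components are the connecting set; the
region is the AF slime within 5 mm of that set, dilated outward by
2 mm. Connecting veins are counted by max flow with unit capacities,
except capacity 100 for edges with an endpoint within 25 mm of either
source node (the node nearest each initial cell's centroid) — the
boost forces the bottleneck into the gap between the cells, and
integer capacities make the count exact. Bandwidth uses the same boost
with width capacities; bandwidth divided by the count is the mean
connecting-vein width. Inter-cell shortest paths are Dijkstra by
length and by drag. Connectivity quantities are evaluated on the
largest component so that small segmentation fragments can never
capture a source node.

Time series over the three hours after fusion report the morphological
indexes of mask ∩ FR per 15-min step; CA, PA, network length and max
width are additionally normalised by their value at fusion, so those
columns are exactly 1 in the first row.

## Synthetic scenes

The generator plants a planar graph between the MST and the Delaunay
triangulation of blue-noise points in a disc: the MST plus either a
random 18 % of the remaining Delaunay edges (`hole_density`, tuned so
the mean node degree sits in the branch-dominated band around 2.7
typical of biological transport networks) or, when an `nnl_range` is
given, shortest extra edges until the straight-line NNL enters the
range. Widths are log-logistic (shape 3, scale 0.55 mm, clipped to
[0.35, 2.2] mm) with a trunk boost decaying with hop distance from the
root, giving the right-skewed many-thin/few-thick hierarchy; veins are
rasterised as capsules, pseudopod fans as ≥ 2 mm discs at frontier
nodes, the initial cell as a 13-mm-diameter disc. Rendering uses a
pale background (235, 235, 230), yellowish slime (220, 210, 140) with
width-dependent darkening, and Gaussian sensor noise of 4/255 — strong
enough that segmentation is non-trivial, weak enough that it is
solvable. Everything is a pure function of (params, seed).

Growth sequences advance the frontier along the network: frame t
contains the edges whose endpoints lie within the t-th quantile of
network distance from the root, which guarantees connectivity and
strictly increasing covered area; the default growth scene (~110
nodes, 28 mm radius) exceeds four times the initial-cell area, the
span the normalized-area analysis samples. Fusion sequences grow two
cells rooted near opposite dish edges and bridge them at the merge
frame with the requested number of corridors; each corridor runs
through two mid-gap waypoints carrying short side stubs, so the traced
graph contains a genuine mid-gap edge whose endpoints are more than
25 mm from both sources — outside the max-flow boost zone, as in the
dish geometry the count was designed for. Corridor thinning, when
enabled, shrinks corridor widths linearly after the merge; its effect
shows in the connecting-vein mean width (the fusion region's *maximum*
width sits at junction blobs of cell veins and is insensitive to it).

**What passing tests show, and what they do not.** The synthetic scenes
exercise the pipeline's geometry: contrast levels, vein hierarchies,
enclosed regions, growth and fusion timing are realistic in structure.
They do not emulate uneven illumination, dish reflections, condensation,
or the slow colour drift of ageing plasmodia; performance on real
photographs therefore depends on the segmentation parameters
(sensitivity, window, contrast floor) being re-tuned per imaging setup,
while everything downstream of the binary mask carries over unchanged.

## Validation summary

Graph algorithms (MST, shortest paths, betweenness, max flow) are
checked exactly against exhaustive enumeration on small random graphs;
index limits are checked against closed forms (tortuosity and LE of
straight-edge graphs, the unit-square NNL value 1/(1+√2), drag
efficiencies 1 and 0.0625 of 0.5-mm and 1.0-mm edges); fault tolerance
is checked against the exhaustive removal-order average on K4 within
Monte-Carlo error. End-to-end, rendered 512×512 scenes are recovered
with mean IoU ≈ 0.95, network length within a few percent and mean
width well within 15 % (recovery is measured on vein-only scenes,
whose planted length is analytic; disc features have medial axes of
their own). Problem sizes — 8 scenes, 8 fusion runs, 20-graph
ensembles in the acceptance script — were chosen so the whole
validation runs in well under a minute per section on one core.
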