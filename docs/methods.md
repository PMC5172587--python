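# Methods

This note documents the models and numerical choices behind `vessel3d`:
what each stage computes, which parameters matter and why they have the
defaults they do, what the synthetic phantoms emulate (and what they do
not), and where the known limitations are.

## Problem setting

The input is an ordered stack of registered RGB images of serial tissue
sections in which microvessel endothelium carries a brown peroxidase
reaction product (DAB) on a light background. Sampling is strongly
anisotropic: ≈0.28 μm/px in-plane versus ≈7 μm between sections. The goal
is a solid triangle-mesh model of the vasculature on which two
classifications run: local caliber (capillary vs sinus) and network
connectivity. Registration is assumed done upstream; `vessel3d` consumes
already-aligned stacks.

## Stain isolation

The brown stain is well separated from the near-achromatic background by
the HSV saturation channel, `S = (max−min)/max` over (R, G, B), with
`S = 0` where `max = 0`, scaled to 0–255. Typical stain pixels land near
S ≈ 210, background near S ≈ 10–30, so a fixed threshold of 70 cleanly
divides them. Saturation also halves data volume before interpolation
(one channel instead of three; a full-scale single-channel ROI of
3500 × 3500 × 140 voxels is 1.60 GB against 4.79 GB for RGB).

## Optical-flow z-interpolation

For every pair of consecutive sections a dense optical-flow field is
estimated in both directions with the iterative Lucas–Kanade estimator
(`skimage.registration.optical_flow_ilk`; window radius 10 px, 3 warp
iterations). An intermediate plane at fraction `t` of the gap advects each
endpoint part-way along its own flow and blends them `(1−t) : t`; the
symmetric blend avoids ghosting at gap midpoints. Warping uses bilinear
sampling, so output intensities never leave the input range.

**Plane-count convention.** Each of the `n−1` gaps contributes
`Δz / target_z` planes: the leading original plus the warped
intermediates; the trailing original of the stack is not emitted. A
21-section stack at 7 μm interpolated to 1 μm therefore yields exactly
(21−1)·7 = 140 planes. The natural inclusive count would be 141; the
convention with the final original dropped is the one this package uses
throughout.

## The six-filter chain

Order is fixed: Threshold 70 → Close 10 → Fill hole → Dilate 3 → Close 5
→ Blur 0.33.

* **Threshold** zeroes voxels strictly below 70 of 255 and passes the rest
  unchanged (it is a mask, not a binarisation: surviving voxels keep their
  intensity).
* **Closings** are grayscale morphological closings with *Euclidean ball*
  structuring elements whose radii are measured in voxels, even though
  voxels are anisotropic. On a 0.28 × 0.28 × 1 μm grid a radius of 10
  voxels therefore smooths ≈3.6× more aggressively along z than in-plane;
  this is deliberate (it mends the inter-section discontinuities that
  anisotropy causes) and it also reproduces the z-elongation bias visible
  in the resulting models. The implementations are exact (`scipy.ndimage`
  flat morphology with the true ball footprint) and are verified against
  brute-force shifted-array definitions in the test suite.
* **Fill hole** operates on the support (voxel > 0): zero-intensity
  regions not 6-connected to the volume border are enclosed cavities
  (vessel lumina) and are filled with the minimum intensity of their
  enclosing shell, so that lumina become solid and later caliber
  measurements see full vessel cross-sections. A per-slice 2-D variant is
  available (`fill_holes_per_slice`); 3-D is the default.
* **Blur** is a 3-D Gaussian, σ = 0.33 voxels, reflecting boundary,
  computed in float and rounded back to 8 bits; it smooths the staircase
  the isosurface extractor would otherwise inherit.

## Meshing

* **Isosurface.** Marching cubes at iso = 127.5 (the intensity midpoint;
  the choice is exposed in the config since no canonical value exists for
  this stage). Voxel spacing is applied so vertices are in μm;
  intensity-above-iso is "inside" and winding gives outward normals.
* **Heal / solidify.** Duplicate vertices are merged (10⁻⁶ μm),
  degenerate faces dropped, and *every* boundary loop — small tessellation
  defects as well as the large open rings where vessels meet the volume
  border — is fan-triangulated around its centroid. Components that still
  fail the closed-2-manifold contract are dropped with a warning. The
  result is a set of watertight components with positive enclosed volume:
  the "solid forms" on which interior-removal and the distance-based QC
  are well defined.
* **Taubin smoothing.** Ten iterations of the classical λ = 0.5,
  μ = −0.53 pair with uniform (umbrella) weights. The negative μ step
  re-inflates what the λ step shrank: on closed test meshes ten iterations
  change the enclosed volume by ≪1%, versus ≈1% shrinkage for the same
  number of pure-Laplacian steps (asserted by test). Connectivity is
  untouched.

## Caliber model

* **Volumetric obscurance.** Per-vertex visibility ∈ [0, 1]: the fraction
  of a fixed Fibonacci-sphere direction set (default 24) whose rays escape
  the model's bounds. Only the outgoing hemisphere is cast; rays into the
  surface count as blocked. A vertex on an enclosed inner shell scores 0;
  an exposed point on a locally flat surface ≈0.5. Vertices below the
  removal threshold (default 0.05) are deleted with their faces — this
  strips the inner wall surfaces inside solidified vessels. Vertices
  flagged as cut surface are never removed, which implements the
  requirement that outer-surface geometry must not be disturbed.
* **Component filter.** Connected components (shared-triangle vertex
  adjacency) whose exact largest diameter — maximum pairwise vertex
  distance, computed directly up to 5000 vertices and via the convex hull
  above (still exact) — falls below 70 μm are removed. 70 μm is 5% of the
  space diagonal of a full-scale 980 × 980 × 140 μm model; the package
  computes the cutoff from the model extent (`diagonal_fraction_threshold`)
  rather than hard-coding it.
* **Shape-diameter function.** From each vertex, 30 rays are cast into the
  mesh within a cone around the inward normal; each ray terminates at the
  first surface it strikes *from the inside* (front-face grazes along the
  launch vertex's own neighbourhood are traversed through — without this,
  staircase meshes produce sub-μm artifact values). The recorded value is
  the shortest ray (default) or, optionally, the median of the rays within
  one standard deviation ("robust"), which is less corner-sensitive.

  **Cone angle.** The default cone half-angle is 20°. With shortest-ray
  aggregation the reading on a tube of diameter D is `D·cos(θ_max)`; at
  20° that is 0.94 D (a 6% low bias), while at wider angles the shortest
  in-cone chord no longer measures the diameter at all (at 60° it is
  0.5 D). Since the caliber thresholds are absolute lengths
  (12 / 30 / 16.5 μm), the narrow cone is the setting under which "SDF ≈
  local diameter" actually holds; the angle remains configurable.
* **Coloring.** Red below 12 μm, green above 30 μm, two linear ramps
  meeting at 16.5 μm in the 50/50 red–green blend. 16.5 μm is not the
  arithmetic middle of the band; anchoring the ramp junction there is one
  consistent reading of a gradient "centred at 16.5 μm". Cut-surface
  vertices are painted light grey.
* A broad flat object read from its broad side legitimately reports its
  thickness, not its width — a 4 μm plate reads ≈4 μm. Flattened sinuses
  therefore can appear in the capillary color class; the recovery scoring
  exempts strongly flattened sinus edges for exactly this reason.

## Connectivity model

Components below 7 μm largest diameter (0.5% of the full-scale diagonal)
are discarded; components between 7 and 28 μm form the red "small
structure" class (mostly fused single cells, elongated along z by the
anisotropic closing); the remaining networks are ranked by total surface
area — "largest" is interpreted as largest area; vertex count gives the
same ranking on uniform meshes — with rank 1 light blue, ranks 2..n dark
blue when a model has several comparable networks, and the rest green.
Cut surfaces are light blue in this model.

## Quality control and repair

* **Distances.** Per-vertex nearest-surface distance is computed exactly
  (point-to-triangle, KD-pruned with radius-binned candidate search), the
  deterministic limit of the "shortest ray in all directions" description.
  Both directions matter: forward (reference → model) finds structures the
  processing lost; backward finds structures the processing invented. The
  symmetric Hausdorff distance is the maximum over both.
* **Repair.** Connected components of the healed marching-cubes reference
  whose *minimum* vertex distance to the processed model exceeds 10 μm are
  appended verbatim to the model and flagged with a `repaired` vertex
  attribute. Minimum (not maximum) is the conservative reading: only
  entirely missing structures are re-added, and afterwards every reference
  component provably lies within the threshold of the output. The
  appended geometry is raw reference mesh, not re-processed — the flag
  lets a reviewer tell it apart.
* **Visual QC.** Six-panel per-slice montages (scan, saturation of the
  flanking sections, interpolated plane, filtered plane, red overlay of
  every voxel filtering changed) and model-contour overlays on the scans
  (plane section of the mesh, optionally tilted for a depth impression).
  The blind-end census is a reviewing aid that flags geodesic extremities
  of tube-like components not explained by the stack boundary; it is a
  heuristic (double-BFS poles plus a ring-compactness test with a 15 μm
  probe radius) and feeds no quantitative result.

## Synthetic phantoms

The generator emulates the documented anatomy and artefact taxonomy:

* Two caliber classes in largely disjoint territories — each network grows
  as a biased random-walk tree (step 10 μm, branch probability 0.15, mild
  z-bias so vessels traverse the stack) inside its own slab of the domain,
  with a global surface-to-surface clearance (default 25 μm) between
  different networks enforced against every previously placed tube.
  Per-network base diameters are drawn from the central part of the class
  range (a given vascular bed has a characteristic caliber); per-edge
  jitter is ±10%.
* Optional end-to-side capillary→sinus anastomoses with an abrupt caliber
  change.
* Sinuses can be rendered as elliptical tubes flattened up to 3:1 along z.
* Rendering paints the *wall shell* (default 1.5 μm) in a DAB-like brown
  (RGB ≈ (120, 70, 20), saturation ≈ 212) on a light background
  (≈ (235, 230, 225), saturation ≈ 11), samples one section every 7 μm
  (inclusive: a 140 μm block gives 21 sections), and injects defects at
  configurable rates: unstained wall arcs (sectioning gaps), capillaries
  collapsed to a ≈2.5 μm solid profile, and isolated stained cells.
  Everything is deterministic per seed.

What the phantoms do **not** emulate: registration error (out of scope —
inputs are registered by assumption), cell-scale texture, bone trabeculae,
staining gradients, scanner background. Passing the phantom tests
demonstrates that the *reconstruction machinery* preserves topology and
caliber under the stated imaging geometry and artefact models; it does not
validate stain chemistry or registration quality on real scans.

## Desk-scale demonstration conditions

The canonical end-to-end run (`vessel3d.demo`) uses one capillary and two
sinus networks, no anastomoses and no defects, in a 200 × 200 × 140 μm
block rendered as 21 sections of 256 × 256 px (0.78 μm/px). The demo
interpolates to 3.5 μm z-planes — two planes per section gap — rather than
the full-scale 1 μm; thresholds in μm are spacing-aware, and the voxel-unit
filter radii then act on a 0.78 × 0.78 × 3.5 μm grid, preserving the
z-heavy smoothing character of the full-scale pipeline. Sinus flattening
is disabled in the demo so that the caliber ground truth is unambiguous.
The 21 → 140 plane-count behaviour is exercised separately on a small
fixture at the full-scale 7 → 1 μm setting. The whole demonstration,
including both ray-cast analyses and the bidirectional distance QC, runs
in roughly two to four minutes on one CPU.

Recovery scoring: a mesh vertex is classed capillary when its SDF is below
the 16.5 μm gradient centre; its truth class is that of the nearest
centerline sample; components map to truth networks by majority vote.
Topology matches when the component count equals the network count and the
mapping is a bijection.

## Numerical choices and degenerate inputs

* Ray casting uses a uniform spatial hash (cell ≈ the median triangle
  extent) with a vectorised 3-D DDA traversal and Möller–Trumbore
  intersection; all direction sets are fixed low-discrepancy spirals, so
  every ray-based quantity is deterministic.
* Exact point-triangle distance falls back to edge/vertex projections for
  degenerate (zero-area) triangles.
* Empty volumes yield empty meshes (not errors); empty meshes propagate as
  empty models; a single-slice stack fails interpolation with a
  stage-labelled error; an empty target mesh makes surface distance
  undefined and raises.
* `largest_diameter` of a single vertex is 0; convex-hull failure on
  degenerate point sets falls back to direct pairwise distances.
* All randomness (phantoms, renders) flows from explicit seeds; the
  pipeline itself has none, and the run manifest (config hash + per-stage
  checksums) is byte-stable across runs.

## Known limitations

* The healing step closes every boundary loop by centroid fans; strongly
  non-planar holes could self-intersect. Non-orientable remnants are
  dropped rather than repaired.
* Shortest-ray SDF carries a −6% bias at the default cone angle and is
  noise-sensitive on rough meshes; the robust variant trades bias for
  variance. Neither corrects for the dilation the filter chain applies to
  thin structures (≈ +2 voxel radii), which inflates capillary readings by
  a few μm at coarse voxel sizes.
* Optical-flow interpolation assumes locally smooth motion between
  sections; structures that appear in only one section (thin in-plane
  vessels) fade rather than track, which is the main capillary
  discontinuity mode — subsequently mitigated, but not eliminated, by the
  large closing.
* The blind-end census is a heuristic reviewing aid with tunable probe
  radius; it is not part of any quantitative contract.
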