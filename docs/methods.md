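# Methods

`swell3d` quantifies post-operative facial swelling from three surface scans of
the same face: pre-operative (T0), early post-operative (T1, typically three
days after mandibular third-molar extraction) and follow-up (T2, one week).
All geometry is in millimetres. The pipeline produces, for each pair
T0–T1, T1–T2 and T0–T2, a mean signed linear difference (mm) over a facial
region of interest and a closed-volume difference (mm³), both oriented
later-minus-earlier so that swelling onset is positive and resolution
negative.

## Canonical anatomical frame

Scans are placed in a right-handed frame derived from anatomical landmarks:
the Frankfurt horizontal plane through both porions and the left orbitale maps
to z = 0 (z superior), the midsagittal plane through the nasion maps to x = 0,
and the origin is the porion midpoint. The y axis points anteriorly. The x
axis points toward the subject's *left*; consequently the right hemiface is
x ≤ 0 and the ROI's hemiface rule is `side="right" → keep x ≤ midline`,
`side="left" → keep x ≥ midline`. Orientation requires the Frankfurt triplet
to span a triangle of more than 1 mm² — anything smaller is rejected as
degenerate rather than silently producing an unstable frame.

An optional pre-oriented reference surface (e.g. a soft-tissue model
segmented from an already-oriented CBCT) can refine the landmark orientation
of T0 by surface registration; segmentation itself is out of scope and the
reference is accepted as a mesh.

## Surface registration

T1 and T2 are registered onto oriented T0 with iterative closest point
matching against the target *surface* (exact nearest point on triangles via a
k-d-tree candidate search, not nearest vertex), starting from the identity —
scans are acquired in natural head position, so gross alignment holds.

Robustness to the swelling itself is essential: the T1 surface genuinely
differs from T0 over the operated cheek, and a plain least-squares fit drags
the registration toward the bump. Two rejection rules run per iteration:

* a fixed trim: the worst `trim_fraction` (default 0.10) of correspondences
  by distance is discarded;
* an adaptive cutoff: correspondences farther than `outlier_scale` (default
  3) times the median distance are discarded, keeping at least 25 % of
  points. Once the healthy surface is in contact the median residual
  collapses and the swelling patch is excluded *whatever its size*, which a
  fixed trim cannot guarantee.

The per-iteration motion is the linearized point-to-plane least-squares step
(normals taken from the matched target faces), re-orthonormalized exactly
through the rotation vector. Point-to-plane is used deliberately: on smooth,
convex, nearly spherical surfaces the classical point-to-point (Kabsch) update
converges so slowly in rotation that it is still millimetres away after
hundreds of iterations, while point-to-plane reaches numerical convergence in
under ten. Iteration stops when the trimmed RMS improves by less than
`rms_change_tolerance` (default 1e-4 mm) or at `max_iterations` (default
100). Up to `subsample_size` (default 5000) source vertices are used, drawn
with a seeded generator; given the seed the whole registration is
deterministic.

## Region of interest

The ROI is the operated hemiface bounded superiorly by the zygomatic arch,
inferiorly by the submandibular fossa, posteriorly by the preauricular region
and medially by the facial midline. Each boundary is realized as an
axis-aligned plane through the corresponding landmark in the canonical frame —
the simplest reproducible reading of anatomical boundary names. The ROI is
defined once on oriented T0 and applied to every registered scan; per-scan
ROIs would break the additivity of volume differences.

`clip_to_roi` splits triangles exactly at the planes (new vertices on the
plane, attributes interpolated linearly), so clipped areas and volumes do not
depend on mesh resolution at the boundary. Clipping is idempotent: points
within 1e-9 mm of a plane are snapped onto it and never re-split.

## Signed distances

For each vertex p of the later scan the nearest point q on the earlier
(reference) surface is found; the signed distance is ‖p − q‖ with the sign of
(p − q)·n(q), n being the reference's outward face normal (globally
normalized by the sign of the enclosed volume when the reference is closed).
Positive values mean the later surface lies outside the earlier one —
swelling excess; negative values are deficits. The reported linear difference
is the vertex-uniform arithmetic mean of signed distances over ROI vertices
(an area-weighted mean is available but not the default), with the sample SD
alongside. Averaging *signed* rather than absolute distances is what makes
resolution between T1 and T2 come out negative.

Colormap exports write the later mesh with the signed distance as a vertex
scalar and an 8-bit symmetric diverging color (−span blue, 0 white, +span
red, clamped outside); the default span is the 95th percentile of
|signed distance|, since acquisition noise makes the raw maximum unstable.
Displacement vectors (p − q) are exported as a VTK polydata point cloud for
glyph rendering.

## Volumes

The enclosed volume of a closed, consistently oriented mesh is the divergence
theorem sum V = |Σ_f det(v0, v1, v2)/6|. A globally reversed winding is
normalized (and flagged), not treated as an error.

Open meshes are closed by filling each boundary loop with a triangle fan.
Two details matter:

* **Loop tracing.** Boundary edge sets decompose into edge-disjoint directed
  cycles; the tracer splits a cycle whenever it revisits a vertex, so pinch
  vertices shared by two holes never produce a self-crossing loop (which
  would double edges in the fill and break watertightness).
* **Fan apex.** The apex is the *arclength-weighted* centroid of the boundary
  curve. A plain vertex average moves with sampling density; for non-planar
  loops the enclosed volume depends linearly on the apex through the loop's
  vector area, so an apex that is a property of the curve — not of its
  tessellation — is required for volumes of similar patches to cancel in a
  difference.

ROI volumes in the pipeline go one step further. `clip_to_roi_solid` first
closes the scan, then clips plane-by-plane, capping each planar hole
immediately. Every cap lies exactly in its ROI plane, so the result is the
exact solid intersection of the scan with the ROI box, and cap geometry
cancels exactly between two scans sharing the ROI. (A single fan lid over the
combined non-planar boundary loop does not have this property: when swelling
displaces the boundary curve, the two lids differ and can bias the volume
difference by a few percent — this was measured against an independent
column-integration oracle and is why the solid intersection is used.) The
volume difference is then the difference of the two closed ROI volumes,
later minus earlier; with a shared ROI this telescopes, so
(T0–T2) = (T0–T1) + (T1–T2) holds to floating-point precision.

## Synthetic study conditions

The generator emulates the study design with fully known ground truth:

* **Head**: ellipsoid with semi-axes (70, 90, 100) mm — lateral, anterior,
  vertical half-extents of an adult head — as a subdivided icosahedron
  (default subdivision 4, 2562 vertices). Landmarks are placed analytically
  on the surface so that the generated frame *is* the canonical frame.
* **Swelling**: each vertex displaced along the base mesh's area-weighted
  normal by A·exp(−d²/2σ²), d the Euclidean distance to a cheek-centred
  bump point. Defaults A(T1) = 3 mm, A(T2) = 1 mm (partial resolution),
  σ = 15 mm — a bump a few centimetres across with millimetre amplitude,
  matching the scale of reported post-extraction swelling. Euclidean rather
  than geodesic distance keeps the ground truth computable independently of
  the code under test; normals are evaluated on the undisplaced mesh so the
  displacement field does not depend on its own output.
* **Ground truth added volume**: measured by the generator's own oracle as
  the difference of closed-mesh volumes after vs before the bump, at
  generation resolution. On a flat slab this converges to the closed form
  2πAσ² (the Gaussian plane integral), which the tests verify to 2 %.
* **Misalignment**: each timepoint is independently perturbed by a seeded
  random rigid motion, default within 5° and 5 mm — the natural-head-position
  repositioning error the pipeline must undo. Per-vertex Gaussian jitter is
  available but off by default.

Everything derives from a single seed; identical scenarios are bit-identical.

What the generator does *not* emulate: real facial topography (ears, nose,
eyes), scanner noise and holes, texture, non-rigid expression changes. Passing
tests therefore demonstrate the correctness of the geometry pipeline under
known deformations and misalignments, not the clinical accuracy of phone-based
scanning.

## Known limitations and numerical choices

* ROI truncation: the Gaussian bump has infinite support; its tails outside
  the ROI box are genuinely not counted. With the default geometry the
  deficit is <0.1 % at σ = 15 mm and ~1 % at σ = 25 mm, which is why the
  end-to-end recovery slope sits near 0.99 rather than exactly 1.
* Hole filling assumes edge-manifold input (≤ 2 faces per edge) and a
  consistently oriented neighbourhood; a non-manifold edge raises an error
  naming it. Self-intersecting fills are not detected; for volume purposes
  the signed sum remains the winding-number integral.
* STL corner merging is exact bitwise coordinate equality — scanner exports
  duplicate facet corners exactly, and epsilon welding would be
  resolution-dependent.
* Problem sizes in the test-suite and acceptance script (icosphere
  subdivisions 3–4, 50-seed oracle sweeps, 20 end-to-end scenarios,
  0.2 mm oracle grid) were chosen as the smallest sizes at which the
  discretization errors under test are clearly separated from the assertion
  tolerances.
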