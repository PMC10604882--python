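# Methods

This note documents the models, parameters, and numerical choices behind
`tavi4d`, and what the synthetic validation does and does not establish.

## Image model

All geometry lives in physical LPS millimetre coordinates (the DICOM
patient frame). A voxel index maps to space through
`x = origin + orientation · (spacing ⊙ ijk)`; every mask is stored on the
exact grid of its source volume, and every distance, radius, and volume is
computed in millimetres — cardiac CT voxels are anisotropic (typically
0.65 × 0.65 × 0.56 mm), so index-space geometry would be biased. DICOM
slices are grouped into phases by the temporal position identifier
(fallback: acquisition number, then equal position-sorted blocks), sorted
along the slice normal, checked for gaps, and rescaled to HU. NIfTI I/O
converts between the nibabel RAS affine and LPS.

## Frame segmentation

Thresholding at `th1` keeps everything brighter than contrast-filled
blood; `th1 = 800` HU suits nitinol frames under standard protocols and is
exposed for other alloys. Island removal drops components with fewer than
`th2` voxels (inclusive at the boundary: size ≥ `th2` survives).
`th2 = 11,000` voxels is the clinical default at sub-millimetre spacing
where metal blooming inflates the apparent strut volume; it scales with
voxel volume and device, and phantom-scale runs use `th2 = 1000`.

Dense artifacts that survive island removal (calcifications, bright
anatomy) are separated from the frame by **fill fraction**: component
voxels divided by the voxels of its *solidified hull*. The hull seals
surface apertures by morphological closing (ball, `closing_radius_mm`,
default 3 mm), caps open tube mouths (below), and flood-fills internal
cavities; the synthetic caps themselves are excluded from the hull volume.
A solid blob scores ≈ 1, a closed shell ≈ its shell/ball ratio, and a
wireframe tube scores low (struts over the enclosed cylinder, ≈ 0.15–0.35).
The component with the lowest fill fraction wins, provided it is below
`density_cutoff` (default 0.5); otherwise the study is rejected as
containing no thread-like structure. Labeling uses 26-connectivity so thin
oblique struts do not fragment.

## Filling segment

A wireframe encloses its lumen only after sealing. The filling is
computed as: close the frame with a ball wider than the inscribed radius
of a strut cell (3 mm default; raise it for large-cell devices); cap the
two open mouths with thin disks placed at the tip-crown *centroid* planes
(normal to a rough inertia axis of the frame — the eigenvector whose
eigenvalue stands apart from the two near-equal transverse ones, which is
robust for both long and short/wide tubes), sized from the local tip
radius; flood-fill; take the largest enclosed component; then run
`iterations` (default 6) rounds of one-voxel conditional closing bounded
by the true struts and the hull. A candidate cavity smaller than 5% of
the hull volume is treated as a sealing artifact and rejected ("no
enclosed cavity"), so solid inputs fail loudly.

Placing the caps at the crown centroid rather than the outermost
rasterized strut voxel makes the filling end at the tip *centerline*, the
same convention as the analytic inner volume ∫π r(h)² dh; with it the
voxel filling reproduces a cylinder's volume to ≈ 1–3%. A one-voxel
dilate/fill/erode sandwich closes staircase pinholes where the oblique
cap meets the rim; without it, diagonal background paths can leak the
cavity at non-axis-aligned tilts.

## Principal axis and reformat

The axis estimate starts from the PCA of the filling voxel cloud (in mm)
and is polished by fitting a line through ~15 axial slab centroids over
the central 90% of the extent. The refinement cancels the small bias that
surface voxelization asymmetries induce in the raw inertia axis
(≈ 1° at low tilt, < 0.2° after refinement). Slab projections are
quantized to a quarter voxel and the slab edges offset by half a quantum
so bin boundaries never cut through a single voxel plane — an exact-tie
pathology that otherwise splits a slice between slabs by the sign of a
1e-16 rounding term and skews the fit. A filling with inertia eigenvalue
ratio ≤ 1.2 is rejected as axially ambiguous.

The rotation taking the director `v` to `ẑ` is built from
`θ = arccos(v·ẑ)` and `n = v × ẑ/|v × ẑ|` via Rodrigues' formula, applied
about the study center. Conventions: `v` is sign-canonicalized to
positive z; `v ∥ ẑ` yields θ = 0, R = I; the antiparallel case rotates by
π about x̂. Resampling is trilinear for HU, nearest-neighbour for masks,
onto an isotropic grid at the input in-plane spacing, covering the
rotated bounding box.

Which tip is the outflow cannot be read from the frame alone; the tip
with the larger aortic-lumen area in the plane 5 mm beyond it is labelled
outflow (the ascending aorta continues past the device). When the root
mask is absent or the two sides differ by < 5%, an explicit configuration
flag decides. The axis is recomputed independently per phase; aligning
`h` across phases assumes the device length change over the cycle is
negligible.

## Aortic-root segmentation

Seeds: a foreground ball of `r1` voxels (default 2) at the filling
centroid — always inside contrast — and a background circle of `r2`
voxels (default 40, converted to mm with the in-plane spacing) around the
frame center of mass in the plane orthogonal to the axis, assumed to lie
outside the root on typical anatomy. Seeding never lands on a strut.

Label competition is a multi-source Dijkstra on the 6-connected grid
graph with edge weight `|ΔHU| + ε`. The `ε` term (default 1e-3 HU per
edge) is a hop-count tiebreak: on flat-intensity plateaus the boundary
lands midway between the seeds, and the result is fully deterministic;
remaining exact ties go to the foreground. Over a ~200-voxel path ε
contributes ≲ 0.2 HU, far below any tissue contrast. No spatial locality
penalty is added beyond ε. The struts are left in the cost image — they
are included in the grown region (reaching a 3000 HU voxel from the
400 HU lumen is cheaper than from 40 HU background), which matches the
meaning of `CSA_a`: the root cross-section spans the device.

Post-processing: (a) a grow-by-`g`/shrink-by-`s` smoothed copy
(`g = 1 mm`, `s = 2 mm`) masks off noisy protrusions — implemented as
closing(`g`) followed by opening(`s − g`) so each radius appears in an
exactly dual dilate/erode pair and the bulk surface is not systematically
eroded by lattice quantization; (b) opening with `r_open = 3 mm` removes
coronary-caliber side branches, keeping the largest component; (c) a
3-wide binary median smooths the surface. All metric morphology uses
exact Euclidean distance transforms with the voxel spacing as sampling;
re-dilations carry half a voxel of slack (bounded by the pre-opening
mask) so discrete rounding does not shave the smooth wall. The median
radius default is 1 voxel: at sub-millimetre voxels a 5-wide median
visibly erodes curved walls while a 3-wide one still removes salt noise.

## Metrics

`V(t)` is the filling voxel count times the voxel volume. `c(t)` is the
centroid of the *frame* mask (uniform voxel mass) — the device the
displacement formula refers to — and `d(t) = |c(t) − c(t−1)|` is defined
for t ≥ 1 with no cyclic wrap. `α(t)` are the arccosines of the absolute
direction cosines of the axis, reported in degrees in [0°, 90°].

CSA curves are measured on the reformatted stacks: per-slice foreground
pixel count × pixel area, mapped to `h` (outflow slice → 0%, inflow →
100%) and linearly interpolated onto a 1%-step grid. Up to two
consecutive empty interior slices are bridged by interpolation; more
indicate a broken filling and abort. The profile's volume integral adds
half a slice at each end (the tips extend half a slice beyond the
first/last slice centers); with that correction ∫CSA dh reproduces V to
≪ 1%. Tip-adjacent values (h < 2% or > 98%) inherit the capping
convention and are lower-confidence.

`h2` is the argmax over h of the time-averaged equivalent diameter
2√(CSA/π), after smoothing with a 5-step moving average. Two tie rules
keep the convention of outflow-maximal devices: a maximum inside the 3%
tip band snaps to `h2 = h1 = 0`, and when the set of heights within 0.5%
of the maximal diameter spans ≥ 30% of the device (an essentially
uniform caliber, sub-voxel differences only) the maximum-diameter plane
is likewise reported at the outflow. Devices with a genuinely distinct
interior bulge are unaffected.

Cohort tables aggregate, per device model, the mean and cycle range
(max − min) of V, d, and the plane-wise CSA/dCSA series, then mean ±
*sample* (n−1) standard deviation across patients. Models whose `h2`
coincides with `h1` omit the h2 rows. Cross-section eccentricity,
perimeter, and maximum diameter are deliberately out of the validated
surface.

## Synthetic phantom

The generator emulates the study conditions the pipeline targets: a
diamond-lattice wireframe tube (two helical strut families plus tip
crown rings; 12 circumferential × 8 axial cells, the small-cell topology
of self-expanding frames) of inner radius r(h), strut centerlines half a
strut outside r(h) so the lumen radius *is* r(h); apparent
(blooming-inclusive) strut thickness 1.4 mm; HU: background 40, lumen
400, frame 3000, calcification 1200, speckles 1500 — frame and
calcification above `th1`, lumen well below; Gaussian noise (σ = 20 HU,
clipped to the 0–4095 scanner range) and a small 0.15 mm PSF blur;
optional per-phase rigid translation and radial expansion, tilt of the
device axis, speckle islands, a solid calcification ellipsoid, and a
2 mm coronary-like branch on the lumen. Ten phases by default, matching
a typical gated acquisition; validation studies use 1–4 phases where the
property under test does not depend on T. Wireframe voxelization is by
exact point-cloud distance (KD-tree), making mask centroids sub-voxel
faithful — translation recovery to ~0.2 mm rides on this. The root-region
truth mask is the full contrast tube including strut-occupied voxels,
because `CSA_a` spans the device.

Not modelled: beam hardening and streak artifacts, leaflets and
calcium-on-leaflet, non-rigid wall motion, ECG mis-gating, partial-volume
blur beyond the small PSF. Passing phantom tests therefore establishes
the geometric correctness and internal consistency of the pipeline — not
its robustness to clinical artifact levels, which the threshold and
density stages only approximate.

Validation problem sizes: 96–104 voxels per axis at 0.6 mm isotropic
(≈ 0.9–1.2 M voxels per phase), device r = 10 mm, L = 30 mm inside an
R = 14–16 mm lumen; displacement studies use 4 phases, plane studies 2,
cohort studies three 2-phase patients. The static-motion study sets the
noise to zero so that repeated phases are voxel-identical and the zero
displacement is exact at mask level.

## Known limitations

- `th1`/`th2` are device- and protocol-specific; balloon-expandable
  cobalt-chromium frames need a different `th1`.
- The closing radius must exceed the inscribed strut-cell aperture
  radius; very large-cell devices require raising it (and the phantom's
  cell counts model small-cell frames).
- The background seed circle assumes the root fits inside `r2` in-plane
  voxels; unusual anatomy may need a larger field of view or smaller `r2`.
- h is normalized per phase; systematic device foreshortening across the
  cycle would alias into the CSA curves.
- The Dijkstra growth is memory-bound at ~40 bytes/voxel; very large
  grids (512³) should be cropped around the device first.
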