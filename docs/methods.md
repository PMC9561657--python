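# Methods

## Scope and model of the data

`sarcomorph` quantifies intrasarcomere structure in 3D voxel volumes of
striated muscle of the kind produced by FIB-SEM: isotropic voxels (5–15 nm),
axis 0 aligned with the contractile axis, and per-structure label or binary
masks (Z-disks, A-bands, mitochondria, SR/T, lipid droplets) produced by an
upstream pixel classifier. The package does not perform semantic
segmentation itself; it consumes masks and raw grayscale volumes. All
distances and lengths are reported in nm; positions are voxel centers,
physical position = index × voxel size. Anisotropic volumes are rejected
rather than resampled, and a `--transpose` load option reorders axes
explicitly — there is no silent auto-detection of the contractile axis.

## Synthetic phantoms and their ground truth

Every analysis stage is exercised on constructive digital phantoms
(`sarcomorph.phantom`) because real FIB-SEM volumes are 10^8–10^11 voxels
and external. A phantom is a cylindrical myofibril of radius R (default
240 nm) with:

- **Z-disks**: transverse sheets of thickness 100 nm repeating with period
  P = 2100 nm (a physiological resting sarcomere length);
- **A-band**: the myosin-bearing span, by default P − Z-disk − 2·W_I with
  I-band width W_I = 200 nm;
- **myosin filaments**: solid tubes of radius r = 10 nm on a hexagonal
  lattice with center-to-center constant a = 45 nm, one label per filament
  per sarcomere segment;
- **barrel taper**: a radial scale factor s(d) applied to every filament
  position and to the myofibril surface, falling from 1 in the A-band to
  √(1−δ) at the Z-disk face so that Z-disk CSA = (1−δ) × A-band CSA. The
  displacement is proportional to radial position (outermost shell moves
  most, the axial filament not at all), is confined to within
  W_I + Z-disk thickness of the Z-disk, and follows either a circular arc
  tangent at the A-band edge (default) or a parabola. Negative δ expands
  the ends, emulating tubular insect muscle where lattice spacing grows
  toward the filament ends.
- **organelles**: mitochondrial tubes either wrapping the Z-disk
  transversely ("grid" configuration) or running longitudinally
  ("parallel"), thin SR/T tubes, and spherical lipid droplets. Organelle
  volumes are made mutually disjoint by priority
  (Z-disk > filaments > mitochondria > SR/T > lipid). The A-band volume is
  a *region* mask of the myosin span and intentionally contains the
  filaments.

Phantom filaments span Z-disk face to Z-disk face rather than only the
A-band, so the end-most 50-nm slab of filament voxels carries the fully
compressed lattice a·√(1−δ); with a strict myosin-only extent the taper
zone would barely reach the filament tips and end-slab compression would be
unmeasurable.

Ground truth is *recomputed by counting on the emitted volumes* wherever
possible: CSA heterogeneity from per-period max-projection areas,
mitochondrial content and Z-adjacent fraction from voxel counts, per-slab
lattice constants from the taper profile. `build_matched_pair` constructs a
grid-configuration phantom and a parallel-configuration phantom whose
mitochondrial volume is solved to match, isolating network *placement*
from mitochondrial *amount*.

Grayscale rendering assigns each structure an 8-bit intensity band
(background 90, filaments 190, organelles between) plus additive Gaussian
noise with SD = contrast/SNR; bands are placed ≥4 SD from the 0/255 clip
bounds at SNR 5 so the empirical SNR is unbiased. The renderer makes no
attempt at EM texture realism (no cristae, membranes, or shot-noise
statistics), so tracer results on phantoms bound what the detector can do
on clean geometry, not its robustness to real EM contrast.

## CSA heterogeneity per half-sarcomere sheet

The sarcomere period is estimated from the autocorrelation of the per-slice
Z-disk voxel count (parabolic sub-voxel refinement; ≥3 Z-disks required;
manual override supported). The volume is tiled into period-length slabs
with boundaries at M-lines, so each slab holds one whole Z-disk sheet. Per
slab the Z-disk binary is max-projected along the axis and its foreground
area counted; each Z-disk serves its two flanking half-sarcomeres, so its
area appears twice. A-band areas come from half-period slabs: average
projection → local contrast normalization (square window of radius P/4
in-plane, clip ±10 SD, affine stretch to 8-bit) → multiply by the slab's
max-projection mask → IsoData (iterative intermeans) threshold → count.
The per-half-sheet statistic is 100·(A−Z)/A, so 40% means the Z-disk CSA
is 40% below the A-band; the raw Z/A ratio is emitted alongside because
the alternative convention A/Z−1 is also in circulation. Negative values
(inverted barrel) are allowed and flagged. On phantoms the procedure
recovers constructed δ ∈ {0, 0.1, 0.2, 0.4} within 3 percentage points at
10 nm voxels and is insensitive to 10% salt noise (the average projection
and masking absorb it).

## Z-adjacent mitochondria, proximity, local thickness

Distance fields are exact Euclidean distance transforms
(`scipy.ndimage.distance_transform_edt`), voxel-center to voxel-center.
Mitochondrial voxels within W_I + 200 nm (inclusive) of the nearest Z-disk
voxel are Z-adjacent; the fraction of mitochondrial voxels in that pool
indexes how perpendicular/grid-like the network is, and mitochondrial
content is mitochondrial voxels over cell voxels. W_I is an explicit input
measured on the raw data, never auto-estimated, and one scalar per volume.
Per-filament organelle distances are the minimum of the organelle distance
field over the filament's voxels; downstream proximity bins are half-open
(0, 100], (100, 200], … nm with exact overlap excluded by the filter
below. Local thickness implements the largest-inscribed-sphere definition:
exact EDT, pruning of voxels whose sphere lies inside a neighbor's
(distance ridge), then largest-first sphere painting. No installed package
provides this primitive, so it is implemented here directly; on tube
phantoms it recovers a 2.45-fold diameter ratio within 5%.

## Filament morphometry

Each filament is a set of unit-mass voxels (no intensity weighting). The
inertia tensor about the centroid is eigen-decomposed; *deviation from
linearity* is the moment about the filament's **longest** principal axis
divided by the voxel count — the mean squared perpendicular distance of
filament mass from its best-fit line, in nm². For an elongated body this
is the **smallest** eigenvalue of the inertia tensor: it is minimal for
straight filaments and grows with curvature, which is the behavior the
metric exists for. Some tools number eigenvalues the other way around, so
the largest eigenvalue is exposed as an alternative via a switch. Closed
forms used as oracles: a straight circular rod floors at r²/2 (50 nm² at
r = 10 nm); a thin parabolic arc of chord L, sagitta s adds (4/45)s²
(272.2 nm² at L = 1000, s = 50, r = 10). Voxelization puts a
position-dependent floor on the metric: at 10 nm voxels a 10 nm-radius
cross-section is 1–5 voxels and the floor varies by tens of nm², so
curvature comparisons between filament populations are made at 5 nm
voxels, where the floor is resolved and rotation invariance holds within
5% (at 2.5 nm voxels for single-filament eigenvalue checks). Proximity
analyses keep only filaments longer than 1 µm that share no voxel with any
organelle mask.

## Filament tracing

The detector computes, per voxel, the maximum masked normalized
cross-correlation of the grayscale volume against a hollow-cylinder
template over sampled orientations (template statistics over the
mask-cylinder window; FFT box sums for the local image mean and variance;
constant volumes yield zero correlation and a degenerate flag; a border
margin of half the template cube is invalidated because its window
statistics are truncated). Correlation is mapped to 0–255. Default
template and tracer parameters are the production settings of the source
workflow (length 100 nm, outer radius 19 nm, inner 0, mask 20 nm, ~5°
angular sampling; seed ≥115, continuation ≥80, direction coefficient 0.3,
minimum distance 20 nm, minimum length 500 nm, cone 100 nm/30°/10% step).
Two wordings in that workflow are interpretations here, both configurable:
"angular sampling 5" is read as ~5° spacing between quasi-uniformly
sampled hemisphere orientations (golden-spiral cap sampling), and
"minimum distance 20" as nm — 20 *voxels* at 5 nm would be 100 nm and
suppress genuine 45 nm lattice neighbors.

Tracing is greedy and deterministic: seeds are 3³ local maxima above the
seed threshold in decreasing correlation order (lexicographic voxel-index
tie-break); each trace grows bidirectionally, blending the previous step
direction with the local (sign-aligned, axial) orientation field, scanning
candidate points on the search cone from the minimum step outward and
doubling the step up to the cone length while correlation stays above the
seed level; a branch stops below the continuation threshold, outside the
volume, or within the minimum distance of an accepted trace; short traces
are discarded.

Full-hemisphere 5° sampling is ~800 orientations with one FFT pass each —
the production setting that took days on large workstations. The test and
acceptance suites instead use 15–20° sampling restricted to a 30° cone
around the longitudinal axis (phantom filaments are near-axial) and a
template whose outer radius matches the 10 nm rendered filament radius;
with the production 19 nm template against 10 nm cylinders the nested
indicator correlation caps near 0.19 and nothing clears the seed
threshold. On a noiseless 61-filament single-sarcomere phantom at 5 nm
voxels the tracer reaches recall and precision 1.0 at 20 nm centerline
tolerance, and pure-noise volumes clear the seed threshold in <5% of
trials.

## Lattice spacing along the sarcomere

Filament voxels are sliced into 50-nm slabs of exact distance from the
Z-disk, max-projected to 2D binary cross-sections, zero-padded to the next
power of two (no window function), and the radially averaged FFT magnitude
binned by integer-rounded radius r, mapped to real distance d = N·pixel/r.
The headline estimate is the magnitude argmax at d ∈ [30, 60] nm, with
confidence = peak/median magnitude in the band (flagged below 1.5). For an
ideal hexagonal lattice this peak is the d₁₀ row spacing a·√3/2; since
published comparisons also use center-to-center spacings, the 2/√3
conversion is emitted alongside and magnitude-vs-power is a switch. The
estimator is linear under lattice scaling and rotation-invariant to within
one radial bin; on phantoms it recovers the constructed ordering —
end slabs < center slabs when ends are compressed (mouse-like) and the
reverse when ends are expanded (tubular-insect-like).

## Geometric isometric-force model

Two scenarios for accommodating a mitochondrion at the sarcomere end.
*Uniform*: the whole CSA shrinks by f, filament count shrinks
proportionally, per-filament force unchanged → relative force 1−f.
*Heterogeneous*: only the Z-disk CSA shrinks; filament count is constant
but each filament bends along a circular arc tangent at the A-band and
inserts into the Z-disk at tilt θ(x) = 2·atan(ρ_g(1−ρ)x) for normalized
radius x, with ρ = √(1−f) and aspect ratio ρ_g = R/h (bundle radius over
taper length). Only the axial (cosine) component of the unchanged tensile
force contributes, with uniform radial filament density:

    F(f) = ∫₀¹ 2x·cos θ(x) dx = (2/q²)·ln(1+q²) − 1,  q = ρ_g(1−√(1−f)).

The closed form is an independent check on the quadrature (2001-point
trapezoid by default; agreement ~1e-7). The source geometry's R and h are
not published; ρ_g = 0.6 is the single-parameter calibration that
reproduces *both* reference losses — 1.81% at f = 0.40 and 10.26% at
f = 0.80 — jointly, and is exposed as a configuration knob. Tilts reaching
90° raise an infeasible-geometry error.

## Numerical choices and degenerate inputs

- Period slab boundaries are placed at M-lines so each slab holds exactly
  one Z-disk; periods that do not fit completely are dropped.
- IsoData thresholding runs on the contrast-normalized 8-bit image;
  single-valued slab images raise rather than returning a fabricated area.
- The Z-adjacent threshold comparison is inclusive (≤).
- Local-thickness sphere painting is largest-first so overwrites are
  monotone.
- Single-voxel filaments have all-zero inertia eigenvalues and are flagged
  degenerate, not dropped.
- Empty masks, empty slabs, flat axial profiles, and all-zero FFT images
  raise `ValueError` with specific messages.
- Every stochastic operation (noise rendering, droplet placement) takes an
  explicit seed; fixed seed ⇒ bit-identical output.

## Problem sizes

Phantoms in the test and acceptance suites are 2–3 sarcomere periods at
10 nm voxels (≈630×85×85 voxels) for CSA/partition/lattice work, one
period at 5 nm voxels (≈420×97×97) for tracing and curvature comparisons —
sizes chosen so the full constructive geometry (≥50 filaments, ≥3 Z-disks,
complete taper zones) is present while any stage runs in seconds to a few
minutes on one CPU.

## Known limitations

- Phantoms are periodic, noise-free in geometry, and contain no myofibril
  branching, no actin, no cross-bridges, and no EM texture; passing tests
  demonstrate correctness of the measurements on known geometry, not
  performance on real FIB-SEM contrast.
- The tracer matches the *described* behavior of the reference
  correlation-tracing workflow, not any proprietary implementation's
  numerical output; seed suppression and cone-search internals differ in
  unknowable details.
- The force model is purely geometric: no molecular dynamics, no
  lattice-spacing dependence of cross-bridge kinetics, no sarcomere-length
  dependence.
- Individual-mitochondrion statistics (instance segmentation) are out of
  scope; the partition operates on semantic masks.
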