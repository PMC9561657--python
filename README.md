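# sarcomorph

Intrasarcomere morphometry for 3D volume electron microscopy of striated
muscle.

In muscle cells the contractile sarcomeres and the organelles that power
them — mitochondria, sarcoplasmic reticulum, lipid droplets — compete for
the same tightly packed volume. When mitochondria wrap perpendicularly
around the sarcomere ends, the sarcomere's cross-sectional area (CSA)
shrinks locally at the Z-disks, the peripheral myosin filaments bend, and
the hexagonal myofilament lattice compresses near the filament ends.
`sarcomorph` provides the measurements to quantify all of this from
isotropic voxel volumes (FIB-SEM scale, 5–15 nm voxels) plus a geometric
model of what the deformation costs in contractile force. It is written
for microscopists and muscle physiologists working with segmented vEM
data, and ships a synthetic phantom generator with exact ground truth so
every stage is testable without microscope data.

## What it computes

- **CSA heterogeneity per half-sarcomere sheet** — per sarcomere period,
  max-projected Z-disk area Z versus A-band area A;
  statistic 100·(A−Z)/A.
- **Z-adjacent mitochondrial partition** — fraction of mitochondrial
  voxels within W_I + 200 nm (exact Euclidean distance) of a Z-disk, the
  index of a grid-like vs parallel network; plus mitochondrial content.
- **Myosin filament tracing** — normalized cross-correlation against a
  hollow-cylinder template over sampled orientations, greedy centerline
  tracing through the correlation/orientation fields, rasterization to
  label volumes.
- **Deviation from linearity** — per filament, the moment of inertia about
  its longest principal axis divided by volume: the mean squared
  perpendicular distance from the best-fit line (nm²), r²/2 for a straight
  rod of radius r, (4/45)s² + r²/2 for a thin parabolic arc of sagitta s.
- **Organelle proximity** — exact-EDT minimum distance from each filament
  to each organelle class; local-thickness (largest inscribed sphere)
  diameters.
- **Lattice spacing along the sarcomere** — per 50-nm distance-from-Z-disk
  slab, the radial 2D-FFT magnitude peak at 30–60 nm (the hexagonal d₁₀
  row spacing a·√3/2 for an ideal lattice; the 2/√3 center-to-center
  conversion is emitted alongside).
- **Isometric-force model** — uniform CSA reduction costs force
  proportionally (1−f); reducing only the Z-disk CSA tilts filaments by
  θ(x) = 2·atan(ρ_g(1−ρ)x) with ρ = √(1−f), costing only
  1 − ∫₀¹2x·cosθ(x)dx — about 1.8% at a 40% Z-disk reduction and 10.3%
  at 80% with aspect ratio ρ_g = 0.6.

See `docs/methods.md` for the full model descriptions, parameter defaults,
and numerical choices.

## Worked example

Build a mouse-like phantom (grid mitochondria, Z-disk CSA reduced 40%,
three sarcomeres at 10 nm voxels) and measure it:

```python
import sarcomorph as sm

spec = sm.preset_spec("mouse_like", n_periods=3, seed=1)
ph = sm.build_phantom(spec)

table, summary = sm.measure_csa_heterogeneity(ph.volumes["zdisk"],
                                              ph.volumes["aband"])
print(summary)
# {'mean_percent_difference': 39.486893474623535,
#  'sd_percent_difference': 0.0, 'n_half_sheets': 6, 'any_inverted': False}

part = sm.partition_mitochondria(ph.volumes["mito"], ph.volumes["zdisk"],
                                 iband_width_nm=spec.iband_width_nm,
                                 cell=ph.volumes["cell"])
print(part.z_adjacent_fraction, round(part.mito_content, 4))
# 1.0 0.0121
```

The measured heterogeneity (39.5%) recovers the constructed 40% Z-disk CSA
reduction; every mitochondrial voxel of the Z-wrapping grid network falls
inside the W_I + 200 nm Z-adjacent threshold, at a mitochondrial content
of 1.2% of cell volume. The force model puts numbers on what that barrel
shape costs:

```python
from sarcomorph import force
print(force.force_curve([0.0, 0.4, 0.8]).round(4).to_string(index=False))
#   f  uniform_force  heterogeneous_force  uniform_loss_pct  heterogeneous_loss_pct
# 0.0            1.0               1.0000               0.0                  0.0000
# 0.4            0.6               0.9819              40.0                  1.8070
# 0.8            0.2               0.8974              80.0                 10.2551
```

Reducing the whole sarcomere CSA by 40% costs 40% of the force; confining
the reduction to the Z-disk costs 1.8%.

A command-line interface mirrors the stages
(`sarcomorph phantom|trace|linearity|proximity|csa|mito|lattice|force|all`);
`sarcomorph all --out results/ --preset mouse_like` runs the whole phantom
pipeline into a directory of CSV/JSON tables.

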