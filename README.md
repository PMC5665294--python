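# sfxgeom

Detector-geometry refinement for serial still-shot (XFEL-style)
crystallography.

Segmented detectors such as the CSPAD are dismantled and rebuilt often, so
the positions of their panels must be back-calculated from diffraction data.
`sfxgeom` implements a refinement protocol that decomposes every panel
correction into two movement families refined against separate targets:

* **Euclidean movements** — translation *d* along the spindle joining the
  sample to the panel centre, and tilts *α*, *β* about the two axes through
  the panel centre normal to the spindle.  These change the relative
  arrangement of back-projected rays and are refined by maximizing a
  reward-based clustering score of the pixel offsets between observed and
  predicted spots,

  E = Σᵢ Σⱼ≠ᵢ exp(−[(Δxᵢ−Δxⱼ)² + (Δyᵢ−Δyⱼ)²]/k²),  k = 5 px,

  which depends only on pairwise offset differences and is therefore robust
  to outliers, unlike least squares.

* **Non-Euclidean (sphere) movements** — rigid rotations *θ*, *φ*, *ψ* of a
  panel or panel group about an axis through the sample.  These slide the
  panel over a sphere, preserving the relative arrangement of back-projected
  rays exactly, and are refined by centring the reciprocal-space offsets on
  the origin,

  F = Σᵢ exp(−|Δqᵢ|²/k²),  k = 0.002 Å⁻¹.

Both stages use derivative-free Nelder–Mead simplex optimization, panel by
panel, independent of the detector hierarchy, so any global trend (overall
tilt, distance error) emerges unbiased.

When no indexing solutions exist, an orientation-free path refines geometry
against the **unit-cell fingerprint**: the joint distribution of (length,
length, angle) over pairs of back-projected inter-spot vectors sharing a
spot, which is fixed by the cell dimensions and centring alone.  A 240³
lookup grid scores observed spot triads from 0 to 1; panels are first
refined individually (Euclidean modes, intra-panel triads), then locked to
each other by equal-and-opposite sphere rotations of sibling groups,
ascending the pairing hierarchy to the full detector.

A third component decouples the unit-cell scale from the detector distance
by over-predicting reflections and rescaling the cell so the implied
wavelengths λᵢ = −2 q_z/|q|² of strong reflections centre on the nominal
wavelength, compensating the detector distance by the reciprocal factor.

A seeded synthetic still-diffraction generator (multi-panel detector,
body-centred cubic cell a = 105.5 Å at λ = 1.46 Å by default) makes the
whole protocol testable by perturb-and-recover studies without external
data.

## Worked example

```python
import numpy as np
from sfxgeom import (SceneSpec, make_scene, perturb, PerturbBounds,
                     IndexedGeometryRefinement, RefineConfig,
                     rms_corner_displacement)

scene = make_scene(SceneSpec(n_images=30, seed=2))        # truth + spots
bounds = PerturbBounds(slide_px=2.0, tilt_rad=np.deg2rad(0.2), d_mm=0.11)
perturbed, record = perturb(scene.detector, bounds, seed=7)

print(f"RMS corner error before: "
      f"{rms_corner_displacement(perturbed, scene.detector):.4f} mm")

model = IndexedGeometryRefinement(perturbed, scene.spots, scene.lattices,
                                  wavelength=1.46,
                                  config=RefineConfig(max_cycles=3))
res = model.fit()
print(f"RMS corner error after:  "
      f"{rms_corner_displacement(res.detector, scene.detector):.4f} mm")
print(res.summary())
```

Output:

```
RMS corner error before: 0.1848 mm
RMS corner error after:  0.0019 mm
Geometry refinement (indexed, slip+slide)
  cycles run:            3
  panels:                16
  corner shift RMS (mm): 0.18487
  mean px spread:        0.0405 -> 0.0022
  mean |dq| (A^-1):      0.001218 -> 0.000001
  mean |dq| reduction:   99.9%
```

The 16-panel detector was perturbed by up to 2 pixels of translation and
0.2° of tilt per panel (1.68 px RMS corner error at 0.11 mm pixels); three
refinement cycles on 30 still images recover the true geometry to about
0.02 px, reducing the mean reciprocal offset by ~99.9% on this noise-free
scene.

The same workflow is available from the shell:

```sh
sfxgeom simulate --n-images 150 --seed 1 --out scene/
sfxgeom refine-indexed --geom scene/perturbed.geom --spots scene/spots.csv \
        --orientations scene/lattices.json --out refined.geom --report report.json
sfxgeom refine-preindex --geom scene/perturbed.geom --spots scene/spots.csv \
        --cell 105.5,105.5,105.5,90,90,90 --centring I --out refined.geom
sfxgeom refine-cell --geom scene/truth.geom --spots scene/spots.csv \
        --orientations scene/lattices.json --out cell.json
```

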