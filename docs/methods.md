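# Methods

## The geometry model

The laboratory frame is right-handed with the origin at the sample, +Z along
the beam toward the detector and +Y toward the ceiling.  Each detector
segment (panel) stores a midpoint (mm), unit fast- and slow-scan axes, a
pixel grid and a pixel size; continuous pixel coordinates run over
[0, n_fast] × [0, n_slow] with the centre of integer pixel (i, j) at
(i + 0.5, j + 0.5), and the panel midpoint is the geometric centre of the
active area.  Panels are paired recursively into groups — pairs, foursomes,
quadrants, halves — ending in a single master group; a transform applied to
a group moves all its descendants rigidly, and an unpaired group at an odd
level is promoted unchanged to the next level.

Movements accumulate as *pending* parameters and are absorbed into the
stored midpoint/axes at the end of each refinement cycle; absorption is a
pure representation change (the pixel-to-lab map is preserved to better
than 1e-10 mm) that resets all six parameters to exactly zero.

### Movement modes and conventions

*Euclidean* modes: translation `d` (mm) along the spindle from the sample to
the panel midpoint, then tilts `alpha`, `beta` (radians) about two
orthonormal axes through the midpoint normal to the spindle.  The tilt axes
are built deterministically: u1 = spindle × lab-Y (normalized; lab-X if the
spindle is nearly parallel to Y), u2 = spindle × u1; `alpha` is applied
before `beta`.  Tilts leave the sample-to-midpoint direction unchanged.

*Sphere* (non-Euclidean) modes: a rigid rotation about an axis through the
sample, parameterized by `psi` about the reference axis itself, then
`theta` and `phi` about the two completing orthonormal axes (same
deterministic completion).  The reference axis defaults to the panel's own
spindle; for pairwise group refinement it is the direction of the midpoint
of the two group centres.  Sphere moves preserve every sample-to-pixel
distance and all pairwise angles between rays — they slide the panel over a
sphere without changing the relative arrangement of back-projected
reciprocal coordinates.  No rotation-order convention is given by the
underlying protocol; because all refined angles are small (≲ 1e-3 rad) any
fixed order is equivalent to second order, and the one above is used
throughout.

A lateral (pure X) panel shift is not a single mode: it decomposes into a
Euclidean component (spindle translation + tilt) and a sphere rotation, and
the two stages of refinement recover it jointly.

## Still prediction and offsets

A detector position p back-projects onto the Ewald sphere as
q = (1/λ)(p/|p| − ẑ).  A reciprocal lattice point q = UB·(h,k,l) is
predicted when it passes the centring rule (I: h+k+l even; C: h+k even; F:
h,k,l same parity; axial absences deliberately ignored), lies within the
reciprocal-lattice-point (rlp) radius of the sphere, and its ray q + ẑ/λ
intersects a panel within the resolution limit.  Prediction uses a single
nominal wavelength; the rlp radius plays the role of a profile radius and
absorbs bandwidth.

Observed spots are matched to predictions by searching the surrounding
pixels up to a Chebyshev radius (default 5; 0 for validation) for the
highest pixel value, ties resolving to (slow, fast) scan order.  Each match
stores the offset both in pixels and in reciprocal coordinates; the
reciprocal offset is the difference of the *on-sphere* back-projections of
the observed and predicted positions, so it vanishes identically when the
observation coincides with the prediction.  Strong reflections are
classified by an I/σ(I) equivalent with a Poisson photon model,
σ(I) = gain·sqrt(I/gain) (gain 9.0 ADU/photon, cutoff 0.67); whether the
underlying protocol background-corrects intensities before this cut is not
stated, so the plain model above is the declared choice.

## Indexed refinement

Per panel and per cycle: (1) the Euclidean modes maximize the clustering
reward E (k = 5 px) over strong pixel offsets; (2) the sphere modes maximize
the origin-centring reward F (k = 0.002 Å⁻¹) over strong reciprocal
offsets; (3) pending movements are absorbed.  Matched offsets are frozen at
the start of each cycle and re-derived on the fly under trial movements.
Panels are refined independently of the hierarchy so global trends remain
unbiased.  E is evaluated from the panel's Euclidean-only configuration;
this makes the Euclidean target *exactly* invariant under sphere moves,
which is the formal content of the stage separation: each target depends
only on the modes it refines.

The exact functional forms of the two rewards are reconstructed from their
described properties (a summed exponential of pairwise axis offsets; an
exponential of the reciprocal offset magnitude; scale constants k as above;
F linear-time, E quadratic).  Tests therefore assert properties —
translation invariance, maximum location, loop-oracle equality, robustness
— never absolute score values.

Optimization is Nelder–Mead, by default sequentially one parameter at a
time (initial steps 0.2 mm for d, 0.05° for angles; score tolerance 1e-6),
cycling three times over the parameter list: the d/α/β modes are weakly
correlated through the reward and two passes can stall short of the
optimum on shallow landscapes, while three converge; a joint 3-parameter
simplex is available via `RefineConfig(joint_simplex=True)` and is slightly
more accurate but less faithful to the "each mode refined independently"
design.  The refinement never accepts a score regression (best-seen is
kept) and absorbs after every cycle (default budget 5 cycles).

## Cell-scale refinement

Cell scale and detector distance are confounded.  The decoupling uses the
implied wavelength λ(q) = −2 q_z/|q|² — the wavelength at which a
reciprocal point would sit exactly on the sphere.  Reflections are
over-predicted (rlp radius inflated ×3 by default), located by the local
search, classified strong, and the cell lengths are rescaled by the scalar
s that brings the *median* strong implied wavelength onto the nominal
wavelength (median, not mean, for robustness to over-prediction outliers;
1-D Nelder–Mead).  The detector distance is compensated by 1/s, and
per-image orientation refinement (two small rotations perpendicular to the
beam, minimizing Σ|Δq|²) alternates with the rescale until |s−1| < 1e-4.
Only the single cubic-symmetric scale is refined, not individual axes or
angles.  The loop's contract is that the implied-wavelength distribution
centres on the nominal wavelength; the split between cell and distance
retains a residual confound of a few tenths of a percent.

## Pre-indexing (fingerprint) refinement

Back-projected inter-spot vectors shorter than 0.15 Å⁻¹ are collected per
image (intra-panel: both spots on one panel; inter-panel otherwise).  The
ideal unit-cell fingerprint is a 240³ single-precision grid over
(length, length, angle) ∈ [0, 0.15 Å⁻¹]² × [0°, 90°]: every pair of
reciprocal lattice vectors of the cell stamps a linear ramp rising from 0
at the tolerance edge to 1 at the ideal value, with length tolerance equal
to the rlp radius and angle tolerance asin(r/l1) + asin(r/l2) so shorter
vectors get wider tolerances; the grid is symmetric in the two lengths and
angles are folded into [0°, 90°].  Lookup uses trilinear interpolation
between voxel centres so the refinement target is piecewise smooth.

Spot triads (three spots whose three pairwise vectors all pass the cutoff,
limited to the 40 highest-value spots per image for tractable
combinatorics) are scored as the product of their three pair scores and
summed.  Per-panel Euclidean modes are refined against triads lying
entirely on the panel (skipped below 30 intra-panel vector pairs); sibling
groups are then locked pairwise by a single (θ, φ, ψ) applied with equal
and opposite sign to the two groups about the axis toward the midpoint of
their centres, ascending the hierarchy to the master group.

The ascent runs coarse-to-fine.  The fingerprint score of a group pair has
a sharp basin around the aligned configuration whose width scales with the
lookup tolerance; at the nominal 0.002 Å⁻¹ it is about ±5·10⁻⁴ rad, which
can be narrower than the relative group misalignment left by the per-panel
stage, and a purely local search then locks onto a sidelobe.  A first
ascent pass against a 0.006 Å⁻¹-tolerance lookup (basin wide enough to
contain the expected start) is therefore followed by a pass against the
nominal lookup; the coarse pass may be disabled via
``coarse_tolerance=None``.  In addition, every pair stage seeds its simplex
from a deterministic 9×9 bracketing grid over the two lateral angles
(half-width 3 px equivalent), guaranteeing a start inside the true basin
whenever the relative misalignment is within that bracket.  Alignment of
the whole detector to the beam centre is intentionally left to the indexed
path: without orientations the global tilt is only bounded by the
scattering angle of the lowest-resolution reflection.

Equal-and-opposite rotations conserve each group's sample distances
exactly; the midpoint of the two group centres is conserved only to second
order in the angle (exact conservation is geometrically impossible for
rigid sphere rotations), which suffices to prevent net drift at the ≲1e-3
rad angles encountered.

Because ideal peaks are sampled at voxel centres, the fingerprint target
has a quantization floor of roughly half a pixel equivalent (the length
voxel is 6.25e-4 Å⁻¹ ≈ 0.75 px at the default geometry): refining an
already-true geometry drifts by up to ~0.5 px RMS.  The pre-indexing path
is therefore a bootstrap stage — it pulls panels from a few pixels of error
to within the quantization floor, after which indexed refinement reaches
hundredths of a pixel.

## Synthetic scenes

The generator emulates still-diffraction spot lists, not pixel images.
Defaults define the study conditions used throughout the tests: a 16-panel
4×4 detector (120×120 px panels, 0.11 mm pixels, 18 px gaps) at 90.3 mm; a
body-centred cubic cell a = 105.5 Å at λ = 1.46 Å; rlp radius 3e-4 Å⁻¹ and
a 3.5 Å resolution limit chosen to match the synthetic detector's angular
acceptance (≈50 spots per image).  Orientations are uniform random
rotations from seeded normalized quaternions.  Observed spots are the
truth-geometry predictions plus optional Gaussian pixel noise and uniform
outlier spots; intensities are log-normal photon counts (median 2 photons,
shape 1.5) scaled by the 9.0 ADU/photon gain so that roughly 80% of spots
pass the strong cut, exercising the I/σ classifier.  Perturbations draw
all six movement modes uniformly within bounds and are recorded so truth
can be replayed exactly.

What the generator does *not* model: background and peak profiles (spots
are points with a single value), spectral bandwidth beyond the rlp slab,
per-pixel gain variation, panel-internal distortion, and indexing failure
modes (orientations, when used, are exact).  Passing recovery tests
therefore demonstrates the correctness and convergence of the protocol
under its own assumptions, not performance on detector images.

## Validation studies

The canonical studies live in `sfxgeom.validation` and are reported by
`scripts/acceptance.py`:

* closed-form scattering angle of the (1,1,0) reflection of the 105.5 Å
  I-centred cell through the back-projection map, and the 106.1 → 105.5 Å
  cell deflation percentage;
* indexed perturb-and-recover: 150 noise-free images, per-panel
  perturbations ≤ 2 px translation-equivalent and ≤ 0.2° tilt, RMS corner
  displacement before vs after;
* pre-indexing perturb-and-recover: 500 images, ≤ 2 px translations, no
  orientations;
* half-data-set validation: scenes with 0.3 px noise and 5% outlier spots
  (noise is what makes the two halves differ, so the correlation trend is
  informative), 25 spots per image, odd/even halves refined independently
  from the same perturbed start at 30 and 150 images per half over five
  seeds; the median per-axis Pearson correlation of corner changes grows
  with images per half;
* outlier robustness: a corner panel tilted 0.2° on a 40-image scene with
  0.2 px noise, tilt modes refined with 10% of pooled offsets replaced by
  uniform ±10 px outliers (median of three draws); the reward-based stage
  must stay within twice its clean-data error while the least-squares
  comparison target degrades further.  The light noise gives the clean
  error a meaningful scale; on exactly noise-free data the clean error is
  zero at machine precision and the ratio is undefined.

Problem sizes (images per study, spots per image, Nelder–Mead budgets) are
the package's chosen study conditions: large enough that every recovery
result is far from its threshold, small enough to run on a laptop in
minutes.

## Known limitations

* The radial distance d and the two tilts are weakly separated when the
  Ewald sphere is flat (short wavelength, long distance); this is inherent
  to the information content of the data.
* The fingerprint grid's voxel quantization bounds pre-indexing accuracy at
  about half a pixel; finer grids trade memory for accuracy.
* The cell/distance decoupling leaves a residual confound of a few tenths
  of a percent split between the two.
* File I/O supports a CrystFEL-style geometry dialect subset (fs, ss,
  corner_x/y, min/max extents, res, clen, group paths); masks, bad regions
  and per-pixel maps are out of scope.
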