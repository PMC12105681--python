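# Methods

## The model

The observable throughout is the reduced pair distribution function of an
isolated scatterer in dilute solution,

    G(r) = (s / r) * sum_{i<j} 2 w_ij N(r; r_ij, sigma_ij),

a weighted sum of unit-area Gaussians over unordered atom pairs.  Scattering
weights are `w_ij = f_i f_j / <f>^2` with `f = Z` (the Q→0 limit of the
X-ray form factor): the analysis lives entirely in real space and only the
relative Ag/Cl/C/N/O/P contrast matters, which Z captures.  Pair widths are

    sigma_ij^2 = (B_iso,i + B_iso,j) / (8 pi^2) + sigma_0^2,

where `sigma_0 = 0.05 Å` is a fixed instrument-resolution floor: a finite
Qmax always broadens an experimental PDF, and the floor also keeps model
peaks representable on the default 0.01 Å grid.  No `4 pi rho_0 r` baseline
is included — after background subtraction a dilute solution has no
meaningful average density; the smooth residual channel is handled by the
solvation wave instead.  No correlated-motion (delta-2) peak sharpening is
applied.  Gaussians are evaluated within ±5 sigma; the value at the cutoff
is subtracted before clamping at zero, so the truncated profile is
continuous and the histogram-convolution fast path (below) agrees with the
direct sum to better than 1e-8 instead of being limited by the cutoff step.

Reciprocal-space reduction implements only scaled background subtraction
(`y_sample - s * y_background`) and the sine transform
`G(r) = (2/pi) \int_{qmin}^{qmax} F(Q) sin(Qr) dQ` by trapezoidal
quadrature (defaults qmin = 0.7, qmax = 20 Å⁻¹).  Full intensity
normalisation — Compton, polarisation, absorption, `<f>^2` division —
belongs to beamline reduction software and is out of scope.  `auto_scale`
proposes a background scale by least squares over a user-chosen
background-dominated window; it is a helper, never applied silently, and
its no-negative-excursion cap only engages for intensity-like
(non-negative) curves, since reduced structure functions oscillate through
zero by construction.

## Two-stage refinement

Stage 1 minimises the pointwise misfit over the 3N Cartesian coordinates
plus one scale — 55 parameters for the 18-atom core — with scipy's
trust-region-reflective least squares, each coordinate bounded within
`max_shift = 1.0 Å` of its start value.  The bounds fix the gauge: the PDF
depends only on internal distances, so unbounded rigid drift would be
unidentifiable.  The fit range defaults to 1.7–15 Å (excludes sub-bond
artefacts; the signal is featureless above ~12 Å).  Gradients of the
Gaussian pair sum are analytic — exact closed forms in the pair distances —
which makes a 500-member ensemble tractable on one CPU; a finite-difference
mode remains available (`jac="2-point"`).  The cost tolerance is 1e-10 by
default (ensembles in the test suite use 1e-8 with a 150-iteration cap).
Atom collisions are excluded by a hinge penalty on inter-atomic distances
below 0.5 Å appended to the residual, the smooth equivalent of rejecting
collision steps.

Stage 2 adds the empirical solvation wave
`w(r) = A sin(2 pi r / lambda + phi) exp(-r / xi)`, the damped-sine
signature of solvent restructuring around a dissolved ionic cluster.  The
`exp(-r/xi)` damping form was chosen and is documented here; the wavelength
is initialised from the dominant Fourier period of the stage-1 residual,
the amplitude from its extremum, and four deterministic phase starts are
scanned.  If no wave start improves on stage 1, a zero-amplitude wave is
returned, so Rw is non-increasing across stages by construction.  Whether
positions re-relax jointly with the wave is a flag
(`relax_positions_with_wave`, default off: it roughly doubles the cost and
did not improve recovery on synthetic ground truth).

### Rigid twist pre-stage

Correlated distortion fields — whole Ag channels rotating together about
the cluster axis — defeat a free-atom local optimiser: the coherent move is
several tenths of an Å long, while incoherent per-atom moves reach shallow
spurious minima first.  Following the crystallographic convention of
rigid-body-before-individual refinement, an optional pre-stage
(`rigid_groups`, keyed by the user-supplied channel map) refines one twist
angle per channel about the principal axis.  Three further choices matter:

* **Gauge.** A common rotation of all channels about the axis is an exact
  isometry of every pair distance, so only twist *differences* are
  identifiable.  The pre-stage therefore works in the zero-net-rotation
  gauge (G−1 free angles, the last balancing the sum), and every reported
  twist pattern is that gauge's representative.  Consumers comparing to an
  external reference field should compare patterns after removing the
  common rotation.
* **Basins.** Distinct twist sign patterns form distinct basins; a single
  descent from zero can land in the wrong one.  The pre-stage scans a
  deterministic coarse grid (±10°, ±5°, 0 per free angle), polishes the
  best starts, and ranks the distinct polished solutions by their misfit
  *after* fitting the solvation wave to each residual — the smooth wave
  otherwise tips the choice between near-degenerate basins.
* **Sharing.** In ensemble runs the pre-stage runs once from the common
  unperturbed start; each member begins its free-atom refinement from its
  own perturbation plus that shared coarse solution.  A per-member
  pre-stage would see the ±0.2 Å start perturbation as incoherent noise on
  every pair distance and scatter between basins.

## Ensemble refinement

Each member perturbs every coordinate of the start model by an independent
uniform draw in ±`max_disp` (default 0.2 Å), refines through both stages,
and is stored with its seed (`base_seed + index`) and convergence flag.
The 500-model default follows the ten-models-per-parameter heuristic for a
55-parameter fit; tests and the acceptance script use 20–50 models, which
keeps runs in the minutes on one CPU at the default grid.  Members are
independent; any parallel schedule must reproduce the sequential result.
Refined positions are averaged per atom without re-superposition — all
members share one frame because their refinements are bounded near a
common start — and per-atom spreads (min, max, median, IQR of the distance
from each atom's ensemble mean) provide box-plot statistics.  The mean of
the stage-1 (pre-wave) residuals suppresses member-specific fit noise by
roughly sqrt(n) and exposes any common signal the cluster model cannot
explain — for a DNA-wrapped cluster, the conformational signature of the
bound DNA.

## Distortion geometry

The principal axis is the leading eigenvector of the covariance of the
*reference* coordinates (unweighted), so the axis never inherits
refinement noise; its sign convention (largest-magnitude component
positive, ties towards +z) makes reported angle signs platform-stable.
Positive angles are counterclockwise looking down the +axis direction.
Per-atom records carry the displacement vector (refined − reference), its
magnitude, the signed rotation angle between the two projections onto the
plane perpendicular to the axis, and the radial distance; atoms within
0.1 Å of the axis have undefined angles and are excluded from summaries.
Channel and strand assignments are input metadata (CSV maps), not
computed: there is no robust geometric definition of a channel, and strand
coordination comes from inspection of the crystal contacts.

## DNA conformation

`dna_pdf` computes the PDF of a uniform-Biso structure by linear binning
of the pair distances (2e-5 Å bins) followed by one FFT Gaussian
convolution — mathematically identical to the per-pair sum (equal to it
within ~1e-8) and fast enough for thousands of atoms in a couple of
seconds.  `biso_scan` fits each broadened crystal-DNA PDF to the target
with a closed-form scale and an optional rigid r-shift within ±0.5 Å (the
shift absorbs solution-state swelling), records Rw over r = 3–10 Å — the
window of the medium-range conformational features near 5.2 and 7.7 Å —
and returns the grid argmin.  The default grid 0.25–6.0 Å² in 0.25 steps
brackets crystal-like (0.5), optimal (2.0) and heavily broadened (5.0)
regimes.  The misfit minimum is shallow: with 5% noise the recovered
optimum is typically within one grid step of truth, occasionally two.
`biso_to_rms` converts the optimum to the one-dimensional RMS displacement
`u = sqrt(B_iso / 8 pi^2)` (0.159 Å at 2.0 Å²).

Nucleotide fragment geometries for the base-composition linear-combination
model come from RDKit (ETKDG embedding, MMFF relaxation, fixed seed);
hydrogens are dropped for the X-ray weighting.  The full deoxynucleoside
monophosphate is the default fragment — backbone C–C and P–O bonds carry
the prominent 1.4–1.6 Å bonded distances — with bare bases available via a
flag.

## Synthetic ground truth

The toy cluster mimics the real core's motif — sixteen Ag in four axial
channels around a common axis, two Cl caps on the axis — without being the
crystal structure: 2.4 Å channel radius, 2.8 Å axial spacing (the
first-shell Ag–Ag distance), a 10°-per-layer helical stagger, and an
*irregular* per-channel axial offset (0, 0.70, 0.32, 1.23 Å by default).
The irregularity is essential, not cosmetic: with equivalent channels,
cyclically permuted or reflected twist patterns are homometric — they
produce identical pair-distance spectra — and no estimator could recover
which channel rotated which way.  Real DNA-templated clusters have
crystallographically inequivalent channels, so the irregular stand-in is
also the more faithful one.

The distortion field is a rigid per-channel twist about the principal axis
(defaults +9°, +12°, −3°, −3°: two channels one way, two the other) plus
i.i.d. Gaussian jitter (0.05 Å per coordinate).  Observables add a damped
sine wave (amplitude 10% of the PDF maximum, wavelength 7 Å, decay 6 Å)
and white Gaussian noise (1% of the maximum).  DNA-like backgrounds are
built empirically: sharp bonded peaks at 1.46/2.43/3.69 Å, weak packing
features near 5.5/7.6 Å under a decaying envelope (flat beyond 15 Å), with
the cluster-bound variant adding two broad conformational features near
5.2 and 7.7 Å.  Every generator is a pure function of its spec and seed.

What passing the synthetic recovery tests does and does not show: the
generators share the package's own Gaussian peak model, additive noise,
and exact background additivity, so recovery demonstrates the estimator's
correctness and conditioning, not robustness to the multiplicative and
Q-dependent systematics of real reduced data (imperfect corrections,
correlated noise, Q-dependent form-factor effects).

## Numerical and statistical caveats

* **Axial-rotation gauge.** The PDF is invariant under any rigid motion of
  the whole model; position bounds anchor translations and off-axis
  rotations tightly, but rotation about the long principal axis moves
  atoms little and is essentially free.  Recovered twist patterns are
  therefore zero-net-rotation representatives; only twist differences and
  the sign pattern are data-determined.  Raw-coordinate RMS comparisons
  between refined and generating structures likewise include rigid-motion
  components; tests remove them by Kabsch superposition where exactness is
  asserted.
* **Local minima at high resolution.** With Biso = 0 the pair peaks are
  0.05 Å wide and free-atom refinement has local minima even for small
  (≲0.1 Å) displacement fields; thermal broadening (Biso ≈ 0.5 Å²) widens
  the basins at the cost of resolution.  The rigid pre-stage exists
  precisely to cross this landscape along the coherent directions.
* **Degenerate inputs.** Coincident atoms raise immediately; on-axis atoms
  are flagged rather than given meaningless angles; an all-zero observed
  curve cannot be fit (Rw undefined); non-converged members are flagged,
  not dropped, and more than 20% member failures aborts the ensemble.
* **Determinism.** Identical inputs, options and seeds give bit-identical
  results everywhere: the optimiser is deterministic, all multi-starts are
  fixed grids, and every random draw flows from an explicit seed.
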