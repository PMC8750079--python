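# Methods

`minibeams` models the delivery of planar proton minibeams through a
multislit (or dynamic-aperture) collimator, the magnetic convergence of
those minibeams with dipole or in-phantom fields, and the dosimetric
consequences in a water phantom.  This note records the models, the
parameters that matter, and the boundaries of what the package can and
cannot claim.

## Proton physics

Kinematics are exact relativistic closed forms: momentum
p = sqrt(E(E + 2m)) with m = 938.272 MeV, magnetic rigidity
B&rho; = p/(299.792 MeV/c per T·m).  Two range–energy models are provided:

* **power-law** (default in the library): the Bragg–Kleeman relation
  R = &alpha;E^p with &alpha; = 0.0022 cm·MeV⁻ᵖ, p = 1.77 — a closed,
  invertible form adequate for water over the therapeutic band;
* **tabulated**: monotone PCHIP interpolation of the bundled CSDA table
  for liquid water (NIST PSTAR values, rounded), inverted on the same
  monotone interpolant.

The two agree within 2% over 70–230 MeV.  The tabulated mode is used for
everything that is compared against published depth or field values,
because the published layer peak depths (157–187 mm for 150–166 MeV)
match the CSDA table (157.7 mm at 150 MeV) and not the power law
(156.0 mm).  Energies above 230 MeV are rejected: the transport model is
only parameterized up to that bound.

Range straggling uses &sigma; = 0.012·R^0.935 (cm); multiple Coulomb
scattering uses the Highland angle with X₀ = 360.8 mm for water, without
the logarithmic correction inside the Fermi–Eyges integrand (it is applied
once per finite step in `highland_sigma_theta`; the difference is below
the fidelity of the engine).

## Geometry and delivery

All lengths are mm, energies MeV, fields tesla, angles radians; degrees
appear only at configuration boundaries (tilt gradients are quoted in
deg/mm).  z runs along the beamline with z = 0 at the phantom entrance,
x is the scanning/bending direction, y the slit-length direction; the
deflecting field points along +y.

The reference collimator has 15 slits of 0.4 × 45 mm², 65 mm thick,
4 mm center-to-center (ctc), with slit tilt 0.025 deg per mm of off-axis
distance pointing outward (matching the beam divergence); the converging
setups enlarge the ctc to 6 mm.  The phantom entrance sits 70 mm behind
the collimator; the dipole variant fills the first 50 mm of that gap.
The PBS spot grid is 31 × 17 with 3 mm vertical spacing and horizontal
spacing equal to the ctc.  The pencil-beam sigma at the collimator is not
published for this beamline; we default to 3.0 mm ("a few millimeters"),
exposed in `SpotGrid`.  A static multislit transmits each spot into every
slit with the Gaussian-integral weight; a dynamic aperture transmits each
spot only into its aligned slit.

## Magnetic optics

The no-field landing abscissa at the Bragg peak is the straight drift
x₂ = x₁ + (&Delta;z_coll + &Delta;z_air + R(E))·tan&theta;(x₁).  Field
optimization finds, per (slit, energy), the field that lands the
enlarged-ctc slit on the landing abscissa of its index-matched 4 mm-ctc
reference slit (root solve to 1 µm with Brent's method, bracket 0–10 T).

* **Dipole**: exit angle &phi; = &theta; − asin(&Delta;z_dip/r) with
  r = B&rho;/B the Larmor radius, then a straight drift.  The drift
  convention is selectable; the default ("remaining-air+range") covers the
  collimator and dipole at the slit tilt and the remaining air plus R(E)
  at the exit angle, which reduces exactly to the straight-drift equation
  at B = 0.  A thin-element ("range-only") and a mid-plane
  ("dipole-center") convention are available.
* **In-phantom field**: the proton slows down while bending, so the
  curvature grows along the track.  The central axis is integrated by
  classical RK4 in arc length: dx/ds = sin&alpha;, dz/ds = cos&alpha;,
  d&alpha;/ds = −B/B&rho;(E(s)), with E(s) from the residual range
  R(E₀) − s.  Default step 0.1 mm; a residual-range floor of 1 µm keeps
  the integrable end-of-range curvature singularity finite on the last
  step.  Halving the step moves the landing abscissa by well under 0.1 µm.
  The closed-form dipole kick agrees with vacuum RK4 tracking to better
  than 0.1% whenever the Larmor radius exceeds 20 dipole thicknesses.

The solved in-phantom fields are linear in the slit offset to better than
1% (the bend angle per unit field is fixed by the range and the rigidity
profile; the required deflection is linear in the offset).  They exceed
the published values by a systematic 4–7%, which is the expected
signature of a slightly different effective range–energy relation in the
original Monte Carlo engine; the energy *ratios* of the solved fields
match the published ratios to ~1%.  Bragg-peak retraction — the upstream
shift of the depth at which the path length reaches R — is ≤ 2 mm even
for the outermost 100 MeV minibeam and grows quadratically with the field.

## Dose engine

A beamlet-superposition engine stands in for Monte Carlo transport.  Each
(spot, slit) pair with nonzero transmission becomes a beamlet: its axis is
tilted by the slit and deflected by the field assigned to the **spot**
x-coordinate (the physical correlation at delivery time), so under a
static multislit the flux leaking from neighboring spots is deflected with
a non-optimized field — the origin of the minibeam broadening effect,
which the dynamic aperture removes by construction.  Spot columns beyond
the outermost slit keep the linear field-vs-offset correlation.

Depth dose is an analytical Bragg curve: power-law stopping
(R − z)^(1/p − 1) plus the standard fluence-loss term
(&beta; + &gamma;&beta;p)(R − z)^(1/p) with &beta; = 0.012 cm⁻¹,
&gamma; = 0.6, convolved numerically (0.1 mm bins, exact bin-averaging of
the integrable singularity) with a Gaussian combining range straggling
and machine energy spread.  The curve is shifted so its maximum sits
exactly at R(E): the optics places the Bragg peak at path length R, and
aligning the two models keeps landing positions and peak depths mutually
consistent.  Dose is parameterized by *path length*, so curved
trajectories retract the Bragg peak in z exactly as the trajectory
dictates.  Every delivered layer carries the machine energy spread of
&sigma;_E = 1.2 MeV (≈0.8% at 150 MeV), chosen to match the measured
distal-falloff widths (80–20% ≈ 4–5 mm at ~16 cm range) of clinical
cyclotron beamlines; clinical layers are not monoenergetic and treating
them as such sharpens the peaks unphysically.

The lateral profile is rect(slit width) ⊗ Gaussian(&sigma;(z)), with
&sigma;(z) from Fermi–Eyges accumulation of the Highland scattering power
added in quadrature to a source sigma (default 0.2 mm) and an initial
angular spread (default 2 mrad, the geometric acceptance scale of a
0.4 × 65 mm slit).  Far tails are evaluated through erfc so that deep
inter-minibeam valleys retain full relative precision instead of
cancelling to zero.  Dose is uniform over the slit length in y.  All dose
is relative; absolute calibration is out of scope.

Grids: the full lattice is the reference 0.1 × 2 × 1 mm voxel grid in a
100 × 100 × 300 mm phantom (15M voxels); the default "coarse" grid
(0.2 × 10 × 2 mm) computes a five-configuration comparison in seconds and
is what the test-suite and acceptance runs use.

## Metrics

PVDR at a depth is the dose on the central minibeam axis (interpolated at
x = 0 over a central 10 mm y-window) divided by the minimum dose strictly
between the central and the first off-axis minibeam peak, located per
slice because converging minibeams move with depth.  A vanished valley is
reported as infinite PVDR with a flag, not an exception.  Transverse
profiles are compared over the flat region where the *peak-top envelope*
of the reference profile is ≥ 95% of its maximum; the envelope
interpolates across per-period peak tops because a raw threshold on an
oscillatory profile would select only the peak cores.  In cross-
configuration comparisons both grids are first normalized by their
flat-region envelope mean at the Bragg-peak depth: the optimization
premise is identical dose at the Bragg-peak location, and different
collimation modes transmit different absolute fluence per slit (a static
multislit passes roughly twice the aligned-spot flux of a dynamic
aperture).

## SOBP optimization

The spread-out Bragg peak uses five layers at 150–166 MeV in 4 MeV steps
(individual peaks at ≈157–187 mm) and flattens the central-minibeam
peak-dose curve Dp(z) = &Sigma; wᵢ Dpᵢ(z) over the 157–187 mm window.
The fitness is the maximum dose error max(Dp) − min(Dp) over the window,
evaluated in the last-layer-normalized parameterization (the raw max−min
is degenerate under a global weight scale); the relative form divides by
the window mean and is the figure quoted in percent.  The GA is a
tournament-selection (k = 3), elitist (2) algorithm over log-weight
chromosomes with arithmetic crossover (rate 0.9) and Gaussian mutation
(rate 0.2, scale 0.1 annealed geometrically to 1% over the run);
population 60, 300 generations, mandatory seed.  On the five-layer
analytic library the GA reproduces an independent Nelder–Mead optimum to
five digits; the optimum itself (≈2.9% relative max error) is a property
of the curve model, dominated by the ripple of 7.5 mm peak spacing against
the broadened peak width.  Optimizing against converged-pattern
(in-phantom-field, dynamic-aperture) engine libraries yields larger
normalized low-energy weights than against the no-field reference — the
converging higher-energy layers contribute less dose near the start of
the SOBP — reproducing the reported re-weighting direction.

## Synthetic fixtures

The generators in `minibeams.synth` build inputs with known answers:
cosine-modulated grids whose PVDR is exact by construction (on a lattice
with voxel centers on the extrema), a two-triangle library cheap enough
for exhaustive grid-search oracles, a "planted-flat" library whose last
curve is constructed so a known weight vector gives an exactly flat
plateau (its bumps are deliberately narrow and well separated — with wide
overlapping curves the planted weights are not identifiable from a
flatness objective), and degenerate single-slit / zero-tilt scenarios.

## What passing tests do and do not show

The engine contains no collimator scatter, nuclear halo, slit-edge
effects or secondary particles.  Consequences:

* Absolute PVDR values are far above measurable ones wherever valleys are
  tail-dominated; at the phantom entrance the engine's inter-minibeam
  valleys hold only Gaussian-tail dose (~10⁻³⁰ of peak), so the *increase*
  of entrance PVDR under convergence is reproduced in sign but its
  magnitude is astronomically larger than the ~50% a scatter-complete
  simulation reports.  Published absolute PVDR tables and absolute SOBP
  weight tables are therefore not reproduction targets; orderings,
  ratios at depths where scattering fills the valleys, and flatness
  bounds are.
* Dipole-configuration absolute field strengths depend on drift
  geometry conventions the published description leaves open; the
  in-phantom configuration has no such ambiguity and is reproduced
  quantitatively, the dipole configuration qualitatively (linearity in
  offset, decrease with energy).

## Numerical choices and degenerate inputs

Brent bracket 0–10 T with overdriven trajectories reporting their lateral
exit abscissa (keeps the bracketing function continuous and monotone);
landing tolerance 1 µm; unsolvable rows of a field table carry NaN and the
error list travels in `DataFrame.attrs`.  Beamlets with transmission below
10⁻⁵ are dropped.  Empty energy lists produce empty tables; uniform dose
grids give PVDR exactly 1; a spot beyond every slit transmits nothing in
dynamic mode.  Problem sizes in routine runs: 0.1 mm RK4 steps (~770 steps
per 100 MeV trajectory), coarse 750k-voxel grids, GA 60 × 300 = 18 000
evaluations — each full acceptance run completes in a few seconds.
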