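# Methods

## The physical model

A syconoid (ascon-like) sponge flagellated chamber pumps water through
small wall pores (ostia) and filters it through the microvillar collars of
its choanocytes, without any physical seal ("gasket") between collar tips.
The package models the periodic repeating unit of such a chamber: one
central ostium surrounded by a 5 x 5 lattice of choanocytes (24 collars
and flagella, 5 um pitch; the central lattice site is the ostium).  The
cylindrical chamber wall (85 um chamber diameter) is flattened into the
floor of a rectangular unit cell; curvature is a second-order effect at
one-pore scale.

At these scales (lengths of microns, beat frequency 30 Hz, water) the
Reynolds number is ~1e-3 and the oscillatory Womersley parameter is far
below one, so the flow at each instant of the beat is the steady Stokes
solution for the instantaneous geometry and surface velocities
("quasi-steady" stepping through the beat period).  Linearity of Stokes
flow underlies the pump-characteristic framework (below) and is verified
by the solver's superposition and velocity-scaling tests.

### Geometry (reference configuration, all lengths in um)

| element | value |
| --- | --- |
| ostium diameter / length | 7.0 / 3.0 |
| collar diameter / length | 2.5 / 4.8 |
| microvillus diameter / clear gap | 0.1 / 0.05 |
| flagella spacing | 5.0 |
| choanocytes per ostium | 24 |
| flagellum length | 15.7 |

The flagellum length is not an observable we could fix independently; it
is chosen so that the increased-amplitude beat (below) peaks at exactly
2 um at the tip.

### Beat kinematics

Each flagellum is a thin sheet (flagellum plus vane of width W) beating in
a vertical plane with a base-to-tip traveling wave

    d(s, t) = a (1 - exp(-(s/delta)^2)) sin(2 pi (s/lambda - f t) + phi).

Base case: lambda = 5 um, a = 1 um, delta = 1 um, f = 30 Hz, W = 0.7 um,
all 24 flagella in phase in a common plane.  The amplitude-modulated beat
takes the envelope as the pointwise maximum of the base profile and the
(a = 5 um, delta = 22 um) profile: the amplitude inside the collar keeps
its base value (the collar physically limits it) while the waveform grows
to a 2 um peak at the tip.  This composite form is a model decision the
single saturating profile cannot replace: used alone, (a=5, delta=22)
would *reduce* the confined amplitude four-fold and collapse filtration
and power, contradicting every reported effect of the modulation.

The displacement is applied transverse to the collar axis as a function
of height (the prescribed-motion convention of morphing-mesh solvers), so
the tip stays at a fixed height and the sheet velocity is the exact
analytic time derivative of the waveform.  The centerline stretches only
a little over the cycle (~1.6% for the base beat, ~3.4% for the
amplitude-modulated one, asserted in the suite): the traveling wave moves
the steep portions along the flagellum with little change of integrated
arclength.  A strictly inextensible (arclength) parameterization was
tried and rejected: it compresses the steep tip region of the modulated
beat into a near-zigzag block whose simulated pumping reverses.

The functional form above and the flagellum length are declared model
choices: they are consistent with the base-case amplitude of ~1 um over
most of the flagellum and the 2 um tip peak of the increased-amplitude
beat, which are the constraints we have.

### Porous collars

The collar wall is a ring of parallel microvilli; homogenized, it is a
Brinkman layer whose resistance derives from the classical problem of
Stokes flow normal to an infinite row of equal, equally spaced cylinders.
The drag per unit cylinder length is computed by the method of fundamental
solutions with closed-form periodic Stokeslet-row kernels (`grating.py`);
the method converges exponentially and reproduces the classical dilute
small-t expansion (t = 2 pi a / b) exactly in its validity range.  At the
microvillar density (gap/diameter = 0.5) the dilute expansion itself is
out of range - its error is tens of percent - which is why the full
solution is used.  An independent finite-difference Stokes solve of the
same configuration cross-checks the drag within 10% over gap/diameter
0.25-2 in the test suite.

The resulting Darcy coefficient (pressure drop = alpha * U * wall
thickness) is alpha ~ 10.2 Pa s/um^2 at the reference spacing; on the
grid the one-cell-thick shell carries alpha * d_mv / h so the integrated
wall resistance is preserved.  An optional base-to-tip gap profile
(wider at the base) interpolates the gap linearly in height.

## The flow solver

Uniform staggered (MAC) grid, periodic in all three directions.  The
vertical period closes the flow loop chamber core -> return plenum ->
ostium -> chamber, standing in for the uniform-pressure inlet and core
boundaries of an open domain: plenum and core are wide open, so pressure
is uniform there to discretization accuracy, and the loop's own hydraulic
resistance is two orders of magnitude below the ostium's.  A back-pressure
load is imposed as a uniform vertical body-force layer spanning the plenum
cross-section; integrating the momentum equation once around the loop
shows the pressure drop across that layer is exactly the integrated force.

Rigid surfaces (chamber wall, ostium tube, optional gasket baffle) are
stair-step rasterized: a face unknown is eliminated when its center lies
inside the solid grown by 0.35 h.  The growth margin is a wall-placement
convention: no-slip enforced at constrained face centers puts the
hydrodynamic surface about half a spacing outside them, and the margin was
fixed once against the Poiseuille closed form (<1% flux bias at D/16)
and then cross-checked on the independent cylinder-row oracle.

The beating sheets are immersed-boundary constraints: the vane
cross-section at each arclength station is sampled laterally and
aggregated into chunks of about one grid spacing; each chunk is one
constraint row (mean of trilinear interpolation rows) tied to the sheet
velocity through a Lagrange multiplier, with a Tikhonov compliance of
1e-3 h^2/mu.  Sub-grid vane widths therefore enter smoothly through the
sample positions.  The compliance trades constraint sharpness against
Krylov conditioning; it leaves an rms velocity slip on the sheets
(asserted below 20% of the target rms at the coarse profile in the
suite), which biases absolute pumping rates low but largely cancels in
the ratios between cases.  The Brinkman term is
likewise written as a regularized constraint (compliance 1/alpha per
face), which keeps the velocity operator an exact constant-coefficient
Laplacian.

The saddle system (momentum + incompressibility + constraints) is
augmented with a grad-div term gamma * G G^T u (gamma = 30 mu; it
vanishes at the divergence-free solution) and solved by LGMRES with an
exact FFT inverse of the constant-coefficient periodic Stokes(+grad-div)
operator as the (u, p) preconditioner, a per-flagellum dense block
preconditioner (regularized-Stokeslet mobility kernel) for the sheet
multipliers, and diagonal scaling for the Brinkman multipliers.
Convergence is verified on the true residual (default 1e-6 relative,
within the quasi-steady contract); non-convergence raises with the
residual attached.

For in-phase beating in a common plane, the chamber at phase t + T/2 is
the mirror image of phase t through the vertical mid-plane, so only half
the beat phases are solved and the rest are generated by mirroring.

### Functionals

* Q_ost: inward flux through the ostium mouth disk, phase-averaged.
* Q_col: upward flux out of the 24 collar interiors at collar-tip height
  (equals the flux through the porous walls, since the collar base is
  sealed by the chamber wall), phase-averaged.
* P_flagella: rate of work of the sheet constraint forces on free fluid
  faces.  At zero back-pressure this matches the total viscous + Brinkman
  dissipation to <5% (energy-balance self-check in the suite; the match
  is numerically exact up to the compliance slip).
* Stagnation height: first sign change of the mean vertical velocity on
  the vertical line through the ostium center - the hydrodynamic gasket.

### Problem sizes

Three profiles (our own, chosen for desk-scale runs on one CPU): coarse
h = 1.0 um (25 x 26 x 25 cells; used by the test suite and the acceptance
script), standard h = 0.625 um (40 x 42 x 40; used for the quantitative
study runs), fine h = 0.5 um for convergence checks.  8 phases per beat
period (4 solved, 4 mirrored).  The production values cited in the
original study were obtained with a body-fitted finite-volume solver at
much higher resolution; agreement of absolute rates at our reduced
resolutions is expected only at the tens-of-percent level, while
percent-change comparisons between paired cases benefit from cancelation
of the shared discretization bias.

## Pump characteristic framework

A basic pumping unit (ostium-of-zero-length + 24 choanocytes) has the
linear characteristic P_hat = 1 - Q_hat; the ostium tube is the system
resistance R_ost = 128 mu L/(pi D^4) (5.09e-5 Pa s/um^3 for the reference
ostium).  The unit is characterized by simulating three adverse loads
(0, P_est/2, P_est with P_est = 0.06 Pa a priori) and fitting the line;
R^2 > 0.999 is enforced, and the operating point follows as
Q_hat = 1/(1 + R_ost/C_pump).

## Tracer transport

Passive point prey enter across the ostium mouth (flux-weighted seeding
by rejection sampling, or uniform seeding with flux weights - the two
estimators agree within Monte-Carlo error) and are advected by RK4
(dt = T/200) with trilinear spatial and periodic linear temporal
interpolation of the phase fields.  A particle within one grid cell of a
collar shell counts as having encountered the filter and is removed;
crossing the exit plane above the flagellar tips counts as bypass.
Prey are non-diffusive over the ~ms transit (large Peclet number).

## Experimental statistics

Dye-speed flux: jet speed = replicate mean of distance/time (10-20 mm
front travel), flow = speed x osculum area (plug flow).  Cytometry
concentrations are bead-calibrated (analyzed volume = bead count / stock
concentration); retention per prey class is 100 (Cin - Cex)/Cin,
negative values preserved.  Box summaries use linear-interpolation
("type 7") quartiles - a convention that had to be fixed, as none is
stated for the reference results - and whiskers extend to the most
extreme data points within 1.5 IQR of the quartiles.  The headline
"mean +/- 6%" could be a standard error or a standard deviation; both are
reported.

## Synthetic data generator

The generator emulates the paired In-Ex experiment on 10 sponges: latent
per-sponge retention (Normal, truncated at 100%; defaults Euk 98%, HNA
98%, LNA 60%, 6% between-sponge sd), log-normal ambient concentrations
(cv 0.3; Euk 10, HNA 400, LNA 600 cells/uL - typical coastal seawater
scales), Poisson event counts in a 50 uL analyzed volume with a Poisson
bead spike (50 beads/uL stock), and a 1-event Poisson contamination floor
in exhaled samples so a perfectly retaining sponge never yields exactly
100% by construction.  Dye-speed defaults (1 mm/s jet, 0.46 mm^2 osculum,
400k ostia) put the per-ostium rate near 1150 um^3/s.  The noise model is
our own minimal standard choice for cytometry counts; the real experiment
adds gating uncertainty, instrument drift and class misassignment that
the generator does not emulate, so passing recovery tests demonstrates
the correctness of the estimator arithmetic, not field-data robustness.
All draws derive from one seed; identical configs give byte-identical
tables.

## Known limitations

* Stair-step rigid walls and chunk-aggregated sheets are first-order
  accurate; absolute rates at the test profiles carry tens-of-percent
  discretization bias (the reproduction contract is correspondingly
  loose, and ratios are the more trustworthy outputs).
* The sheet compliance leaves a ~10% velocity slip at the default
  profile, biasing pumping rates low.
* The periodic flow loop replaces the open chamber core; headroom above
  the flagellar tips is finite (4 um by default).
* No fluid-structure interaction: the beat is prescribed, and vane
  bending under load (relevant to high-pressure leucon pumps) is out of
  scope, as is the non-linear leucon characteristic.
* Collar capture is purely geometric encounter; no adhesion or
  size-dependent sieving.
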