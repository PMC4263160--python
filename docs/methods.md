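# Methods

## The model

Field-polarized ellipsoidal colloids are reduced to hard prolate spheroids of
revolution (short semi-axis `R`, long semi-axis `a = rho R`) whose long axes
are all pinned along the field direction `+z`; orientation is not a degree of
freedom.  The field-induced polarization of one particle is represented by
two opposite point charges at `(0, 0, +/-d)` from the centre.  The offset

    d = R sqrt(3 (rho^2 - 1) / 5)

makes the pair reproduce both the dipole and the octupole moment of a
uniformly polarized spheroid.  The derivation uses the classical equivalence
of a uniformly polarized spheroid (outside its surface) to a focal-segment
line density of dipoles `mu(z) ~ 1 - z^2/c^2`, `|z| <= c = sqrt(a^2 - R^2)`:
its axial multipoles are `p1 = int mu dz` and `p3 = 3 int mu z^2 dz`, with
`p3/p1 = (3/5) c^2`, while a charge pair gives `p3/p1 = d^2`.  The geometry
module carries both the discrete potential and the quadrature of the exact
one, so the representation is validated inside the test suite rather than
assumed.

All lengths are in units of `R` and energies in units of `k_B T`.  The
interaction energy is

    U* = Gamma * sum over inter-particle site pairs of Z_i Z_j / r*_ij,

with `r* = r / 2R` (distance relative to the side-by-side contact distance,
the minimum centre-to-centre distance of parallel spheroids) and
`Z = +/- 1`.  The single coupling knob `Gamma = q^2 / (8 pi eps_m R k_B T)`
absorbs the charge magnitude and medium permittivity.  The medium cannot
follow the driven polarization, so no electrolyte screening enters.
Intra-particle site pairs are a constant and are excluded everywhere.

The `point_dipole` interaction mode replaces the charge pair by an ideal
z-dipole of the same moment `2 q d` at the particle centre.  It is the
negative control: with it the simulations form the familiar dipolar strings
but never sheets or tubes, which isolates the role of the higher multipoles
(the separated poles) in the tubular self-assembly.

## Electrostatics and Ewald conventions

Finite aggregates (the lattice calculations) use direct pairwise sums.
Periodic systems use Ewald summation with:

* conducting ("tinfoil") boundary, no surface dipole term;
* minimum image applied per site pair, orthorhombic boxes;
* the intra-particle pair excluded via the standard `erf` correction;
* parameters from a single accuracy target `eps` (default `1e-5`):
  `s = sqrt(ln 1/eps)`, real-space cutoff `r_c = min(L)/2`, splitting
  parameter `alpha = s / r_c`, reciprocal cutoff `k_c = 2 alpha s`.

Because every particle carries the same site structure along z, the
reciprocal sum needs only the centre structure factor
`T(k) = sum_i exp(i k . c_i)`; the site form factor enters as a weight
`4 sin^2(k_z d)` (charge pairs) or `(2d)^2 k_z^2` (ideal dipoles).  The
Monte Carlo kernel updates `T(k)` incrementally per accepted move and
refreshes it from scratch at every snapshot, so floating-point drift never
accumulates; the cached running energy is required (and tested) to track a
from-scratch recomputation to 1e-6 relative.

The tinfoil choice is a convention decision: the original lattice-sum
boundary condition is not documented.  The test suite pins the
implementation to an independent cubic-shell image-sum oracle, Richardson
extrapolated, after adding the analytic `2 pi M^2 / 3V` vacuum-to-tinfoil
offset.

## Monte Carlo protocol

Strictly single-particle translations: a trial displacement uniform in a
cube of half-width one particle radius `R` (the displacement parameter;
configurable), hard-core overlap test first, then Metropolis acceptance
`min(1, exp(-dU*))`.  One cycle is N attempted moves.  The overlap test for
identical parallel spheroids is exact and cheap: the affine map `z -> z/rho`
sends both particles to spheres of radius `R`, so overlap reduces to
`dx^2 + dy^2 + (dz/rho)^2 < (2R)^2`.

Runs are bit-reproducible given the seed.  The reference systems are

* 384 particles, `rho = 2.7`, volume fraction `phi ~ 0.06`, `Gamma` in
  [0, 10]: compact aggregates appear with increasing coupling, then ordered
  sheets that span the box in two directions; hollow fibres do not form;
* 36 particles at `phi = 0.015` (box too small in xy for a spanning sheet,
  so aggregate size is effectively finite): at `Gamma = 9.8` runs converge
  to a single hollow fibre spanning the box along z.

Full-fidelity runs are 1e7 cycles.  The test suite runs scaled-down
versions (4e3-4.8e5 cycles, and 128 particles where the full system has
384); at that budget aggregation and z-spanning fibre formation are robust
(every strong-coupling seed ends in one or two spanning aggregates), but
tube-wall annealing is not always complete: interior defect particles
persist in many seeds, so only a minority of a ten-seed batch (2-6 of 10,
depending on the run schedule) classify as defect-free hollow tubes, where
1e7-cycle runs converge fully.  Likewise the 128-particle box is too small
for the two-axis spanning monolayer sheet (it would need ~70% of all
particles in one plane), so the strong-coupling state there is a single
z-spanning ordered aggregate rather than a sheet label.  Green scaled tests
establish the onset and ordering of the morphologies, not full convergence
of every seed.

An energy-plateau runner (`run_until_plateau`) advances in chunks and stops
when consecutive chunk-mean energies per particle agree within a tolerance
(default 0.05 kT); it picks the scaled cycle count adaptively instead of
hard-coding one.

## Morphology classification

The original morphologies were identified visually; the quantitative
classifier here is an artifact design, with thresholds exposed:

1. contact graph: edge when the contact function is within `(1+delta)^2`,
   default `delta = 0.2`; labels are required (and tested) to be stable for
   `delta` in [0.1, 0.3];
2. cluster spanning by breadth-first unwrapping under minimum image: a
   cluster spans an axis when it reconnects to its own periodic image;
3. cascade: no spanning and largest cluster < 50% -> fluid; spanning two
   axes -> sheet; spanning z only -> string if the mean z-slab occupancy is
   <= 2.5 particles, tube if at least 70% of slabs form closed
   (largest angular gap <= pi), hollow (minimum radius > 0.5 x mean ring
   radius) rings of >= 4 particles; everything else -> compact, with
   diagnostics attached.

Slabs have thickness `2 rho R` (the tightest within-column period); the
cluster axis is a straight line `x(z), y(z)` least-squares fitted to the
unwrapped coordinates, which tolerates overall tilt or shear of a fibre
while still rejecting filled rods.  Ring counts are reported per occupied
slab; for ideal even-`n_x` tube fixtures they equal `n_x` exactly.

One geometric caveat: odd-`n_x` ideal tubes carry an in-register seam whose
minimal-radius construction leaves adjacent columns at a contact-function
value of about 1.25, so they only cohere into one cluster for
`delta >~ 0.12`; the robustness tests use `delta >= 0.15` for odd fixtures.

## Sheet and tube lattices

Sheets are centred rectangular lattices: `n_x` columns, `n_z` particles per
column at period `l_z`, alternate columns shifted by `l_z/2`.  Because the
energy is purely electrostatic over hard particles, its minimum sits on the
contact boundary (no interior stationary point exists), so the column
spacing is slaved to `l_z` by the diagonal contact condition
`l_x^2 + (l_z / 2 rho)^2 = (2R)^2`, leaving a single free parameter.  The
feasible range is `l_z in [2 rho R, 2 sqrt(3) rho R]` for a sheet (the upper
bound from second-neighbour columns reaching side-by-side contact).

Tubes wrap the same column structure on a cylinder at angular spacing
`2 pi / n_x`.  The design choice made here: the cylinder radius is the
*smallest overlap-free* radius.  Where the adjacent-column chord condition
is feasible it binds and `r_c = l_x / (2 sin(pi/n_x))` with adjacent columns
exactly at contact; at strong curvature (small `n_x`, large `l_z`) the
in-register second-neighbour columns would interpenetrate first, and the
radius inflates minimally so that pair carries the contact instead.  The
same rule produces the single in-register seam of odd `n_x`.  An
alternating-ring wrap is used throughout; helical wraps were evaluated and
are never lower in energy for this interaction.

The 1D minimization over `l_z` is a dense scan plus bounded refinement
(tolerance 1e-6 R) with explicit endpoint checks, since the contact bound
itself is frequently the minimizer.  Energies are reported per particle and
relative to the dimer reference: the global two-particle contact minimum, a
staggered side-by-side pair at `dz ~ 4.65 R` with energy `-0.964 Gamma`
(total), which beats the head-to-tail pair (`-0.795 Gamma`).

For the energy maps over `10 <= n_z <= 70`, `4 <= n_x <= 24`, the direct sum
exploits the column structure (z-offsets take `2 n_z - 1` values with known
multiplicities), reducing the cost per evaluation from `O((n_x n_z)^2)` to
`O(n_x^2 n_z)`; the fast path is pinned to the brute-force direct sum in the
tests.

What the computed maps show in this implementation: both kinds decrease
monotonically in `n_z`; the tube approaches the sheet from below as `n_x`
grows (the difference decays like the eliminated z-edge cost, ~1/n_x); the
tube is cheaper than the sheet over most of the grid because closing the
cylinder removes the two z-edges.  At the smallest widths (`n_x = 4`) the
hard core caps the feasible `l_z` of the tube (opposite columns touch)
before the staggered optimum is reached, and there the sheet wins instead.
The resulting sign structure of `E_tube - E_sheet` is therefore not a
diagonal boundary: it is positive only in the narrow strong-curvature
column, and everywhere else negative with magnitude below ~0.09 per
particle, shrinking as `n_x` grows.

## Known limitations

* Monodisperse, perfectly aligned particles only; no rotational moves, no
  field-strength mapping, no electrolyte screening.
* The scaled-down Monte Carlo budgets (minutes, not hours) leave individual
  strong-coupling seeds short of full annealing; statements about "all
  seeds converge" hold only at full fidelity.
* Lattice energetics are athermal (energy minimization, no entropy); they
  rationalize, but do not predict, finite-temperature stability.
* Classification thresholds are artifact choices; near-threshold
  configurations (partially closed fibres) legitimately flip between
  `compact` and `tube` along a trajectory.
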