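# tubuloid

Coarse-grained simulation of tubular self-assembly of field-polarized
ellipsoidal colloids.

Prolate colloids aligned by an AC electric field assemble into strings,
ordered sheets and -- remarkably -- hollow single-walled tubes, a morphology
otherwise associated with highly specific interactions (virus shells,
microtubules).  This package implements a minimal model reproducing that
behaviour: hard parallel prolate spheroids (short semi-axis `R`, aspect
ratio `rho`) whose induced polarization is represented by two opposite point
charges at `z = +/-d` on the particle axis, with

    d = R sqrt(3 (rho^2 - 1) / 5)

chosen so the pair matches the dipole *and* octupole moments of a uniformly
polarized spheroid.  A single dimensionless coupling
`Gamma = q^2 / (8 pi eps_m R k_B T)` sets the interaction strength; the
reduced pair energy is `Gamma sum Z_i Z_j / (r_ij / 2R)` over inter-particle
charge sites.  An ideal-dipole mode of matched moment serves as the negative
control: it makes the familiar dipolar strings but never sheets or tubes,
showing that the separated poles (higher multipoles) drive the tubular
assembly.

The package provides, as library modules and a `tubuloid` CLI:

* `geometry` -- exact overlap/contact tests for parallel spheroids (affine
  map to spheres), the charge-pair construction, and the exact
  polarized-spheroid potential as a quadrature oracle;
* `electrostatics` -- direct site sums, Ewald summation (tinfoil boundary)
  with incremental move energies, and the ideal-dipole control;
* `mc` -- Metropolis Monte Carlo: single-particle translations, hard-core
  rejection, deterministic trajectories, extended-XYZ output;
* `morphology` -- contact-graph clustering with periodic spanning analysis
  and classification into fluid / string / compact / sheet / tube
  (including hollow-ring detection and per-ring particle counts);
* `lattice` -- constrained minimum-energy calculations for idealized sheet
  (centred rectangular) and tube (cylinder-wrapped) aggregates: a 1D
  minimization in the stacking period `l_z` with all other lattice
  parameters slaved to particle contact, energy maps over aggregate size
  `(n_z, n_x)` relative to the two-particle (dimer) minimum.

## Worked example

Energetics of the building blocks (coupling `Gamma = 1`, lengths in `R`):

    >>> from tubuloid import SpheroidShape, charge_pair, dimer_reference
    >>> shape = SpheroidShape(R=1.0, rho=2.7)
    >>> charge_pair(shape).d
    1.9426785632214096
    >>> ref = dimer_reference(shape)
    >>> round(ref.total, 4), round(ref.head_to_tail_total, 4), round(ref.dz, 3)
    (-0.9643, -0.7951, 4.651)

The minimum-energy two-particle configuration is *not* the head-to-tail
chain (-0.795 kT at Gamma=1) but a staggered side-by-side pair at an axial
offset of 4.65 R (-0.964 kT): the positive pole of one particle nests
between the poles of its neighbour.  This interweaving is what knits columns
into sheets, and the uncompensated charge on sheet edges is what closes
finite sheets into tubes.

A scaled-down simulation of the tube-forming state point (36 particles,
volume fraction 0.015, `Gamma = 9.8`; the full-fidelity runs use 1e7
cycles):

    tubuloid simulate --n 36 --rho 2.7 --phi 0.015 --gamma 9.8 \
        --cycles 150000 --seed 8 --out run_tube

prints the final-frame classification

    {"label": "tube", "spanning": ["z"], "ring_counts": [5, 5, 8, 7, 5, 6],
     "cluster_sizes": [36], "largest_fraction": 1.0}

a single hollow fibre spanning the box along the field, with 5-8 particles
per ring cross-section.  `run_tube/` holds the trajectory (extended XYZ),
the final frame and a JSON metadata record sufficient to replay the run
bit-for-bit.

Sheet/tube energy maps (per particle, relative to the dimer minimum):

    tubuloid minimize --n-z 10:70:10 --n-x 4:24:4 --out maps.csv

Other subcommands: `scan` (morphology table over a Gamma grid),
`classify` (label a stored configuration), `potential` (discrete vs exact
polarized-spheroid potential profiles).

## Acceptance script

    python scripts/acceptance.py --seed 1 --out results/acceptance.json

re-runs the package's main computations from scratch -- a scaled
strong-coupling Monte Carlo run of the 36-particle system with final-frame
classification, the dimer reference, and a coarse sheet/tube energy map --
and writes the results JSON to `--out` (progress and summaries go to
stderr).

## Notes

`docs/methods.md` documents the model assumptions, Ewald conventions,
classifier thresholds, the lattice constructions and the known limitations,
including exactly what the scaled-down test budgets do and do not
establish.
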