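# Methods

## The model

`crystalhabit` predicts crystal morphology with the attachment-energy (AE)
habit rule and its solvent-modified extension, applied here to calcium
minodronate, Ca(Min)₂ — a 0-D calcium bisphosphonate coordination compound
crystallizing in C2/c (a = 19.40 Å, b = 9.78 Å, c = 17.05 Å, β = 106.44°;
force-field-optimized cell a = 19.27 Å, b = 9.74 Å, c = 17.05 Å, β = 107.99°).

The rule: the relative growth rate of face (h k l) is proportional to the
magnitude of its attachment energy,

    R_hkl ∝ |E_att|,    E_att = E_latt − E_slice,

where E_latt is the per-cell lattice energy and E_slice the per-cell energy of
an isolated slice of thickness d_hkl. In solution, adsorption of solvent onto
a face costs energy on attachment; the modified rule subtracts the
crystal–solvent adhesion energy

    E_att′ = E_att − E_int,    E_int = E_tot − (E_cry + E_sol),
    R′_hkl ∝ |E_att′|.

Faster faces grow out of the habit; the morphology is the Wulff polyhedron
whose center-to-plane distance for each symmetry-expanded face is
proportional to its growth rate. Faces whose plane falls outside the
intersection carry zero area — for Ca(Min)₂ the (0 0 2) and (1 1 −1) forms
disappear in every organic–water solvent, leaving a three-form habit.

### Growth-rate column vs. attachment energies

For the bundled five-face table, distances proportional to |E_att|
(250.08, 266.26, 365.24, 284.40, 185.29 kcal/mol) reproduce the published
facet-area percentages essentially exactly (20.38 / 30.96 / 4.54 / 9.02 /
35.10 %). The library therefore always derives habit distances from the
energies via `growth_rates_from_energies` (the rule above); a direct
distance override exists for non-standard inputs.

## Module-by-module numerical choices

**Lattice geometry.** All metric quantities (volume, d-spacings, plane
normals) are computed from an explicitly constructed triclinic direct basis
(a along x, b in the xy plane) and its inverse-transpose reciprocal basis;
the monoclinic b-unique closed forms are special cases and are used only as
test oracles. Density is ρ = Z·M/(N_A·V); for Ca(Min)₂ the composition that
reproduces both published densities (1.65 and 1.69 g/cm³, ±0.02) is Z = 4
units of Ca(C₉H₁₁N₂O₇P₂)₂·5H₂O — one Ca²⁺, two singly deprotonated
minodronate anions, five waters — supplied as data, not hard-coded.
Ca–O contacts longer than the ionic-radius sum (1.21 + 1.00 = 2.21 Å) are
classified ionic (strictly greater than; the boundary falls on the
covalent/coordinate side).

**Form expansion.** The Laue class is derived from the space-group symbol
(C2/c → 2/m) via gemmi; orbits are generated by applying the point-group
part of a holohedral representative space group to (h k l) and always
include the Friedel mate. For the trigonal −3m class the −3m1 setting is
the default.

**Wulff construction.** The habit is the halfspace intersection
{x : x·n ≤ d} over all expanded planes, computed with Qhull
(`scipy.spatial.HalfspaceIntersection` seeded at the origin, which is
strictly interior whenever all distances are positive). Boundedness is
pre-checked by requiring the origin strictly inside the convex hull of the
unit normals; failure raises an explicit unbounded-habit error (e.g. a lone
monoclinic {2 0 0} form, whose two parallel planes bound a slab). Vertices
are merged at 1e-8 × max distance; duplicate planes generated by two forms
keep the closer one. Facet polygons are recovered per input plane
(vertices within tolerance of the supporting plane, ordered by angle about
the normal), so every facet is attributed to its generating form; absent
forms report exactly 0 % area. The side ratio of two forms defaults to the
scale-invariant √(mean single-facet area) quotient, with a max-in-plane-edge
alternative.

**Energetics.** Energies are 12-6 Lennard-Jones plus point-charge Coulomb
(332.0637 kcal·Å/mol·e²) with geometric-mean mixing (Lorentz–Berthelot
optional), a 15.5 Å van der Waals cutoff, direct-sum electrostatics for
clusters and minimum-image cutoff electrostatics for periodic toys. There
are no bonded terms: molecules are rigid and intramolecular pairs are
excluded by default. Reproducing the study's absolute kcal/mol face energies
is out of scope (those came from a commercial Dreiding/Ewald setup); the
algebra, signs and orderings are the testable surface. E_int is evaluated as
the crystal↔solvent cross-pair sum — identical, for a pairwise-additive
potential, to the defining subtraction E_tot − (E_cry + E_sol) but free of
summation-order round-off, so separations beyond the cutoff give exactly
zero; the subtraction identity is still asserted to 1e-9 on every
evaluation. The toy attachment energy sums lattice images within the cutoff
(a lattice translation (i j k) lies in layer h·i + k·j + l·k along the
normal), giving E_latt from all layers and E_slice from the slab's layers
only; it is exercised on single-site LJ crystals where an explicit slab–slab
sum is the oracle.

**Interface models.** Solvent layers are packed by seeded random sequential
insertion of rigid templates (water: 3-site, O–H 0.957 Å, H–O–H 104.5°,
q(O) = −0.72 e, q(H) = +0.36 e) with a 1.5 Å intermolecular floor and
in-plane minimum-image wrapping; the layer thickness is fixed analytically
by count·M/(N_A·ρ·A), so the realized density is exact by construction.
Interfaces stack slab → organic → water → vacuum (default 100 Å) along +z
with an organic/water volume ratio of 1/3 at equal cross-sections. Slabs are
cleaved keeping whole molecules whose centroids fall inside the depth window
(default 2·d_hkl) to avoid cut bonds; the surface normal is rotated to +z
and `surface_edge_z` is the maximum crystal-atom z. Surface roughness
S = A_acc/A_hkl integrates the upper envelope of probe-inflated vdW spheres
(probe default 1.0 Å, grid default 0.25 Å, periodic in-plane) by central
differences. The coarse-grid estimate approaches its converged value from
below (finite differences smooth the cusps), so convergence is checked by
shrinking refinement increments rather than one-sided monotonicity. For
finite clusters a Shrake–Rupley sampler provides the closed-form check
(isolated sphere → 4π(r+p)²).

**Density profiles.** Time-averaged per-role mass histograms over z bins
(default 0.5 Å, atoms binned at their centers), converted to g/cm³ with the
fixed cross-section; the default analysis window is the final quarter of the
frames, mirroring the usual equilibration/production split of the 500 ps
protocol (the protocol config carries the full set: 298.15 K NVT, NHL
thermostat, 1 fs steps, frames every 500 steps, first 250 ps equilibration,
last 125 ps analysis — the window stays configurable since the split leaves
a middle stretch unused). Peaks are interior local maxima above 10 % of the
global maximum, refined by 3-point parabolic interpolation at the apex bin
and returned tallest-first; plateaus report their center, and plateaus
touching the window boundary (flat or monotone profiles) are not peaks. The
overlap fraction integrates the role's mass below the crystal surface edge
with pro-rata handling of the straddling bin.

**Side-ratio statistics.** Per-solvent OLS (statsmodels) of side ratio vs
organic volume; ranking by ratio at a fixed volume with alphabetical,
flagged tie-breaks; correlations against relative permittivity, dipole
moment, density and carbon count reported as Spearman rank coefficients
(the claims are monotone, not linear) with Pearson alongside. With nine
solvents no significance is claimed by default; label-permutation p-values
are opt-in.

## The synthetic generators and what they do (not) show

The generators supply every input class with known ground truth: toy LJ /
rocksalt crystals (attachment-energy path), packed solvent boxes, layered
Gaussian interface trajectories (profile path), linear-plus-noise side-ratio
tables, and slab+adsorbate fixtures (interaction-energy signs). Defaults
follow the study conditions where stated: 500-water layers at 1.0 g/cm³,
organic/water 1/3, 100 Å vacuum, 15.5 Å cutoff, layer centers near the
22.3–24.4 Å band just outside a ~22.7 Å surface edge, side-ratio endpoints
0.78 (DEF) and 0.10 (MEF) at 250 μL with a common 0.05 intercept. Profile
fixtures use ~800 mass points per layer — a few hundred solvent molecules,
i.e. a realistic layer at these cross-sections. The generators emulate
geometry and statistics, not physics: layers are ideal Gaussians with
uncorrelated thermal jitter, solvent molecules are rigid and randomly
oriented rather than equilibrated, and toy crystals have single-site bases.
Passing tests therefore validate the analysis machinery (binning, peak
finding, energy algebra, habit geometry, regression), not the force field
or MD behavior of real Ca(Min)₂ interfaces.

## Known limitations

- No Ewald summation; periodic electrostatics use minimum-image cutoff sums,
  adequate for the neutral/weakly-charged toys exercised here.
- No bonded terms, thermostats or integrators: MD itself is out of scope;
  the package consumes trajectories.
- Hirshfeld surface analysis and promolecule densities are out of scope.
- Absolute attachment/interaction energies of the real crystal are not
  reproducible with the bundled generic LJ parameters; only printed energies
  (as inputs), signs, orderings and geometry are exercised.
- The accessible-area envelope counts the top surface only (one-sided S).
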