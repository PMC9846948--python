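# crystalhabit

Attachment-energy crystal habit prediction with solvent modification,
interface model building and interfacial density analysis — built around the
morphology of calcium minodronate (Ca(Min)₂), a calcium bisphosphonate
coordination compound whose crystal shape is steered by polar aprotic
co-solvents during aqueous crystallization.

## Who this is for

Crystal-engineering and molecular-modelling practitioners who want to go
from a unit cell and a table of per-face attachment energies to a predicted
morphology, quantify how a solvent reshapes it, and analyze the
crystal–solvent interface: the sort of workflow usually locked inside
commercial morphology tools, here as a tested, scriptable library with a CLI.

## The model

The growth rate of face (h k l) follows the attachment-energy rule

    R_hkl ∝ |E_att|,          E_att = E_latt − E_slice,

and in solution the modified rule

    R′_hkl ∝ |E_att′|,        E_att′ = E_att − E_int,
    E_int = E_tot − (E_cry + E_sol),

where E_int is the adhesion energy between a crystal face and its solvent
layer (negative when adsorption is favorable, so solvent slows growth).
The habit is the Wulff polyhedron with center-to-plane distances
proportional to the rates over all symmetry-equivalent faces (Laue class
2/m for space group C2/c); fast faces leave the polyhedron and are "absent".

The package covers, module by module: unit-cell geometry and d-spacings
(`lattice`), Laue form expansion and Wulff construction (`habit`), LJ +
Coulomb energetics and the AE algebra (`energetics`), layered
slab/organic/water/vacuum interface models and surface-roughness S ratios
(`interface`), trajectory mass-density profiles (`profiles`), side-ratio
regression and solvent-property correlations (`stats`), seeded synthetic
generators with ground truth (`synth`), and format I/O plus a typer CLI
(`io`, `cli`).

## Worked example

Predict the vacuum morphology of Ca(Min)₂ from its optimized cell
(a = 19.27 Å, b = 9.74 Å, c = 17.05 Å, β = 107.99°) and the bundled
five-face attachment-energy table:

```bash
$ crystalhabit habit --out-prefix camin
(2 0 0): 20.38%
(1 1 0): 30.96%
(0 0 2): 4.54%
(1 1 -1): 9.02%
(2 0 -2): 35.10%
```

The percentages are each form's share of the total habit surface: the
(2 0 −2) form, with the weakest attachment energy (−185.29 kcal/mol), grows
slowest and dominates the shape at 35.10 %, while the strongly-bound
(0 0 2) form (−365.24 kcal/mol) nearly grows out at 4.54 %. The command also
writes a facet-area CSV, a JSON habit report and an OBJ polyhedron.

The same quantities from Python:

```python
>>> from crystalhabit import MillerIndex, d_spacing, crystal_density
>>> from crystalhabit.data import optimized_cell, reported_cell, ca_min_composition
>>> round(d_spacing(optimized_cell(), MillerIndex(2, 0, 0)), 2)
9.16
>>> round(crystal_density(reported_cell(), ca_min_composition()), 2)
1.65
>>> round(crystal_density(optimized_cell(), ca_min_composition()), 2)
1.69
```

Solvent-modified habits use a face table with an `e_int` column
(`crystalhabit habit-solvent faces.csv`); inflating the (0 0 2) and
(1 1 −1) rates this way removes both forms from the habit, matching the
three-face morphologies grown from organic–water mixtures. Other
subcommands: `dspacing`, `build-interface`, `s-ratio`, `profile`,
`fit-sideratio`, `correlate`, `synth` (see `--help`).

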