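"""Non-bonded energy kernels and the attachment-energy algebra."""

import math

import numpy as np
import pytest

from crystalhabit.energetics import (
    COULOMB_CONSTANT,
    AtomSite,
    EnergyBreakdown,
    ForceFieldParams,
    MolecularSystem,
    attachment_energy_toy,
    interaction_energy,
    modified_attachment_energy,
    nonbonded_energy,
)
from crystalhabit.lattice import MillerIndex, UnitCell
from crystalhabit.synth import adsorption_config, toy_crystal


def pair_system(r, element="X", charges=(0.0, 0.0)):
    return MolecularSystem(
        [
            AtomSite(element, 1.0, charges[0], (0.0, 0.0, 0.0), molecule_id=0),
            AtomSite(element, 1.0, charges[1], (r, 0.0, 0.0), molecule_id=1),
        ]
    )


def naive_energy(system, params, exclude_intramolecular=True):
    """Double-loop oracle over all pairs (finite clusters only)."""
    total = 0.0
    atoms = system.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if exclude_intramolecular and atoms[i].molecule_id == atoms[j].molecule_id:
                continue
            r = math.dist(atoms[i].position, atoms[j].position)
            eps = math.sqrt(params.epsilon[atoms[i].element] * params.epsilon[atoms[j].element])
            if params.mixing_rule == "geometric":
                sig = math.sqrt(params.sigma[atoms[i].element] * params.sigma[atoms[j].element])
            else:
                sig = 0.5 * (params.sigma[atoms[i].element] + params.sigma[atoms[j].element])
            if r <= params.vdw_cutoff:
                sr6 = (sig / r) ** 6
                total += 4 * eps * (sr6 * sr6 - sr6)
            if params.coulomb_method == "direct_sum" or r <= params.vdw_cutoff:
                total += params.coulomb_constant * atoms[i].charge * atoms[j].charge / r
    return total


class TestNonbondedEnergy:
    def test_lj_zero_crossing(self, lj_params):
        assert nonbonded_energy(pair_system(3.0), lj_params) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        params = ForceFieldParams(epsilon={"X": 0.5}, sigma={"X": 3.0})
        sys = pair_system(3.0 * 2 ** (1 / 6))
        assert nonbonded_energy(sys, params) == pytest.approx(-0.5, rel=1e-12)

    def test_coulomb_direct_sum(self):
        params = ForceFieldParams(epsilon={"X": 0.0}, sigma={"X": 1.0})
        sys = pair_system(2.0, charges=(1.0, -1.0))
        assert nonbonded_energy(sys, params) == pytest.approx(-COULOMB_CONSTANT / 2.0, rel=1e-12)

    @pytest.mark.parametrize("mixing", ["geometric", "lorentz-berthelot"])
    def test_random_clusters_match_double_loop_oracle(self, rng, mixing):
        params = ForceFieldParams(
            epsilon={"A": 0.2, "B": 0.45},
            sigma={"A": 2.8, "B": 3.3},
            mixing_rule=mixing,
            vdw_cutoff=9.0,
        )
        for _ in range(20):
            n = int(rng.integers(5, 31))
            atoms = []
            for i in range(n):
                atoms.append(
                    AtomSite(
                        "A" if rng.uniform() < 0.5 else "B",
                        1.0,
                        float(rng.uniform(-0.3, 0.3)),
                        tuple(rng.uniform(0, 12, 3)),
                        molecule_id=int(rng.integers(0, 6)),
                    )
                )
            sys = MolecularSystem(atoms)
            try:
                fast = nonbonded_energy(sys, params)
            except ValueError:
                continue  # overlapping random atoms
            assert fast == pytest.approx(naive_energy(sys, params), rel=1e-12, abs=1e-12)

    def test_translation_rotation_invariance(self, rng, lj_params):
        atoms = [
            AtomSite("X", 1.0, float(q), tuple(p), molecule_id=i)
            for i, (q, p) in enumerate(zip(rng.uniform(-0.2, 0.2, 8), rng.uniform(0, 6, (8, 3))))
        ]
        sys = MolecularSystem(atoms)
        e0 = nonbonded_energy(sys, lj_params)
        # translate
        assert nonbonded_energy(sys.translated([5.0, -3.0, 11.0]), lj_params) == pytest.approx(
            e0, abs=1e-9
        )
        # rotate
        th = 0.7
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        rotated = MolecularSystem(
            [
                AtomSite(a.element, a.mass, a.charge, tuple(rot @ np.asarray(a.position)),
                         molecule_id=a.molecule_id)
                for a in atoms
            ]
        )
        assert nonbonded_energy(rotated, lj_params) == pytest.approx(e0, abs=1e-9)

    def test_order_independence(self, rng, lj_params):
        atoms = [
            AtomSite("X", 1.0, 0.1, tuple(p), molecule_id=i)
            for i, p in enumerate(rng.uniform(0, 8, (10, 3)))
        ]
        e1 = nonbonded_energy(MolecularSystem(atoms), lj_params)
        perm = list(rng.permutation(len(atoms)))
        e2 = nonbonded_energy(MolecularSystem([atoms[i] for i in perm]), lj_params)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_missing_element_parameters(self, lj_params):
        sys = pair_system(3.0, element="Zz")
        with pytest.raises(KeyError, match="Zz"):
            nonbonded_energy(sys, lj_params)

    def test_overlapping_atoms_rejected(self, lj_params):
        with pytest.raises(ValueError, match="overlap"):
            nonbonded_energy(pair_system(1e-9), lj_params)

    def test_cutoff_monotone_on_attractive_tail(self):
        """Enlarging the cutoff only deepens a purely attractive LJ tail sum."""
        positions = [(0.0, 0.0, 0.0)] + [(4.0 + 3.5 * i, 0.0, 0.0) for i in range(15)]
        atoms = [AtomSite("X", 1.0, 0.0, p, molecule_id=i) for i, p in enumerate(positions)]
        sys = MolecularSystem(atoms)
        prev = 0.0
        for cutoff in (5.0, 8.0, 12.0, 16.0):
            params = ForceFieldParams(epsilon={"X": 0.3}, sigma={"X": 3.0}, vdw_cutoff=cutoff)
            e = nonbonded_energy(sys, params)
            assert e <= prev + 1e-12
            prev = e


class TestInteractionEnergy:
    def test_breakdown_identity(self, rng, lj_params):
        sys = adsorption_config(separation=3.0, adsorbate_count=5, seed=3)
        bd = interaction_energy(sys, lj_params)
        assert bd.e_int == pytest.approx(bd.e_tot - bd.e_cry - bd.e_sol, abs=1e-9)

    def test_zero_beyond_cutoff(self, lj_params):
        sys = adsorption_config(separation=20.0, adsorbate_count=4, seed=1)
        bd = interaction_energy(sys, lj_params)
        assert bd.e_int == 0.0

    def test_single_pair_analytic(self):
        params = ForceFieldParams(epsilon={"X": 0.2}, sigma={"X": 3.0}, vdw_cutoff=15.5)
        sys = MolecularSystem(
            [
                AtomSite("X", 1.0, 0.0, (0, 0, 0), molecule_id=0, role="crystal"),
                AtomSite("X", 1.0, 0.0, (0, 0, 3.0 * 2 ** (1 / 6)), molecule_id=1, role="water"),
            ]
        )
        bd = interaction_energy(sys, params)
        assert bd.e_int == pytest.approx(-0.2, rel=1e-12)

    def test_adsorbed_layer_is_attractive(self, lj_params):
        sys = adsorption_config(separation=3.2, adsorbate_count=8, seed=2)
        bd = interaction_energy(sys, lj_params)
        assert bd.e_int < 0

    def test_missing_roles_rejected(self, lj_params):
        sys = MolecularSystem([AtomSite("X", 1, 0, (0, 0, 0), role="crystal")])
        with pytest.raises(ValueError, match="organic"):
            interaction_energy(sys, lj_params)


class TestModifiedAttachmentEnergy:
    def test_identity_at_zero_interaction(self):
        assert modified_attachment_energy(-250.08, 0.0) == pytest.approx(-250.08)

    def test_arithmetic(self):
        assert modified_attachment_energy(-250.08, -50.0, area_scale=1.0) == pytest.approx(-200.08)

    def test_solvent_inhibits_growth(self, rng):
        """Negative E_int with |scale·E_int| < |E_att| always shrinks |E_att′|."""
        for _ in range(100):
            e_att = -float(rng.uniform(50, 400))
            e_int = -float(rng.uniform(0, 0.9)) * abs(e_att)
            e_prime = modified_attachment_energy(e_att, e_int)
            assert abs(e_prime) < abs(e_att)
            assert e_prime < 0

    def test_positive_e_att_rejected(self):
        with pytest.raises(ValueError):
            modified_attachment_energy(10.0, 0.0)


class TestAttachmentEnergyToy:
    CUT = 7.0
    A = 3.0

    def params(self):
        return ForceFieldParams(
            epsilon={"X": 0.3}, sigma={"X": 2.8}, vdw_cutoff=self.CUT,
            coulomb_method="minimum_image_cutoff",
        )

    def crystal(self):
        return toy_crystal("cubic", a=self.A, basis="single_lj")

    def test_slab_slab_oracle_100(self):
        """E_att equals the explicit sum over one slice against all slices below."""
        crystal, cell = self.crystal()
        bd = attachment_energy_toy(crystal, MillerIndex(1, 0, 0), cell, self.params())

        def lj(r):
            if r > self.CUT:
                return 0.0
            sr6 = (2.8 / r) ** 6
            return 4 * 0.3 * (sr6 * sr6 - sr6)

        oracle = 0.0
        reach = int(self.CUT / self.A) + 2
        for i in range(-reach, 0):
            for j in range(-reach, reach + 1):
                for k in range(-reach, reach + 1):
                    oracle += lj(self.A * math.sqrt(i * i + j * j + k * k))
        assert bd.e_att == pytest.approx(oracle, rel=1e-6)
        assert bd.e_att == pytest.approx(bd.e_latt - bd.e_slice, abs=1e-9)
        assert bd.e_att < 0

    def test_thick_slab_limit(self):
        """As the slice thickness grows, E_slice approaches E_latt."""
        crystal, cell = self.crystal()
        params = self.params()
        gaps = []
        for layers in (1, 4, 12):
            bd = attachment_energy_toy(
                crystal, MillerIndex(1, 0, 0), cell, params, slice_thickness=layers * self.A
            )
            gaps.append(abs(bd.e_slice - bd.e_latt))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.1 * abs(bd.e_latt)

    def test_in_plane_extensivity(self):
        """Doubling the cell in-plane leaves the per-cell attachment energy unchanged."""
        params = self.params()
        single, cell1 = toy_crystal("cubic", a=self.A, basis="single_lj")
        doubled, _ = toy_crystal("cubic", a=self.A, basis="single_lj", supercell=(1, 2, 2))
        cell2 = UnitCell(self.A, 2 * self.A, 2 * self.A)
        bd1 = attachment_energy_toy(single, MillerIndex(1, 0, 0), cell1, params,
                                    slice_thickness=self.A)
        bd2 = attachment_energy_toy(doubled, MillerIndex(1, 0, 0), cell2, params,
                                    slice_thickness=self.A)
        assert bd2.e_att == pytest.approx(4 * bd1.e_att, rel=1e-9)

    def test_minimum_image_violation_rejected(self):
        crystal, cell = self.crystal()
        params = ForceFieldParams(
            epsilon={"X": 0.3}, sigma={"X": 2.8}, vdw_cutoff=15.5,
            coulomb_method="minimum_image_cutoff",
        )
        with pytest.raises(ValueError, match="minimum-image"):
            nonbonded_energy(crystal, params, exclude_intramolecular=False)


class TestEnergyBreakdown:
    def test_identity_check(self):
        bd = EnergyBreakdown(e_tot=-10.0, e_cry=-6.0, e_sol=-3.0, e_int=-1.0)
        bd.check()
        bad = EnergyBreakdown(e_tot=-10.0, e_cry=-6.0, e_sol=-3.0, e_int=-2.0)
        with pytest.raises(AssertionError):
            bad.check()
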