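"""Non-bonded energies and the attachment-energy algebra.

Energy model: 12-6 Lennard-Jones plus point-charge Coulomb with geometric-mean
mixing, evaluated atom-by-atom inside a real-space cutoff (default 15.5 Å).
All molecules are rigid — no bonded terms — and intramolecular pairs are
excluded by default.  The three identities this module exists for are

    E_att  = E_latt − E_slice          (vacuum attachment energy)
    E_int  = E_tot − (E_cry + E_sol)   (crystal–solvent adhesion)
    E_att′ = E_att − E_int             (solvent-modified attachment energy)

Energies are in kcal/mol, distances in Å, charges in elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import ATOMIC_MASSES, MillerIndex, UnitCell, d_spacing, plane_unit_normal

__all__ = [
    "AtomSite",
    "MolecularSystem",
    "ForceFieldParams",
    "EnergyBreakdown",
    "nonbonded_energy",
    "interaction_energy",
    "modified_attachment_energy",
    "attachment_energy_toy",
    "COULOMB_CONSTANT",
]

#: kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637

ROLES = ("crystal", "organic", "water")


@dataclass(frozen=True)
class AtomSite:
    element: str
    mass: float  # amu
    charge: float  # e
    position: tuple[float, float, float]  # Å
    molecule_id: int = 0
    role: str = "crystal"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not all(np.isfinite(self.position)):
            raise ValueError("non-finite coordinates")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")


@dataclass
class MolecularSystem:
    """A set of atoms, optionally with a periodic box.

    The box is a 3×3 row matrix of lattice vectors (orthorhombic or triclinic);
    ``None`` means a finite cluster.  Struct-of-arrays accessors are provided
    for the vectorized energy kernels.
    """

    atoms: list[AtomSite]
    box: np.ndarray | None = None
    tags: str = ""

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise ValueError("box must be a 3x3 matrix of lattice vectors")
            if abs(np.linalg.det(self.box)) <= 0:
                raise ValueError("box volume must be positive")

    # -- struct-of-arrays views --------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms], dtype=int)

    @property
    def roles(self) -> list[str]:
        return [a.role for a in self.atoms]

    def subset(self, roles: str | tuple[str, ...]) -> "MolecularSystem":
        if isinstance(roles, str):
            roles = (roles,)
        return MolecularSystem(
            [a for a in self.atoms if a.role in roles], box=self.box, tags=self.tags
        )

    def translated(self, shift) -> "MolecularSystem":
        shift = np.asarray(shift, dtype=float)
        return MolecularSystem(
            [replace(a, position=tuple(np.asarray(a.position) + shift)) for a in self.atoms],
            box=self.box,
            tags=self.tags,
        )

    def total_mass(self, role: str | None = None) -> float:
        return float(sum(a.mass for a in self.atoms if role is None or a.role == role))

    def merged_with(self, other: "MolecularSystem") -> "MolecularSystem":
        offset = 1 + max((a.molecule_id for a in self.atoms), default=-1)
        shifted = [replace(a, molecule_id=a.molecule_id + offset) for a in other.atoms]
        return MolecularSystem(self.atoms + shifted, box=self.box, tags=self.tags)


@dataclass(frozen=True)
class ForceFieldParams:
    """Per-element LJ parameters plus electrostatics settings.

    ``epsilon`` (kcal/mol) and ``sigma`` (Å) are per-element maps; pair
    parameters come from the chosen mixing rule.  ``coulomb_method`` is
    ``"direct_sum"`` (finite clusters, no cutoff on charges) or
    ``"minimum_image_cutoff"`` (periodic toys, same cutoff as LJ).
    """

    epsilon: dict[str, float]
    sigma: dict[str, float]
    mixing_rule: str = "geometric"
    vdw_cutoff: float = 15.5
    coulomb_method: str = "direct_sum"
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon must be >= 0")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma must be > 0")
        if self.vdw_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.mixing_rule not in ("geometric", "lorentz-berthelot"):
            raise ValueError("mixing_rule must be 'geometric' or 'lorentz-berthelot'")
        if self.coulomb_method not in ("direct_sum", "minimum_image_cutoff"):
            raise ValueError("unknown coulomb_method")

    def pair_tables(self, elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom epsilon and sigma arrays; raises listing missing elements."""
        missing = sorted({e for e in elements if e not in self.epsilon or e not in self.sigma})
        if missing:
            raise KeyError(f"no LJ parameters for elements: {', '.join(missing)}")
        eps = np.array([self.epsilon[e] for e in elements])
        sig = np.array([self.sigma[e] for e in elements])
        return eps, sig


@dataclass
class EnergyBreakdown:
    """Energy decomposition of a crystal–solvent interface (kcal/mol)."""

    e_tot: float = 0.0
    e_cry: float = 0.0
    e_sol: float = 0.0
    e_int: float = 0.0
    e_latt: float | None = None
    e_slice: float | None = None
    e_att: float | None = None

    def check(self, tol: float = 1e-9) -> None:
        if abs(self.e_int - (self.e_tot - self.e_cry - self.e_sol)) > tol:
            raise AssertionError("breakdown identity violated")
        if self.e_att is not None and self.e_latt is not None and self.e_slice is not None:
            if abs(self.e_att - (self.e_latt - self.e_slice)) > tol:
                raise AssertionError("attachment identity violated")


def _pair_energy_matrix(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    q_a: np.ndarray,
    q_b: np.ndarray,
    params: ForceFieldParams,
    exclude: np.ndarray | None,
) -> float:
    """Sum of pair energies between group a and group b (full double count)."""
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    mask = np.ones_like(r, dtype=bool)
    if exclude is not None:
        mask &= ~exclude
    if np.any(r[mask] < 1e-6):
        raise ValueError("overlapping atoms (pair distance < 1e-6 Å)")
    if params.mixing_rule == "geometric":
        eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])
        sig_ij = np.sqrt(sig_a[:, None] * sig_b[None, :])
    else:  # lorentz-berthelot
        eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])
        sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        in_cut = mask & (r <= params.vdw_cutoff)
        sr6 = np.where(in_cut, (sig_ij / np.where(r > 0, r, 1.0)) ** 6, 0.0)
        lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
        lj = np.where(in_cut, lj, 0.0)
        qq = q_a[:, None] * q_b[None, :]
        if params.coulomb_method == "direct_sum":
            coul_mask = mask
        else:
            coul_mask = in_cut
        coul = np.where(coul_mask, params.coulomb_constant * qq / np.where(r > 0, r, 1.0), 0.0)
    return float(lj.sum() + coul.sum())


def nonbonded_energy(
    system: MolecularSystem,
    params: ForceFieldParams,
    exclude_intramolecular: bool = True,
) -> float:
    """Total non-bonded energy of a system (kcal/mol).

    For periodic systems the minimum-image convention is applied, which
    requires the cutoff not to exceed half the smallest box height.
    """
    return _system_energy(system, params, exclude_intramolecular)


def _system_energy(
    system: MolecularSystem,
    params: ForceFieldParams,
    exclude_intramolecular: bool,
    pair_filter: np.ndarray | None = None,
) -> float:
    """Pair-sum energy, optionally restricted to an (n, n) boolean pair filter."""
    n = system.n_atoms
    if system.box is not None:
        heights = _box_heights(system.box)
        if params.vdw_cutoff > 0.5 * heights.min() + 1e-9:
            raise ValueError(
                f"cutoff {params.vdw_cutoff} Å exceeds half the minimum box height "
                f"({0.5 * heights.min():.3f} Å): minimum-image violation"
            )
    if n < 2:
        return 0.0
    pos = system.positions
    q = system.charges
    eps, sig = params.pair_tables(system.elements)
    mol = system.molecule_ids

    if system.box is None:
        exclude = np.eye(n, dtype=bool)
        if exclude_intramolecular:
            exclude |= mol[:, None] == mol[None, :]
        if pair_filter is not None:
            exclude |= ~pair_filter
        return 0.5 * _pair_energy_matrix(pos, pos, eps, eps, sig, sig, q, q, params, exclude)

    # periodic: minimum image on fractional coordinates
    box = system.box
    inv = np.linalg.inv(box)
    frac = pos @ inv
    dfrac = frac[:, None, :] - frac[None, :, :]
    dfrac -= np.round(dfrac)
    diff = dfrac @ box
    r = np.linalg.norm(diff, axis=-1)
    exclude = np.eye(n, dtype=bool)
    if exclude_intramolecular:
        exclude |= mol[:, None] == mol[None, :]
    if pair_filter is not None:
        exclude |= ~pair_filter
    mask = ~exclude
    if np.any(r[mask] < 1e-6):
        raise ValueError("overlapping atoms (pair distance < 1e-6 Å)")
    if params.mixing_rule == "geometric":
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        sig_ij = np.sqrt(sig[:, None] * sig[None, :])
    else:
        eps_ij = np.sqrt(eps[:, None] * eps[None, :])
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    in_cut = mask & (r <= params.vdw_cutoff)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(in_cut, (sig_ij / np.where(r > 0, r, 1.0)) ** 6, 0.0)
        lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
        lj = np.where(in_cut, lj, 0.0)
        coul = np.where(
            in_cut, params.coulomb_constant * q[:, None] * q[None, :] / np.where(r > 0, r, 1.0), 0.0
        )
    return 0.5 * float(lj.sum() + coul.sum())


def _box_heights(box: np.ndarray) -> np.ndarray:
    """Perpendicular heights of the box along its three lattice directions."""
    vol = abs(np.linalg.det(box))
    cross = np.array(
        [np.cross(box[1], box[2]), np.cross(box[2], box[0]), np.cross(box[0], box[1])]
    )
    return vol / np.linalg.norm(cross, axis=1)


def interaction_energy(
    interface: MolecularSystem,
    params: ForceFieldParams,
    exclude_intramolecular: bool = True,
) -> EnergyBreakdown:
    """Crystal–solvent adhesion energy E_int = E_tot − (E_cry + E_sol).

    The solvent is everything labelled organic or water.  E_int is evaluated
    as the crystal↔solvent cross-pair sum, which for a pairwise-additive
    potential is identical to the defining subtraction but free of
    summation-order round-off (exactly zero when the groups are out of
    range); the full, crystal-only and solvent-only evaluations are returned
    alongside and the identity is verified to 1e-9 on every call.
    """
    roles = set(interface.roles)
    if "crystal" not in roles or not roles & {"organic", "water"}:
        raise ValueError("interface must contain 'crystal' atoms and 'organic'/'water' atoms")
    e_tot = nonbonded_energy(interface, params, exclude_intramolecular)
    e_cry = nonbonded_energy(interface.subset("crystal"), params, exclude_intramolecular)
    e_sol = nonbonded_energy(interface.subset(("organic", "water")), params, exclude_intramolecular)
    is_cry = np.array([a.role == "crystal" for a in interface.atoms])
    cross = is_cry[:, None] != is_cry[None, :]
    e_int = _system_energy(interface, params, exclude_intramolecular, pair_filter=cross)
    bd = EnergyBreakdown(e_tot=e_tot, e_cry=e_cry, e_sol=e_sol, e_int=e_int)
    bd.check()
    return bd


def modified_attachment_energy(e_att: float, e_int: float, area_scale: float = 1.0) -> float:
    """Solvent-modified attachment energy E_att′ = E_att − area_scale·E_int.

    ``area_scale`` rescales a box-level interaction energy to the reference
    cell of the attachment energy (A_cell/A_box); pass 1.0 when both are on
    the same footing.
    """
    if e_att > 0:
        raise ValueError("attachment energies are non-positive by convention")
    return e_att - area_scale * e_int


def attachment_energy_toy(
    crystal: MolecularSystem,
    hkl: MillerIndex,
    cell: UnitCell,
    params: ForceFieldParams,
    slice_thickness: float | None = None,
) -> EnergyBreakdown:
    """Attachment energy of a toy periodic crystal face: E_att = E_latt − E_slice.

    E_latt is the per-cell energy of the infinite crystal (lattice sum inside
    the cutoff); E_slice is the per-cell energy of an isolated slab of
    thickness d_hkl cut perpendicular to (h k l).  Intended for desk-scale toy
    crystals (e.g. a single-LJ-atom cubic lattice), not real structures.
    """
    if crystal.box is None:
        raise ValueError("attachment energy needs a periodic crystal")
    if slice_thickness is None:
        slice_thickness = d_spacing(cell, hkl)
    e_latt = _lattice_energy_per_cell(crystal, params)
    e_slice = _slab_energy_per_cell(crystal, cell, hkl, slice_thickness, params)
    bd = EnergyBreakdown(e_latt=e_latt, e_slice=e_slice, e_att=e_latt - e_slice)
    return bd


def _replicated_energy(
    base: MolecularSystem, images: list[np.ndarray], params: ForceFieldParams
) -> float:
    """Per-cell energy: half the interaction of the home cell with all images
    (including in-cell pairs once)."""
    pos = base.positions
    q = base.charges
    eps, sig = params.pair_tables(base.elements)
    total = 0.0
    for shift in images:
        other = pos + shift
        if np.allclose(shift, 0.0):
            exclude = np.eye(len(pos), dtype=bool)
        else:
            exclude = None
        total += _pair_energy_matrix(pos, other, eps, eps, sig, sig, q, q, params, exclude)
    return 0.5 * total


def _image_shifts(box: np.ndarray, cutoff: float, keep) -> list[np.ndarray]:
    heights = _box_heights(box)
    reps = np.ceil(cutoff / heights).astype(int) + 1
    shifts = []
    for i in range(-reps[0], reps[0] + 1):
        for j in range(-reps[1], reps[1] + 1):
            for k in range(-reps[2], reps[2] + 1):
                if keep(i, j, k):
                    shifts.append(i * box[0] + j * box[1] + k * box[2])
    return shifts


def _lattice_energy_per_cell(crystal: MolecularSystem, params: ForceFieldParams) -> float:
    shifts = _image_shifts(crystal.box, params.vdw_cutoff, lambda i, j, k: True)
    return _replicated_energy(crystal, shifts, params)


def _slab_energy_per_cell(
    crystal: MolecularSystem,
    cell: UnitCell,
    hkl: MillerIndex,
    thickness: float,
    params: ForceFieldParams,
) -> float:
    """Per-cell energy of an isolated slab of the given thickness normal to (h k l).

    The slab consists of the lattice layers 0 .. n_layers−1 along the plane
    normal (a lattice translation (i j k) sits in layer h·i + k·j + l·k); the
    in-plane periodicity is retained in full within the cutoff.
    """
    box = crystal.box
    d = d_spacing(cell, hkl)
    n_layers = max(1, int(round(thickness / d)))

    def layer_of(i: int, j: int, k: int) -> int:
        return hkl.h * i + hkl.k * j + hkl.l * k

    heights = _box_heights(box)
    reps = np.ceil((params.vdw_cutoff) / heights).astype(int) + 1

    # smallest lattice vector representing each slab layer
    base: dict[int, np.ndarray] = {}
    r0 = int(reps.max()) + abs(hkl.h) + abs(hkl.k) + abs(hkl.l) + n_layers
    for i in range(-r0, r0 + 1):
        for j in range(-r0, r0 + 1):
            for k in range(-r0, r0 + 1):
                li = layer_of(i, j, k)
                if 0 <= li < n_layers:
                    v = i * box[0] + j * box[1] + k * box[2]
                    if li not in base or np.linalg.norm(v) < np.linalg.norm(base[li]):
                        base[li] = v

    pos = crystal.positions
    q = crystal.charges
    eps, sig = params.pair_tables(crystal.elements)
    total = 0.0
    for li in range(n_layers):
        if li not in base:
            continue
        b = base[li]
        home = pos + b
        # lattice images around b that stay inside the slab and within reach
        bi = np.round(b @ np.linalg.inv(box)).astype(int)
        for di in range(-r0, r0 + 1):
            for dj in range(-r0, r0 + 1):
                for dk in range(-r0, r0 + 1):
                    i2, j2, k2 = bi[0] + di, bi[1] + dj, bi[2] + dk
                    if not 0 <= layer_of(i2, j2, k2) < n_layers:
                        continue
                    s = i2 * box[0] + j2 * box[1] + k2 * box[2]
                    if np.linalg.norm(s - b) > params.vdw_cutoff + float(np.ptp(pos)) * 2 + 1e-9:
                        continue
                    exclude = np.eye(len(pos), dtype=bool) if (di, dj, dk) == (0, 0, 0) else None
                    total += _pair_energy_matrix(
                        home, pos + s, eps, eps, sig, sig, q, q, params, exclude
                    )
    return 0.5 * total / n_layers
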