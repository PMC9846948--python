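"""Layered crystal/organic/water/vacuum interface models and surface roughness.

The builder follows the usual recipe for modified attachment-energy studies:
cleave a slab normal to (h k l), replicate it U × V in-plane, stack a packed
organic layer and a packed water layer on top (organic/water volume ratio 1/3
by default), and finish with a vacuum gap (default 100 Å) that isolates the
interface from its periodic image.  Surface roughness is quantified by
S = A_acc / A_hkl, the probe-accessible area of the upper surface envelope
over the planar face area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import AtomSite, MolecularSystem
from .lattice import AMU_TO_G_PER_A3, MillerIndex, UnitCell, d_spacing

__all__ = [
    "Slab",
    "SolventBoxSpec",
    "InterfaceModel",
    "SurfaceAccessibility",
    "MoleculeTemplate",
    "WATER_TEMPLATE",
    "pack_solvent_box",
    "assemble_interface",
    "solvent_accessible_ratio",
    "accessible_area_cluster",
]

#: van der Waals radii (Å) used for the surface envelope.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "Ca": 2.31, "Na": 2.27, "Cl": 1.75, "X": 1.70,
}


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecule template: element symbols, masses, charges, local coords."""

    name: str
    elements: tuple[str, ...]
    masses: tuple[float, ...]
    charges: tuple[float, ...]
    coords: tuple[tuple[float, float, float], ...]

    @property
    def molar_mass(self) -> float:
        return float(sum(self.masses))

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges))


def _water_template() -> MoleculeTemplate:
    # rigid 3-site water: O-H 0.957 Å, H-O-H 104.5°, q(O) = -0.72 e, q(H) = +0.36 e
    r, theta = 0.957, math.radians(104.5)
    h1 = (r * math.sin(theta / 2), r * math.cos(theta / 2), 0.0)
    h2 = (-r * math.sin(theta / 2), r * math.cos(theta / 2), 0.0)
    return MoleculeTemplate(
        name="water",
        elements=("O", "H", "H"),
        masses=(15.999, 1.008, 1.008),
        charges=(-0.72, 0.36, 0.36),
        coords=((0.0, 0.0, 0.0), h1, h2),
    )


WATER_TEMPLATE = _water_template()


@dataclass
class Slab:
    """Crystal slab cleaved normal to (h k l), surface normal along +z."""

    cell: UnitCell
    hkl: MillerIndex
    depth: float
    u_repeat: int
    v_repeat: int
    atoms: MolecularSystem
    cross_section: float  # Å² of the U×V in-plane cell

    @property
    def surface_edge_z(self) -> float:
        """Max crystal atom z: the edge of the crystal surface."""
        return float(self.atoms.positions[:, 2].max())


@dataclass(frozen=True)
class SolventBoxSpec:
    """Random packing request for one solvent layer."""

    template: MoleculeTemplate
    count: int
    target_density: float  # g/cm³
    cross_section: float  # Å²
    seed: int = 0
    min_distance: float = 1.5  # Å, intermolecular atom-atom floor

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.target_density <= 0 or self.cross_section <= 0:
            raise ValueError("density and cross-section must be positive")

    @property
    def thickness(self) -> float:
        """Layer thickness implied by count, molar mass, density, cross-section."""
        volume = self.count * self.template.molar_mass * AMU_TO_G_PER_A3 / self.target_density
        return volume / self.cross_section


@dataclass
class InterfaceModel:
    """Composite slab/organic/water/vacuum model."""

    slab: Slab
    system: MolecularSystem
    organic_thickness: float
    water_thickness: float
    vacuum_thickness: float

    @property
    def total_height(self) -> float:
        return (
            self.slab.depth + self.organic_thickness + self.water_thickness + self.vacuum_thickness
        )


@dataclass(frozen=True)
class SurfaceAccessibility:
    a_acc: float  # Å²
    a_hkl: float  # Å²

    @property
    def s_ratio(self) -> float:
        return self.a_acc / self.a_hkl


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def pack_solvent_box(spec: SolventBoxSpec, max_attempts: int = 20000) -> MolecularSystem:
    """Randomly pack ``count`` rigid molecules into a box at the target density.

    Random sequential insertion with rejection: each molecule gets a random
    position and orientation from the seeded RNG and is accepted when every
    atom stays at least ``min_distance`` from atoms of previously placed
    molecules (with in-plane minimum-image wrapping).  The box thickness is
    fixed by count · M / (N_A · ρ · A), so the realized density is exact.
    """
    rng = np.random.default_rng(spec.seed)
    lx = math.sqrt(spec.cross_section)
    ly = spec.cross_section / lx
    lz = spec.thickness
    template = np.asarray(spec.template.coords)
    placed: list[np.ndarray] = []
    atoms: list[AtomSite] = []
    role = "water" if spec.template.name == "water" else "organic"
    for mol in range(spec.count):
        for attempt in range(max_attempts):
            rot = _random_rotation(rng)
            center = rng.uniform((0, 0, 0), (lx, ly, lz))
            coords = template @ rot.T + center
            ok = True
            for other in placed:
                diff = coords[:, None, :] - other[None, :, :]
                # in-plane minimum image
                diff[..., 0] -= lx * np.round(diff[..., 0] / lx)
                diff[..., 1] -= ly * np.round(diff[..., 1] / ly)
                if np.min(np.linalg.norm(diff, axis=-1)) < spec.min_distance:
                    ok = False
                    break
            if ok:
                placed.append(coords)
                for el, m, q, xyz in zip(
                    spec.template.elements, spec.template.masses, spec.template.charges, coords
                ):
                    atoms.append(AtomSite(el, m, q, tuple(xyz), molecule_id=mol, role=role))
                break
        else:
            raise RuntimeError(
                f"could not insert molecule {mol + 1}/{spec.count} after {max_attempts} "
                "attempts; lower the density or the minimum distance"
            )
    box = np.diag([lx, ly, lz])
    return MolecularSystem(atoms, box=box, tags=f"packed:{spec.template.name}:seed={spec.seed}")


def assemble_interface(
    slab: Slab,
    organic: MolecularSystem | None,
    water: MolecularSystem,
    vacuum_thickness: float = 100.0,
    cross_section_tol: float = 1e-6,
) -> InterfaceModel:
    """Stack slab → organic → water → vacuum along +z.

    Every layer keeps its internal coordinates; layers are translated so they
    abut without overlap.  Cross-sections must match to ``cross_section_tol``
    (relative).
    """

    def xsec(system: MolecularSystem) -> float:
        if system.box is None:
            raise ValueError("layer has no box; cross-section unknown")
        return float(abs(np.linalg.det(system.box[:2, :2])))

    layers = []
    z = slab.depth
    organic_thickness = 0.0
    if organic is not None and organic.n_atoms > 0:
        a = xsec(organic)
        if abs(a - slab.cross_section) > cross_section_tol * slab.cross_section:
            raise ValueError(
                f"organic layer cross-section {a:.4f} Å² does not match slab "
                f"{slab.cross_section:.4f} Å²"
            )
        organic_thickness = float(organic.box[2, 2])
        layers.append(organic.translated((0.0, 0.0, z - organic.positions[:, 2].min())))
        z += organic_thickness
    a = xsec(water)
    if abs(a - slab.cross_section) > cross_section_tol * slab.cross_section:
        raise ValueError(
            f"water layer cross-section {a:.4f} Å² does not match slab "
            f"{slab.cross_section:.4f} Å²"
        )
    water_thickness = float(water.box[2, 2])
    layers.append(water.translated((0.0, 0.0, z - water.positions[:, 2].min())))
    z += water_thickness

    system = slab.atoms
    for layer in layers:
        system = system.merged_with(layer)
    total = slab.depth + organic_thickness + water_thickness + vacuum_thickness
    box = np.array(
        [
            [math.sqrt(slab.cross_section), 0.0, 0.0],
            [0.0, slab.cross_section / math.sqrt(slab.cross_section), 0.0],
            [0.0, 0.0, total],
        ]
    )
    system = MolecularSystem(system.atoms, box=box, tags="interface")
    return InterfaceModel(
        slab=slab,
        system=system,
        organic_thickness=organic_thickness,
        water_thickness=water_thickness,
        vacuum_thickness=vacuum_thickness,
    )


def solvent_accessible_ratio(
    slab: Slab,
    probe_radius: float = 1.0,
    grid_resolution: float = 0.25,
    radii: dict[str, float] | None = None,
) -> SurfaceAccessibility:
    """Roughness ratio S = A_acc / A_hkl of the slab's upper surface.

    A_acc is the area of the upper envelope z(x, y) of the probe-inflated
    atomic spheres, integrated on a periodic (x, y) grid; A_hkl is the planar
    cross-section.  A perfectly flat surface gives S ≈ 1; cavities and
    protrusions raise it.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if slab.atoms.n_atoms == 0:
        raise ValueError("empty slab")
    radii = radii or VDW_RADII
    pos = slab.atoms.positions
    r = np.array([radii.get(e, 1.7) for e in slab.atoms.elements]) + probe_radius

    lx = math.sqrt(slab.cross_section)
    ly = slab.cross_section / lx
    nx = max(8, int(round(lx / grid_resolution)))
    ny = max(8, int(round(ly / grid_resolution)))
    xs = (np.arange(nx) + 0.5) * lx / nx
    ys = (np.arange(ny) + 0.5) * ly / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    z_floor = float(pos[:, 2].min()) - r.max()
    height = np.full((nx, ny), z_floor)
    for (x0, y0, z0), ri in zip(pos, r):
        dx = gx - x0
        dx -= lx * np.round(dx / lx)
        dy = gy - y0
        dy -= ly * np.round(dy / ly)
        d2 = ri * ri - dx * dx - dy * dy
        contrib = np.where(d2 > 0, z0 + np.sqrt(np.maximum(d2, 0.0)), z_floor)
        height = np.maximum(height, contrib)

    # surface area of the height field with periodic wrapping
    dzdx = (np.roll(height, -1, axis=0) - np.roll(height, 1, axis=0)) / (2 * lx / nx)
    dzdy = (np.roll(height, -1, axis=1) - np.roll(height, 1, axis=1)) / (2 * ly / ny)
    a_acc = float(np.sum(np.sqrt(1.0 + dzdx**2 + dzdy**2)) * (lx / nx) * (ly / ny))
    return SurfaceAccessibility(a_acc=a_acc, a_hkl=slab.cross_section)


def accessible_area_cluster(
    system: MolecularSystem,
    probe_radius: float = 1.0,
    n_points: int = 2000,
    radii: dict[str, float] | None = None,
    seed: int = 0,
) -> float:
    """Probe-accessible area (Å²) of a finite cluster by Shrake–Rupley sampling.

    For an isolated atom of radius r this converges to 4π(r + p)².  Used for
    closed-form checks and small clusters; slabs use the periodic envelope in
    :func:`solvent_accessible_ratio`.
    """
    radii = radii or VDW_RADII
    pos = system.positions
    r = np.array([radii.get(e, 1.7) for e in system.elements]) + probe_radius
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    area = 0.0
    for i in range(len(pos)):
        surface = pos[i] + r[i] * pts
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(pos)):
            if j == i:
                continue
            buried |= np.linalg.norm(surface - pos[j], axis=1) < r[j]
        area += (1.0 - buried.mean()) * 4.0 * math.pi * r[i] ** 2
    return float(area)


def cleave_slab(
    crystal: MolecularSystem,
    cell: UnitCell,
    hkl: MillerIndex,
    depth: float | None = None,
    u_repeat: int = 1,
    v_repeat: int = 1,
) -> Slab:
    """Cleave a slab normal to (h k l) from a periodic crystal, rotated to +z.

    Whole molecules are kept when their centroid lies in the depth window
    (default depth 2·d_hkl), so no intramolecular contacts are cut.  The slab
    is replicated u × v in-plane.
    """
    from .lattice import plane_unit_normal

    if crystal.box is None:
        raise ValueError("need a periodic crystal to cleave")
    d = d_spacing(cell, hkl)
    if depth is None:
        depth = 2.0 * d
    n_layers = max(1, int(round(depth / d)))
    normal = plane_unit_normal(cell, hkl)

    # rotate so the normal is +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3) if normal[2] > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        c = float(np.dot(normal, z))
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))

    box = crystal.box
    # in-plane lattice vectors: two shortest lattice vectors with zero layer index
    candidates = []
    for i in range(-3, 4):
        for j in range(-3, 4):
            for k in range(-3, 4):
                if (i, j, k) == (0, 0, 0):
                    continue
                if hkl.h * i + hkl.k * j + hkl.l * k == 0:
                    candidates.append(i * box[0] + j * box[1] + k * box[2])
    candidates.sort(key=lambda u: float(np.linalg.norm(u)))
    u_vec = candidates[0]
    v_vec = next(
        c for c in candidates if np.linalg.norm(np.cross(u_vec, c)) > 1e-9 * np.linalg.norm(c)
    )
    # stacking vector: any lattice vector in layer 1
    stack = None
    for i in range(-3, 4):
        for j in range(-3, 4):
            for k in range(-3, 4):
                if hkl.h * i + hkl.k * j + hkl.l * k == 1:
                    w = i * box[0] + j * box[1] + k * box[2]
                    if stack is None or np.linalg.norm(w) < np.linalg.norm(stack):
                        stack = w
    if stack is None:
        raise ValueError(f"no stacking vector for {hkl}; indices not coprime?")

    atoms: list[AtomSite] = []
    mol_counter = 0
    for layer in range(n_layers):
        for iu in range(u_repeat):
            for iv in range(v_repeat):
                shift = layer * stack + iu * u_vec + iv * v_vec
                for a in crystal.atoms:
                    p = rot @ (np.asarray(a.position) + shift)
                    atoms.append(
                        AtomSite(
                            a.element, a.mass, a.charge, tuple(p),
                            molecule_id=mol_counter + a.molecule_id, role="crystal",
                        )
                    )
        mol_counter += 1 + max(a.molecule_id for a in crystal.atoms)
    pos = np.array([a.position for a in atoms])
    zmin = pos[:, 2].min()
    atoms = [replace(a, position=tuple(np.asarray(a.position) - [0, 0, zmin])) for a in atoms]

    cross = float(np.linalg.norm(np.cross(rot @ u_vec, rot @ v_vec))) * u_repeat * v_repeat
    sys = MolecularSystem(
        atoms, box=np.vstack([rot @ u_vec * u_repeat, rot @ v_vec * v_repeat, rot @ (stack * n_layers)])
    )
    return Slab(
        cell=cell, hkl=hkl, depth=n_layers * d, u_repeat=u_repeat, v_repeat=v_repeat,
        atoms=sys, cross_section=cross,
    )
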