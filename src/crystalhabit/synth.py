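"""Seeded synthetic-data generators with recorded ground truth.

Every analysis stage in the package can be exercised end-to-end on data from
this module: toy periodic crystals for the attachment-energy path, packed
solvent boxes, layered interface trajectories with prescribed density peaks,
linear side-ratio tables with additive noise, and slab+adsorbate fixtures for
interaction-energy sign tests.  All generators are deterministic under a
fixed seed and stamp their parameters into the output tags/metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import AtomSite, MolecularSystem
from .interface import WATER_TEMPLATE, MoleculeTemplate, SolventBoxSpec, pack_solvent_box
from .lattice import MillerIndex, UnitCell
from .profiles import FrameSet
from .stats import SideRatioSeries

__all__ = [
    "toy_crystal",
    "layered_frames",
    "sideratio_table",
    "adsorption_config",
    "LayerSpec",
]


def toy_crystal(
    lattice: str = "cubic",
    a: float = 5.0,
    b: float | None = None,
    c: float | None = None,
    beta: float = 90.0,
    basis: str = "single_lj",
    supercell: tuple[int, int, int] = (1, 1, 1),
    element: str = "X",
) -> tuple[MolecularSystem, UnitCell]:
    """Toy periodic crystal: single-LJ-atom or charged rocksalt-like basis.

    ``lattice`` is "cubic" or "monoclinic" (b-unique).  The returned system
    carries the supercell box; the returned :class:`UnitCell` describes the
    primitive cell.
    """
    if lattice == "cubic":
        cell = UnitCell(a, a, a)
    elif lattice == "monoclinic":
        cell = UnitCell(a, b if b is not None else a, c if c is not None else a, beta=beta)
    else:
        raise ValueError("lattice must be 'cubic' or 'monoclinic'")
    basis_atoms: list[tuple[str, float, float, np.ndarray]]
    if basis == "single_lj":
        basis_atoms = [(element, 1.0, 0.0, np.zeros(3))]
    elif basis == "rocksalt":
        # two-site charged basis; cell is charge neutral
        basis_atoms = [
            (element, 1.0, +0.5, np.zeros(3)),
            (element, 1.0, -0.5, np.array([0.5, 0.5, 0.5])),
        ]
    else:
        raise ValueError("basis must be 'single_lj' or 'rocksalt'")
    direct = cell.direct_basis()
    atoms: list[AtomSite] = []
    mol = 0
    for i in range(supercell[0]):
        for j in range(supercell[1]):
            for k in range(supercell[2]):
                shift = np.array([i, j, k], dtype=float)
                for el, m, q, frac in basis_atoms:
                    pos = (frac + shift) @ direct
                    atoms.append(AtomSite(el, m, q, tuple(pos), molecule_id=mol, role="crystal"))
                    mol += 1
    box = direct * np.array(supercell)[:, None]
    return MolecularSystem(atoms, box=box, tags=f"toy:{lattice}:{basis}"), cell


@dataclass(frozen=True)
class LayerSpec:
    """One Gaussian solvent layer of a synthetic interface trajectory."""

    center_z: float  # Å
    width: float  # Å (Gaussian sigma)
    role: str  # "organic" or "water" or "crystal"
    n_atoms: int
    atom_mass: float = 18.015

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("layer width must be positive")


def layered_frames(
    layers: list[LayerSpec],
    n_frames: int = 100,
    noise: float = 0.0,
    cross_section: float = 400.0,
    seed: int = 0,
    frame_interval: float = 0.5,
) -> tuple[FrameSet, dict]:
    """Trajectory of Gaussian-placed layers with known peak positions.

    Atoms of each layer are drawn z ~ N(center, width²) once, then jittered by
    ``noise`` (Å, per frame) to emulate thermal motion; x, y are uniform over
    the cross-section.  Metadata records the ground-truth peak centers and,
    for convenience, the exact per-layer mass.
    """
    rng = np.random.default_rng(seed)
    lx = math.sqrt(cross_section)
    ly = cross_section / lx
    base_positions = []
    for layer in layers:
        xy = rng.uniform((0, 0), (lx, ly), size=(layer.n_atoms, 2))
        z = rng.normal(layer.center_z, layer.width, size=layer.n_atoms)
        base_positions.append(np.column_stack([xy, z]))
    frames = []
    box = np.diag([lx, ly, max(l.center_z + 6 * l.width for l in layers)])
    for _ in range(n_frames):
        atoms: list[AtomSite] = []
        mol = 0
        for layer, base in zip(layers, base_positions):
            jitter = rng.normal(0.0, noise, size=base.shape) if noise > 0 else 0.0
            pos = base + jitter
            for p in pos:
                atoms.append(
                    AtomSite("X", layer.atom_mass, 0.0, tuple(p), molecule_id=mol, role=layer.role)
                )
                mol += 1
        frames.append(MolecularSystem(atoms, box=box, tags=f"layered:seed={seed}"))
    metadata = {
        "seed": seed,
        "peak_z": {  # tallest first within each role
            role: [l.center_z for l in sorted(
                (l for l in layers if l.role == role),
                key=lambda l: -l.n_atoms * l.atom_mass / l.width,
            )]
            for role in {l.role for l in layers}
        },
        "layer_mass": {i: l.n_atoms * l.atom_mass for i, l in enumerate(layers)},
        "cross_section": cross_section,
    }
    fs = FrameSet(frames, frame_interval=frame_interval, analysis_window=(0, n_frames))
    return fs, metadata


def sideratio_table(
    slopes: dict[str, float],
    intercepts: dict[str, float] | float = 0.05,
    noise_sigma: float = 0.0,
    volumes: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0),
    seed: int = 0,
) -> tuple[list[SideRatioSeries], dict]:
    """Linear side-ratio series per solvent: ratio = slope·V + intercept + noise."""
    if len(set(volumes)) < 2:
        raise ValueError("volumes are degenerate")
    rng = np.random.default_rng(seed)
    if isinstance(intercepts, (int, float)):
        intercepts = {name: float(intercepts) for name in slopes}
    series = []
    for name in sorted(slopes):
        clean = np.array([slopes[name] * v + intercepts[name] for v in volumes])
        noisy = clean + (rng.normal(0.0, noise_sigma, len(volumes)) if noise_sigma > 0 else 0.0)
        noisy = np.maximum(noisy, 1e-6)  # ratios are positive by definition
        series.append(SideRatioSeries(name, tuple(volumes), tuple(float(x) for x in noisy)))
    metadata = {"seed": seed, "slopes": dict(slopes), "intercepts": dict(intercepts)}
    return series, metadata


def adsorption_config(
    n_slab: tuple[int, int] = (6, 6),
    spacing: float = 3.0,
    adsorbate_count: int = 1,
    separation: float = 3.0,
    adsorbate_role: str = "water",
    seed: int = 0,
) -> MolecularSystem:
    """Slab + adsorbate fixture for interaction-energy sign and zero tests.

    A square monolayer slab of LJ atoms (role=crystal) in the z=0 plane, with
    ``adsorbate_count`` single-site solvent atoms at height ``separation``
    above it.  A separation larger than the cutoff guarantees E_int = 0.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    atoms: list[AtomSite] = []
    mol = 0
    for i in range(n_slab[0]):
        for j in range(n_slab[1]):
            atoms.append(
                AtomSite("X", 40.0, 0.0, (i * spacing, j * spacing, 0.0), molecule_id=mol,
                         role="crystal")
            )
            mol += 1
    lx, ly = n_slab[0] * spacing, n_slab[1] * spacing
    placed: list[tuple[float, float]] = []
    for _ in range(adsorbate_count):
        # rejection sampling keeps adsorbates at least one lattice spacing apart
        for _attempt in range(10000):
            x, y = (float(v) for v in rng.uniform((0, 0), (lx, ly)))
            if all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in placed):
                placed.append((x, y))
                break
        else:
            raise RuntimeError("could not place adsorbates without overlap")
        atoms.append(
            AtomSite("X", 18.0, 0.0, (x, y, separation), molecule_id=mol, role=adsorbate_role)
        )
        mol += 1
    return MolecularSystem(atoms, tags=f"adsorption:sep={separation}:seed={seed}")
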