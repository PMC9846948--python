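"""Format readers/writers and run configuration shared by all stages.

Formats: minimal CIF (cell, symmetry, atom sites — via gemmi), CSV face
tables, (extended) XYZ, minimal PDB, atom sidecar CSV (mass/charge/role per
atom), JSON habit reports and OBJ polyhedron export.  Units everywhere:
Å, kcal/mol, g/cm³, μL, Debye.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .energetics import AtomSite, MolecularSystem
from .habit import FaceRecord, WulffShape
from .lattice import ATOMIC_MASSES, MillerIndex, UnitCell

__all__ = [
    "ProtocolConfig",
    "RunConfig",
    "read_cif_cell",
    "read_face_table",
    "write_face_table",
    "write_area_report",
    "read_xyz",
    "write_xyz",
    "write_pdb",
    "read_sidecar",
    "write_sidecar",
    "write_obj",
    "manifest_hash",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """MD protocol emitted alongside interface models for external engines.

    The defaults are the standard production settings for constrained-surface
    interface runs: NVT at 298.15 K, 15.5 Å van der Waals cutoff, 1 fs steps
    for 500 ps with frames every 500 steps, the first half treated as
    equilibration; interface geometry uses a 100 Å vacuum gap and an
    organic/water volume ratio of 1/3.
    """

    temperature: float = 298.15  # K
    ensemble: str = "NVT"
    thermostat: str = "NHL"
    vdw_cutoff: float = 15.5  # Å
    timestep: float = 1.0  # fs
    duration: float = 500.0  # ps
    dump_interval_steps: int = 500
    equilibration: float = 250.0  # ps
    analysis_window: float = 125.0  # ps at the tail
    vacuum_thickness: float = 100.0  # Å
    organic_water_ratio: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("temperature", "vdw_cutoff", "timestep", "duration", "vacuum_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunConfig:
    """One pipeline invocation: subcommand parameters + protocol + seed."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "subcommand" not in raw:
            raise ValueError(f"malformed config {path}: missing 'subcommand'")
        protocol = ProtocolConfig(**raw.get("protocol", {}))
        return cls(
            subcommand=raw["subcommand"],
            parameters=raw.get("parameters", {}),
            protocol=protocol,
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "."),
            log_level=raw.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "protocol": asdict(self.protocol),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# -- crystallographic input -------------------------------------------------


def read_cif_cell(path: str | Path) -> UnitCell:
    """Unit cell (+ space group, hence Laue class) from a small-molecule CIF."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def num(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise ValueError(f"{path}: missing {tag}")
        return float(val.split("(")[0])

    symbol = None
    for tag in ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M"):
        val = block.find_value(tag)
        if val:
            symbol = val.strip("'\" ")
            break
    return UnitCell(
        a=num("_cell_length_a"),
        b=num("_cell_length_b"),
        c=num("_cell_length_c"),
        alpha=num("_cell_angle_alpha"),
        beta=num("_cell_angle_beta"),
        gamma=num("_cell_angle_gamma"),
        space_group_symbol=symbol,
    )


def read_face_table(path: str | Path) -> list[FaceRecord]:
    """Face table CSV: columns hkl ("h k l"), multiplicity, e_att[, e_int, d_hkl]."""
    df = pd.read_csv(path)
    required = {"hkl", "e_att"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            FaceRecord(
                hkl=MillerIndex.from_string(str(row["hkl"])),
                multiplicity=int(row["multiplicity"]) if "multiplicity" in df else None,
                d_hkl=float(row["d_hkl"]) if "d_hkl" in df and pd.notna(row["d_hkl"]) else None,
                e_att=float(row["e_att"]),
                e_int=float(row["e_int"]) if "e_int" in df and pd.notna(row["e_int"]) else None,
            )
        )
    return records


def write_face_table(faces: list[FaceRecord], path: str | Path) -> None:
    rows = []
    for f in faces:
        rows.append(
            {
                "hkl": f"{f.hkl.h} {f.hkl.k} {f.hkl.l}",
                "multiplicity": f.multiplicity,
                "d_hkl": f.d_hkl,
                "e_att": f.e_att,
                "e_int": f.e_int,
                "e_att_prime": f.e_att_prime,
                "growth_rate": f.growth_rate,
                "area_fraction": f.area_fraction,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_area_report(fractions: dict[MillerIndex, float], path: str | Path) -> None:
    rows = [
        {"hkl": f"{h.h} {h.k} {h.l}", "area_fraction_percent": v} for h, v in fractions.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- coordinate formats -----------------------------------------------------


def write_xyz(system: MolecularSystem, path: str | Path, comment: str = "") -> None:
    """Extended XYZ: a Lattice= entry is written when the system is periodic."""
    lines = [str(system.n_atoms)]
    if system.box is not None:
        lat = " ".join(f"{x:.8f}" for x in system.box.flatten())
        comment = f'Lattice="{lat}" {comment}'.strip()
    lines.append(comment)
    for a in system.atoms:
        x, y, z = a.position
        lines.append(f"{a.element} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, sidecar: str | Path | None = None) -> MolecularSystem:
    """Read (extended) XYZ, optionally joining a sidecar CSV for mass/charge/role.

    Multi-frame files are read by :func:`read_xyz_frames`.
    """
    systems = read_xyz_frames(path, sidecar)
    if len(systems) != 1:
        raise ValueError(f"{path}: expected a single frame, found {len(systems)}")
    return systems[0]


def read_xyz_frames(path: str | Path, sidecar: str | Path | None = None) -> list[MolecularSystem]:
    """Read a concatenated (multi-frame) XYZ trajectory."""
    text = Path(path).read_text().splitlines()
    side = read_sidecar(sidecar) if sidecar else None
    systems = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i].strip())
        comment = text[i + 1] if i + 1 < len(text) else ""
        box = None
        if 'Lattice="' in comment:
            lat = comment.split('Lattice="')[1].split('"')[0]
            box = np.fromstring(lat, sep=" ").reshape(3, 3)
        atoms = []
        for j, line in enumerate(text[i + 2 : i + 2 + n]):
            parts = line.split()
            el = parts[0]
            pos = tuple(float(x) for x in parts[1:4])
            if side is not None:
                mass, charge, role, mol = side[j]
            else:
                mass, charge, role, mol = ATOMIC_MASSES.get(el, 1.0), 0.0, "crystal", j
            atoms.append(AtomSite(el, mass, charge, pos, molecule_id=mol, role=role))
        systems.append(MolecularSystem(atoms, box=box))
        i += 2 + n
    return systems


def write_sidecar(system: MolecularSystem, path: str | Path) -> None:
    rows = [
        {
            "index": i,
            "element": a.element,
            "mass": a.mass,
            "charge": a.charge,
            "role": a.role,
            "molecule_id": a.molecule_id,
        }
        for i, a in enumerate(system.atoms)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sidecar(path: str | Path) -> dict[int, tuple[float, float, str, int]]:
    df = pd.read_csv(path)
    return {
        int(r["index"]): (float(r["mass"]), float(r["charge"]), str(r["role"]), int(r["molecule_id"]))
        for _, r in df.iterrows()
    }


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    """Minimal PDB (HETATM records + CRYST1 when periodic)."""
    lines = []
    if system.box is not None:
        la, lb, lc = (float(np.linalg.norm(v)) for v in system.box)

        def ang(u, v):
            cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            return float(np.degrees(np.arccos(np.clip(cosv, -1, 1))))

        lines.append(
            f"CRYST1{la:9.3f}{lb:9.3f}{lc:9.3f}"
            f"{ang(system.box[1], system.box[2]):7.2f}"
            f"{ang(system.box[0], system.box[2]):7.2f}"
            f"{ang(system.box[0], system.box[1]):7.2f} P 1           1"
        )
    for i, a in enumerate(system.atoms, start=1):
        x, y, z = a.position
        res = {"crystal": "CRY", "organic": "ORG", "water": "HOH"}[a.role]
        lines.append(
            f"HETATM{i:5d} {a.element:<4s}{res:<3s}  {a.molecule_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_obj(shape: WulffShape, path: str | Path) -> None:
    """Wavefront OBJ export of a habit polyhedron (facets grouped by form)."""
    lines = ["# crystalhabit Wulff polyhedron"]
    for v in shape.vertices:
        lines.append(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
    for f in shape.facets:
        h = f["form"]
        lines.append(f"g form_{h.h}_{h.k}_{h.l}")
        lines.append("f " + " ".join(str(int(i) + 1) for i in f["vertex_indices"]))
    Path(path).write_text("\n".join(lines) + "\n")


def manifest_hash(paths: list[str | Path]) -> str:
    """SHA-256 over the contents of the given files (provenance manifest)."""
    digest = hashlib.sha256()
    for p in sorted(str(x) for x in paths):
        digest.update(Path(p).read_bytes())
    return digest.hexdigest()
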