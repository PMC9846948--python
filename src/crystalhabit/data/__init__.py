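"""Bundled editable reference tables for the Ca(Min)₂ case study.

``faces_vacuum.csv`` holds the five morphologically important faces of the
calcium minodronate crystal with their vacuum attachment energies;
``solvents.csv`` holds standard handbook properties (relative permittivity,
dipole moment in Debye, density in g/cm³, carbon count) of the nine polar
aprotic co-solvents.  Both are plain CSV and meant to be edited or replaced
by the user; nothing in the library hard-codes their values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..lattice import ATOMIC_MASSES, CrystalComposition, UnitCell

__all__ = [
    "vacuum_face_table_path",
    "solvent_table_path",
    "load_solvent_properties",
    "reported_cell",
    "optimized_cell",
    "ca_min_composition",
    "reference_side_ratios_250ul",
]


def _data_path(name: str):
    return resources.files(__package__) / name


def vacuum_face_table_path() -> str:
    """Path of the bundled vacuum face table (hkl, multiplicity, d_hkl, e_att)."""
    return str(_data_path("faces_vacuum.csv"))


def solvent_table_path() -> str:
    return str(_data_path("solvents.csv"))


def load_solvent_properties() -> list:
    from ..stats import SolventProperties

    df = pd.read_csv(solvent_table_path())
    return [
        SolventProperties(
            name=str(r["name"]),
            relative_permittivity=float(r["relative_permittivity"]),
            dipole_moment=float(r["dipole_moment"]),
            density=float(r["density"]),
            n_carbon=int(r["n_carbon"]),
        )
        for _, r in df.iterrows()
    ]


def reported_cell() -> UnitCell:
    """As-deposited Ca(Min)₂ cell (C2/c)."""
    return UnitCell(19.40, 9.78, 17.05, beta=106.44, space_group_symbol="C2/c")


def optimized_cell() -> UnitCell:
    """Force-field-optimized Ca(Min)₂ cell (C2/c)."""
    return UnitCell(19.27, 9.74, 17.05, beta=107.99, space_group_symbol="C2/c")


def ca_min_composition() -> CrystalComposition:
    """Z = 4 formula units of Ca(C₉H₁₁N₂O₇P₂)₂·5H₂O.

    One Ca²⁺, two singly deprotonated minodronate anions, two coordination
    plus three lattice waters per formula unit; molar mass assembled from the
    standard atomic weights.
    """
    m = ATOMIC_MASSES
    min_anion = 9 * m["C"] + 11 * m["H"] + 2 * m["N"] + 7 * m["O"] + 2 * m["P"]
    water = 2 * m["H"] + m["O"]
    molar_mass = m["Ca"] + 2 * min_anion + 5 * water
    return CrystalComposition(formula_units_per_cell=4, molar_mass=molar_mass)


def reference_side_ratios_250ul() -> dict[str, float]:
    """Synthetic reference (2 0 0)/(1 1 0) side ratios at 250 μL organic solvent.

    The experimental endpoints are the measured extremes (DEF 0.78, MEF 0.10);
    the intermediate values are synthetic, interpolated to follow the observed
    influence order DEF > DMAC > ace > NMP > DEAC > DMF > MeCN > DMSO > MEF.
    """
    return {
        "DEF": 0.78,
        "DMAC": 0.70,
        "ace": 0.62,
        "NMP": 0.54,
        "DEAC": 0.47,
        "DMF": 0.39,
        "MeCN": 0.31,
        "DMSO": 0.21,
        "MEF": 0.10,
    }
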