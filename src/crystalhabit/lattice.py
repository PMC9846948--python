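"""Unit-cell geometry: direct/reciprocal bases, interplanar spacings, density.

All formulas are implemented for a general triclinic cell; the monoclinic
special cases (b-unique, beta between a and c) fall out of the general
reciprocal-metric treatment.  Lengths are in Å, angles in degrees, volumes in
ų and densities in g/cm³ throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitCell",
    "MillerIndex",
    "CrystalComposition",
    "cell_volume",
    "d_spacing",
    "plane_unit_normal",
    "crystal_density",
    "classify_contact",
    "laue_class_from_space_group",
    "ATOMIC_MASSES",
]

#: 1 u in grams divided by 1e-24 (so that mass[u] * AMU_TO_G / V[ų] is g/cm³).
AMU_TO_G_PER_A3 = 1.66053906892

#: Standard atomic weights (u) for the elements handled by the package.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Br": 79.904, "I": 126.90,
}

_LAUE_CLASSES = (
    "-1", "2/m", "mmm", "4/m", "4/mmm", "-3", "-3m",
    "6/m", "6/mmm", "m-3", "m-3m",
)


class InvalidCellError(ValueError):
    """Raised when lattice parameters do not define a positive-definite metric."""


@dataclass(frozen=True)
class MillerIndex:
    """Miller indices (h k l) of a crystallographic plane family.

    Negative components are plain negative integers; overbar rendering is a
    presentation concern only.
    """

    h: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("Miller index (0 0 0) is not a plane")

    def as_array(self) -> np.ndarray:
        return np.array([self.h, self.k, self.l], dtype=float)

    def __neg__(self) -> "MillerIndex":
        return MillerIndex(-self.h, -self.k, -self.l)

    def __str__(self) -> str:
        return f"({self.h} {self.k} {self.l})"

    @classmethod
    def from_string(cls, text: str) -> "MillerIndex":
        """Parse 'h k l' (space separated, e.g. '2 0 -2')."""
        parts = text.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"expected three integers, got {text!r}")
        return cls(*(int(p) for p in parts))


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell.

    Parameters
    ----------
    a, b, c:
        Axial lengths in Å.
    alpha, beta, gamma:
        Interaxial angles in degrees (alpha between b and c, etc.).
    space_group_symbol:
        Optional Hermann-Mauguin symbol, e.g. ``"C2/c"``.
    laue_class:
        Optional Laue class; inferred from the space-group symbol when absent.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group_symbol: str | None = None
    laue_class: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise InvalidCellError("angles define a degenerate (non-positive-definite) metric")
        if self.laue_class is not None and self.laue_class not in _LAUE_CLASSES:
            raise ValueError(f"unknown Laue class {self.laue_class!r}")
        if self.laue_class is None and self.space_group_symbol is not None:
            object.__setattr__(
                self, "laue_class", laue_class_from_space_group(self.space_group_symbol)
            )

    # -- geometry -----------------------------------------------------------

    def direct_basis(self) -> np.ndarray:
        """Row matrix of the direct lattice vectors (a, b, c) in a Cartesian frame.

        Convention: a along x, b in the xy plane (standard crystallographic
        Cartesian setting).
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        ax = np.array([self.a, 0.0, 0.0])
        bx = np.array([self.b * cg, self.b * sg, 0.0])
        cx_x = self.c * cb
        cx_y = self.c * (ca - cb * cg) / sg
        cx_z2 = self.c * self.c - cx_x * cx_x - cx_y * cx_y
        if cx_z2 <= 0:
            raise InvalidCellError("degenerate metric while building basis")
        cx = np.array([cx_x, cx_y, math.sqrt(cx_z2)])
        return np.vstack([ax, bx, cx])

    def reciprocal_basis(self) -> np.ndarray:
        """Row matrix of the reciprocal lattice vectors a*, b*, c* (no 2π factor)."""
        return np.linalg.inv(self.direct_basis()).T

    @property
    def volume(self) -> float:
        return cell_volume(self)


@dataclass(frozen=True)
class CrystalComposition:
    """Cell contents for density calculations: Z formula units of molar mass M."""

    formula_units_per_cell: int
    molar_mass: float  # g/mol of one formula unit

    def __post_init__(self) -> None:
        if self.formula_units_per_cell < 1:
            raise ValueError("Z must be >= 1")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")


def laue_class_from_space_group(symbol: str) -> str:
    """Map a Hermann-Mauguin space-group symbol to its Laue class.

    Uses gemmi's space-group tables; covers every standard symbol (C2/c -> 2/m).
    """
    import gemmi

    sg = gemmi.SpaceGroup(symbol)
    system = sg.crystal_system_str()
    point_group = sg.point_group_hm()
    if system == "triclinic":
        return "-1"
    if system == "monoclinic":
        return "2/m"
    if system == "orthorhombic":
        return "mmm"
    if system == "tetragonal":
        return "4/mmm" if any(x in point_group for x in ("2", "m")) and point_group not in ("4", "-4", "4/m") else "4/m"
    if system == "trigonal":
        return "-3" if point_group in ("3", "-3") else "-3m"
    if system == "hexagonal":
        return "6/m" if point_group in ("6", "-6", "6/m") else "6/mmm"
    if system == "cubic":
        return "m-3" if point_group in ("23", "m-3") else "m-3m"
    raise ValueError(f"cannot infer Laue class for {symbol!r}")


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in ų.

    V = abc sqrt(1 - cos²α - cos²β - cos²γ + 2 cosα cosβ cosγ); for a b-unique
    monoclinic cell this reduces to abc sinβ.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise InvalidCellError("degenerate metric")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def d_spacing(cell: UnitCell, hkl: MillerIndex) -> float:
    """Interplanar spacing d_hkl in Å from the reciprocal metric.

    d = 1 / |h a* + k b* + l c*|, valid for any crystal system.
    """
    g = hkl.as_array() @ cell.reciprocal_basis()
    return 1.0 / float(np.linalg.norm(g))


def plane_unit_normal(cell: UnitCell, hkl: MillerIndex) -> np.ndarray:
    """Unit normal of the (h k l) plane: direction of h a* + k b* + l c*."""
    g = hkl.as_array() @ cell.reciprocal_basis()
    return g / np.linalg.norm(g)


def crystal_density(cell: UnitCell, comp: CrystalComposition) -> float:
    """Crystal density ρ = Z·M / (N_A·V) in g/cm³ (V in ų)."""
    return comp.formula_units_per_cell * comp.molar_mass * AMU_TO_G_PER_A3 / cell_volume(cell)


def classify_contact(distance: float, radius_1: float, radius_2: float) -> str:
    """Classify a metal–ligand contact as ionic or covalent/coordinate.

    A contact longer than the sum of the two ionic radii is labelled
    ``"ionic"``; at or below the radius sum it is ``"covalent/coordinate"``.
    The boundary itself (distance == radius sum) is not "above" the sum and so
    falls on the covalent/coordinate side.
    """
    if distance <= 0:
        raise ValueError("contact distance must be positive")
    if radius_1 <= 0 or radius_2 <= 0:
        raise ValueError("radii must be positive")
    return "ionic" if distance > radius_1 + radius_2 else "covalent/coordinate"
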