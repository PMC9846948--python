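"""Crystal habit prediction: form expansion, growth rates, Wulff construction.

The habit rule is the classical one for attachment-energy morphology: each
crystallographic form (h k l) is placed at a center-to-plane distance
proportional to its relative growth rate, R_hkl ∝ |E_att| (vacuum) or
R'_hkl ∝ |E_att − E_int| (solvent-modified), and the habit is the convex
polyhedron enclosed by all symmetry-equivalent planes.  Faces whose plane
falls entirely outside the intersection carry zero area ("absent" faces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .lattice import MillerIndex, UnitCell, plane_unit_normal

__all__ = [
    "FaceRecord",
    "WulffShape",
    "expand_form",
    "growth_rates_from_energies",
    "wulff_construct",
    "facet_area_fractions",
    "side_ratio",
]

# Representative (holohedral-setting) space group per Laue class; only the
# point-group part of its operations is used.
_LAUE_REPRESENTATIVE = {
    "-1": "P-1",
    "2/m": "P2/m",
    "mmm": "Pmmm",
    "4/m": "P4/m",
    "4/mmm": "P4/mmm",
    "-3": "P-3",
    "-3m": "P-3m1",
    "6/m": "P6/m",
    "6/mmm": "P6/mmm",
    "m-3": "Pm-3",
    "m-3m": "Pm-3m",
}


class UnboundedHabitError(ValueError):
    """The supplied face normals do not enclose a bounded polyhedron."""


@dataclass
class FaceRecord:
    """One crystallographic form in a habit prediction.

    Energies are in kcal/mol and negative by convention (energy released on
    attachment); ``growth_rate`` is a dimensionless relative rate and
    ``area_fraction`` a percentage of the total habit surface.
    """

    hkl: MillerIndex
    multiplicity: int | None = None
    d_hkl: float | None = None
    e_att: float | None = None
    e_int: float | None = None
    e_att_prime: float | None = None
    growth_rate: float | None = None
    area_fraction: float | None = None


def expand_form(cell: UnitCell, hkl: MillerIndex, laue_class: str | None = None) -> list[MillerIndex]:
    """Orbit of (h k l) under the Laue point group; its length is the multiplicity.

    The Laue class defaults to the one carried by the cell.  Friedel pairs are
    always included (every Laue group contains the inversion).
    """
    laue = laue_class or cell.laue_class
    if laue is None:
        raise ValueError("no Laue class given and none attached to the cell")
    if laue not in _LAUE_REPRESENTATIVE:
        raise ValueError(f"unsupported Laue class {laue!r}")
    ops = gemmi.SpaceGroup(_LAUE_REPRESENTATIVE[laue]).operations()
    seen: dict[tuple[int, int, int], None] = {}
    for op in ops:
        for triple in (op.apply_to_hkl([hkl.h, hkl.k, hkl.l]),):
            t = tuple(int(x) for x in triple)
            seen.setdefault(t, None)
            seen.setdefault(tuple(-x for x in t), None)  # Friedel mate
    return [MillerIndex(*t) for t in seen]


def growth_rates_from_energies(faces: list[FaceRecord], mode: str = "vacuum") -> list[FaceRecord]:
    """Relative growth rates from attachment energies, smallest normalized to 1.

    mode="vacuum" uses R ∝ |E_att|; mode="solvent" uses the modified rule
    R' ∝ |E_att − E_int| and requires ``e_int`` on every face.
    """
    if mode not in ("vacuum", "solvent"):
        raise ValueError(f"mode must be 'vacuum' or 'solvent', got {mode!r}")
    raw = []
    for f in faces:
        if f.e_att is None:
            raise ValueError(f"face {f.hkl} has no attachment energy")
        if mode == "vacuum":
            raw.append(abs(f.e_att))
        else:
            if f.e_int is None:
                raise ValueError(f"face {f.hkl} has no interaction energy (solvent mode)")
            raw.append(abs(f.e_att - f.e_int))
    smallest = min(raw)
    if smallest <= 0:
        raise ValueError("all growth rates must be positive")
    out = []
    for f, r in zip(faces, raw):
        e_prime = None if mode == "vacuum" else f.e_att - f.e_int
        out.append(replace(f, growth_rate=r / smallest, e_att_prime=e_prime))
    return out


@dataclass
class WulffShape:
    """Convex habit polyhedron.

    ``facets`` is a list of dicts with keys ``form`` (generating MillerIndex),
    ``hkl`` (concrete symmetry-equivalent index), ``normal``, ``distance``,
    ``vertex_indices`` (counter-clockwise seen from outside) and ``area``.
    The origin is the Wulff center and lies strictly inside.
    """

    vertices: np.ndarray
    facets: list[dict]
    forms: list[MillerIndex]

    @property
    def total_area(self) -> float:
        return sum(f["area"] for f in self.facets)

    @property
    def volume(self) -> float:
        # cone from origin over each facet
        total = 0.0
        for f in self.facets:
            total += f["distance"] * f["area"] / 3.0
        return total

    def form_area(self, form: MillerIndex) -> float:
        return sum(f["area"] for f in self.facets if f["form"] == form)

    def facet_polygons(self, form: MillerIndex | None = None) -> list[np.ndarray]:
        out = []
        for f in self.facets:
            if form is None or f["form"] == form:
                out.append(self.vertices[f["vertex_indices"]])
        return out

    def is_watertight(self, tol: float = 1e-8) -> bool:
        """Every edge of the facet cycle structure is shared by exactly two facets."""
        from collections import Counter

        edges: Counter = Counter()
        for f in self.facets:
            idx = f["vertex_indices"]
            for i, j in zip(idx, np.roll(idx, -1)):
                edges[frozenset((int(i), int(j)))] += 1
        return all(c == 2 for c in edges.values())


def _ordered_polygon(points_idx: np.ndarray, pts: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Order coplanar vertex indices counter-clockwise around the facet normal."""
    center = pts.mean(axis=0)
    # in-plane frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = pts - center
    ang = np.arctan2(rel @ v, rel @ u)
    return points_idx[np.argsort(ang)]


def _polygon_area(pts: np.ndarray) -> float:
    center = pts.mean(axis=0)
    area = 0.0
    n = len(pts)
    for i in range(n):
        area += 0.5 * np.linalg.norm(np.cross(pts[i] - center, pts[(i + 1) % n] - center))
    return float(area)


def wulff_construct(
    cell: UnitCell,
    faces: list[tuple[MillerIndex, float]],
    laue_class: str | None = None,
    merge_tol: float = 1e-8,
) -> WulffShape:
    """Wulff polyhedron from per-form center-to-plane distances.

    Each form is expanded by the Laue symmetry; the habit is the intersection
    {x : x·n ≤ d} over all expanded planes.  Facet areas are attributed to the
    generating form.  Raises :class:`UnboundedHabitError` when the expanded
    normals do not positively span 3-space.
    """
    if not faces:
        raise ValueError("no faces given")
    if any(d <= 0 for _, d in faces):
        raise ValueError("all distances must be positive")

    normals, distances, form_of, hkl_of = [], [], [], []
    for form, dist in faces:
        for eq in expand_form(cell, form, laue_class):
            n = plane_unit_normal(cell, eq)
            # same plane may be produced by two forms: keep the closer one
            dup = None
            for i, m in enumerate(normals):
                if np.dot(n, m) > 1.0 - 1e-10:
                    dup = i
                    break
            if dup is not None:
                if dist < distances[dup]:
                    distances[dup], form_of[dup], hkl_of[dup] = dist, form, eq
                continue
            normals.append(n)
            distances.append(dist)
            form_of.append(form)
            hkl_of.append(eq)
    normals_arr = np.array(normals)
    dist_arr = np.array(distances)

    if len(normals_arr) < 4:
        raise UnboundedHabitError("fewer than 4 independent halfspaces")
    # bounded iff the origin is strictly inside the convex hull of the normals
    try:
        hull = ConvexHull(normals_arr)
    except Exception as exc:  # degenerate (coplanar) normal set
        raise UnboundedHabitError("expanded normals do not span 3-space") from exc
    # hull.equations: n·x + b <= 0; origin strictly inside iff all b < 0
    if np.any(hull.equations[:, 3] >= -1e-12):
        raise UnboundedHabitError("unbounded habit: normals do not enclose the origin")

    halfspaces = np.hstack([normals_arr, -dist_arr[:, None]])
    hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    pts = hs.intersections

    # merge duplicate vertices
    scale = merge_tol * float(dist_arr.max())
    verts: list[np.ndarray] = []
    vert_index = np.empty(len(pts), dtype=int)
    for i, p in enumerate(pts):
        for j, q in enumerate(verts):
            if np.linalg.norm(p - q) < max(scale, 1e-9):
                vert_index[i] = j
                break
        else:
            vert_index[i] = len(verts)
            verts.append(p)
    vertices = np.array(verts)

    facets = []
    for i in range(len(normals_arr)):
        on_plane = np.abs(vertices @ normals_arr[i] - dist_arr[i]) < max(scale, 1e-9) * 10
        idx = np.nonzero(on_plane)[0]
        if len(idx) < 3:
            continue  # face absent from the habit
        ordered = _ordered_polygon(idx, vertices[idx], normals_arr[i])
        area = _polygon_area(vertices[ordered])
        if area <= scale**2:
            continue
        facets.append(
            {
                "form": form_of[i],
                "hkl": hkl_of[i],
                "normal": normals_arr[i],
                "distance": float(dist_arr[i]),
                "vertex_indices": ordered,
                "area": area,
            }
        )
    return WulffShape(vertices=vertices, facets=facets, forms=[f for f, _ in faces])


def facet_area_fractions(shape: WulffShape) -> dict[MillerIndex, float]:
    """Percent of total surface area per generating form (sums to 100).

    Forms whose planes lie outside the hull are reported with 0.0.
    """
    total = shape.total_area
    return {form: 100.0 * shape.form_area(form) / total for form in shape.forms}


def side_ratio(
    shape: WulffShape,
    form_a: MillerIndex,
    form_b: MillerIndex,
    method: str = "sqrt_area",
) -> float:
    """Characteristic edge-scale ratio of two forms (a habit aspect descriptor).

    Default is the scale-invariant √(mean single-facet area) ratio; alternative
    ``method="max_edge"`` uses the longest in-plane polygon edge of each form.
    """
    areas_a = [f["area"] for f in shape.facets if f["form"] == form_a]
    areas_b = [f["area"] for f in shape.facets if f["form"] == form_b]
    if not areas_a or not areas_b:
        missing = form_a if not areas_a else form_b
        raise ValueError(f"form {missing} is absent from the habit; side ratio undefined")
    if method == "sqrt_area":
        return math.sqrt(float(np.mean(areas_a))) / math.sqrt(float(np.mean(areas_b)))
    if method == "max_edge":

        def max_edge(form: MillerIndex) -> float:
            best = 0.0
            for poly in shape.facet_polygons(form):
                d = np.linalg.norm(poly - np.roll(poly, -1, axis=0), axis=1)
                best = max(best, float(d.max()))
            return best

        return max_edge(form_a) / max_edge(form_b)
    raise ValueError(f"unknown method {method!r}")
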