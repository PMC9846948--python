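"""Mass density profiles along the surface normal and peak/overlap diagnostics.

A trajectory is a :class:`FrameSet` of identical-roster snapshots; the profile
is the time-averaged histogram of atomic masses over z bins, converted to
g/cm³ using the (fixed) interface cross-section.  Peaks locate adsorption
layers; the overlap fraction measures how much of a layer's mass sits below
the crystal surface edge (solvent embedded in surface cavities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import MolecularSystem
from .lattice import AMU_TO_G_PER_A3

__all__ = ["FrameSet", "DensityProfile", "mass_density_profile", "peak_positions", "surface_overlap"]


@dataclass
class FrameSet:
    """Ordered trajectory frames with a constant atom roster.

    ``analysis_window`` selects the production part of the trajectory as a
    (start, end) frame-index pair; the default keeps the final quarter of the
    frames (the tail of the run, after equilibration).
    """

    frames: list[MolecularSystem]
    frame_interval: float = 1.0  # ps
    analysis_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty frame set")
        n0 = self.frames[0].n_atoms
        roster0 = self.frames[0].elements
        for f in self.frames[1:]:
            if f.n_atoms != n0 or f.elements != roster0:
                raise ValueError("frames must share an identical atom roster")

    def production_frames(self) -> list[MolecularSystem]:
        n = len(self.frames)
        if self.analysis_window is None:
            start, end = (3 * n) // 4, n
            if start >= end:
                start = 0
        else:
            start, end = self.analysis_window
        frames = self.frames[start:end]
        if not frames:
            raise ValueError("empty analysis window")
        return frames


@dataclass
class DensityProfile:
    """Per-role mass density (g/cm³) on a common z grid."""

    bin_edges: np.ndarray  # Å, length n_bins + 1
    density: dict[str, np.ndarray]  # role -> g/cm³ per bin
    cross_section: float  # Å²

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def integrated_mass(self, role: str) -> float:
        """Total mass (amu) represented by the profile for one role."""
        vol_per_bin = self.cross_section * self.bin_width  # ų
        return float(self.density[role].sum() * vol_per_bin / AMU_TO_G_PER_A3)


def mass_density_profile(
    frames: FrameSet,
    roles: tuple[str, ...] = ("crystal", "organic", "water"),
    bin_width: float = 0.5,
    cross_section: float | None = None,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Time-averaged mass density profile along z, one curve per role.

    The cross-section defaults to the in-plane box area of the first frame.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    production = frames.production_frames()
    first = production[0]
    if cross_section is None:
        if first.box is None:
            raise ValueError("no box on frames; pass cross_section explicitly")
        cross_section = float(abs(np.linalg.det(first.box[:2, :2])))

    if z_range is None:
        zmin = min(f.positions[:, 2].min() for f in production)
        zmax = max(f.positions[:, 2].max() for f in production)
    else:
        zmin, zmax = z_range
    n_bins = max(1, int(np.ceil((zmax - zmin) / bin_width)))
    edges = zmin + bin_width * np.arange(n_bins + 1)

    density = {role: np.zeros(n_bins) for role in roles}
    vol_per_bin = cross_section * bin_width
    for frame in production:
        z = frame.positions[:, 2]
        m = frame.masses
        frame_roles = np.array(frame.roles)
        for role in roles:
            sel = frame_roles == role
            if not sel.any():
                continue
            hist, _ = np.histogram(z[sel], bins=edges, weights=m[sel])
            density[role] += hist
    for role in roles:
        density[role] *= AMU_TO_G_PER_A3 / (vol_per_bin * len(production))
    return DensityProfile(bin_edges=edges, density=density, cross_section=cross_section)


def peak_positions(
    profile: DensityProfile, role: str, noise_floor_fraction: float = 0.10
) -> list[float]:
    """z positions of local density maxima above the noise floor, tallest first.

    The noise floor is a fraction of the curve's global maximum (default 10%).
    Plateau maxima report the plateau center.
    """
    rho = profile.density[role]
    if rho.max() <= 0:
        return []
    floor = noise_floor_fraction * rho.max()
    centers = profile.bin_centers
    width = profile.bin_width
    peaks: list[tuple[float, float]] = []  # (height, z)
    n = len(rho)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and rho[j + 1] == rho[i]:
            j += 1
        # an interior plateau flanked by strictly lower bins is a peak;
        # plateaus touching the window boundary are not (flat/monotone curves)
        if i > 0 and j < n - 1 and rho[i] > floor and rho[i] > rho[i - 1] and rho[i] > rho[j + 1]:
            z = 0.5 * (centers[i] + centers[j])
            if i == j:
                # parabolic sub-bin refinement through the three bins at the apex
                y0, y1, y2 = rho[i - 1], rho[i], rho[i + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    z += 0.5 * width * (y0 - y2) / denom
            peaks.append((float(rho[i]), float(z)))
        i = j + 1
    peaks.sort(key=lambda p: (-p[0], p[1]))
    return [z for _, z in peaks]


def surface_overlap(profile: DensityProfile, role: str, surface_edge_z: float) -> float:
    """Fraction of a role's mass lying below the crystal surface edge (z < edge).

    Bins straddling the edge contribute pro-rata.  Returns a value in [0, 1];
    0 for an all-zero profile.
    """
    rho = profile.density[role]
    total = rho.sum()
    if total <= 0:
        return 0.0
    edges = profile.bin_edges
    frac_below = np.clip((surface_edge_z - edges[:-1]) / profile.bin_width, 0.0, 1.0)
    return float(np.sum(rho * frac_below) / total)
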