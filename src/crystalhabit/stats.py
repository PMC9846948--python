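"""Side-ratio statistics: linear volume response, solvent ranking, correlations.

The morphology descriptor is the (2 0 0)/(1 1 0) side ratio of the grown
crystals; it responds roughly linearly to the volume of organic co-solvent,
so each solvent gets an ordinary-least-squares line, solvents are ranked by
the ratio they reach at a fixed volume, and the ratio is correlated against
bulk solvent properties (relative permittivity, dipole moment, density,
carbon count).  With only a handful of solvents the correlations are
reported as descriptive rank statistics; permutation p-values are opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SideRatioSeries",
    "SolventProperties",
    "LinearFit",
    "fit_linear",
    "rank_solvents",
    "property_correlations",
]


@dataclass(frozen=True)
class SideRatioSeries:
    """Side-ratio observations for one solvent at increasing organic volumes."""

    solvent: str
    volumes: tuple[float, ...]  # μL
    ratios: tuple[float, ...]  # dimensionless

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.ratios):
            raise ValueError("volumes and ratios must have equal length")
        if any(v < 0 for v in self.volumes):
            raise ValueError("volumes must be >= 0")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("side ratios must be positive")


@dataclass(frozen=True)
class SolventProperties:
    """Bulk properties of one organic solvent."""

    name: str
    relative_permittivity: float
    dipole_moment: float  # Debye
    density: float  # g/cm³
    n_carbon: int

    def __post_init__(self) -> None:
        if min(self.relative_permittivity, self.dipole_moment, self.density) <= 0:
            raise ValueError("solvent properties must be positive")
        if self.n_carbon < 0:
            raise ValueError("carbon count must be >= 0")


@dataclass(frozen=True)
class LinearFit:
    slope: float  # per μL
    intercept: float
    r_squared: float
    slope_stderr: float
    n_obs: int


def fit_linear(series: SideRatioSeries) -> LinearFit:
    """OLS fit of side ratio against organic volume."""
    v = np.asarray(series.volumes, dtype=float)
    r = np.asarray(series.ratios, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(v) == 0:
        raise ValueError("volumes have zero variance")
    model = sm.OLS(r, sm.add_constant(v)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared) if np.var(r) > 0 else 0.0,
        slope_stderr=float(model.bse[1]),
        n_obs=len(v),
    )


def rank_solvents(ratios_at_fixed_volume: dict[str, float]) -> tuple[list[str], list[str]]:
    """Solvents in descending side-ratio order (strongest influence first).

    Returns (ordered names, tie notes).  Ties are broken alphabetically and
    reported in the notes list.
    """
    if not ratios_at_fixed_volume:
        raise ValueError("empty ratio map")
    items = sorted(ratios_at_fixed_volume.items(), key=lambda kv: (-kv[1], kv[0]))
    notes = []
    by_value: dict[float, list[str]] = {}
    for name, val in items:
        by_value.setdefault(val, []).append(name)
    for val, names in by_value.items():
        if len(names) > 1:
            notes.append(f"tie at ratio {val}: {', '.join(names)} ordered alphabetically")
    return [name for name, _ in items], notes


def property_correlations(
    ratios: dict[str, float],
    props: list[SolventProperties],
    n_permutations: int = 0,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Rank (Spearman) and linear (Pearson) correlation of side ratio vs each property.

    Returns ``{property: {"spearman": ρ, "pearson": r, "sign": ±1[, "perm_p": p]}}``.
    Permutation p-values (two-sided, on |Spearman ρ|) are computed only when
    ``n_permutations`` > 0.
    """
    by_name = {p.name: p for p in props}
    unmatched = sorted(set(ratios) - set(by_name))
    if unmatched:
        raise ValueError(f"no properties for solvents: {', '.join(unmatched)}")
    names = sorted(ratios)
    if len(names) < 3:
        raise ValueError("need at least 3 matched solvents")
    y = np.array([ratios[n] for n in names])
    columns = {
        "relative_permittivity": np.array([by_name[n].relative_permittivity for n in names]),
        "dipole_moment": np.array([by_name[n].dipole_moment for n in names]),
        "density": np.array([by_name[n].density for n in names]),
        "n_carbon": np.array([float(by_name[n].n_carbon) for n in names]),
    }
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    for prop, x in columns.items():
        rho = float(sps.spearmanr(x, y).statistic)
        pear = float(sps.pearsonr(x, y).statistic) if np.ptp(x) > 0 else float("nan")
        entry = {"spearman": rho, "pearson": pear, "sign": float(np.sign(rho))}
        if n_permutations > 0:
            null = np.empty(n_permutations)
            for i in range(n_permutations):
                null[i] = abs(sps.spearmanr(x, rng.permutation(y)).statistic)
            entry["perm_p"] = float((np.sum(null >= abs(rho)) + 1) / (n_permutations + 1))
        out[prop] = entry
    return out
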