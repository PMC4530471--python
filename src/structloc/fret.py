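"""FRET: acceptor-photobleach efficiencies and Förster distance conversion.

Transfer efficiency from donor intensities before/after acceptor
photobleaching:

    E = 1 - F_prebleach / F_postbleach

and the sixth-power Förster relation between efficiency and donor-acceptor
separation R, with pair-specific Förster distance R0 (59 Å for AF488/Cy3NTA):

    R = R0 * (1/E - 1)^(1/6),      E = 1 / (1 + (R/R0)^6)

All operations are pure functions. Negative measured efficiencies (no
detectable transfer) are returned as computed with a warning flag and are
excluded when building distance constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_FORSTER_RADIUS


@dataclass
class FretMeasurement:
    """Donor fluorescence before/after acceptor photobleaching at one site."""

    donor_site: str
    f_prebleach: float
    f_postbleach: float
    n_cells: int = 1
    sem_efficiency: float | None = None

    def __post_init__(self):
        if self.f_prebleach < 0 or self.f_postbleach < 0:
            raise ValueError("intensities must be non-negative")
        if self.f_postbleach <= 0:
            raise ZeroDivisionError("f_postbleach must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class DistanceConstraint:
    """A donor position plus FRET-derived distance with uncertainty."""

    donor_coord: np.ndarray
    distance: float
    uncertainty: float = 0.0
    donor_site: str = ""

    def __post_init__(self):
        self.donor_coord = np.asarray(self.donor_coord, dtype=float)
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def fret_efficiency(measurement: FretMeasurement) -> float:
    """E = 1 - F_pre/F_post; may be <= 0 for noisy data (warned, not raised)."""
    e = 1.0 - measurement.f_prebleach / measurement.f_postbleach
    if e <= 0:
        warnings.warn(
            f"non-positive FRET efficiency {e:.3f} at {measurement.donor_site!r} "
            "(no detectable transfer)", stacklevel=2)
    return e


def efficiency_to_distance(efficiency: float,
                           forster_radius: float = DEFAULT_FORSTER_RADIUS) -> float:
    """R = R0 * (1/E - 1)^(1/6) for E in (0, 1]; E = 1 maps to R = 0."""
    if forster_radius <= 0:
        raise ValueError("forster_radius must be positive")
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(f"efficiency {efficiency} outside (0, 1]: distance undefined")
    if efficiency == 1.0:
        return 0.0
    return float(forster_radius * (1.0 / efficiency - 1.0) ** (1.0 / 6.0))


def distance_to_efficiency(distance: float,
                           forster_radius: float = DEFAULT_FORSTER_RADIUS) -> float:
    """E = 1 / (1 + (R/R0)^6); inverse of efficiency_to_distance on (0, 1]."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if forster_radius <= 0:
        raise ValueError("forster_radius must be positive")
    return float(1.0 / (1.0 + (distance / forster_radius) ** 6))


def propagate_distance_uncertainty(efficiency: float, sem_efficiency: float,
                                   forster_radius: float = DEFAULT_FORSTER_RADIUS) -> float:
    """First-order uncertainty |dR/dE| * sem of the converted distance."""
    if not 0.0 < efficiency < 1.0:
        raise ValueError("efficiency must be strictly inside (0, 1) for propagation")
    if sem_efficiency < 0:
        raise ValueError("sem must be non-negative")
    drde = (forster_radius / 6.0) * (1.0 / efficiency - 1.0) ** (-5.0 / 6.0) / efficiency**2
    return float(abs(drde) * sem_efficiency)


def measurements_to_constraints(
    measurements: list[FretMeasurement],
    donor_coords: dict[str, np.ndarray],
    forster_radius: float = DEFAULT_FORSTER_RADIUS,
    average: str = "efficiency",
) -> list[DistanceConstraint]:
    """Convert per-site measurement groups to distance constraints.

    Measurements sharing a donor_site are grouped; per-cell efficiencies are
    averaged first and the mean converted to one distance per site
    (``average='efficiency'``, the default), or each cell's efficiency is
    converted and the distances averaged (``average='distance'``). Sites with
    non-positive mean efficiency yield no constraint.
    """
    if average not in ("efficiency", "distance"):
        raise ValueError("average must be 'efficiency' or 'distance'")
    groups: dict[str, list[FretMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.donor_site, []).append(m)
    constraints = []
    for site, group in groups.items():
        if site not in donor_coords:
            raise KeyError(f"no donor coordinate for site {site!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            effs = np.array([fret_efficiency(m) for m in group])
        if average == "efficiency":
            e_mean = float(effs.mean())
            if e_mean <= 0 or e_mean > 1:
                warnings.warn(f"site {site!r}: mean efficiency {e_mean:.3f} out of "
                              "range, constraint dropped", stacklevel=2)
                continue
            dist = efficiency_to_distance(e_mean, forster_radius)
            sem = float(effs.std(ddof=1) / np.sqrt(len(effs))) if len(effs) > 1 else 0.0
            unc = (propagate_distance_uncertainty(e_mean, sem, forster_radius)
                   if 0 < e_mean < 1 and sem > 0 else 0.0)
        else:
            valid = effs[(effs > 0) & (effs <= 1)]
            if valid.size == 0:
                continue
            dists = np.array([efficiency_to_distance(e, forster_radius) for e in valid])
            dist = float(dists.mean())
            unc = float(dists.std(ddof=1) / np.sqrt(len(dists))) if len(dists) > 1 else 0.0
        constraints.append(DistanceConstraint(
            donor_coord=donor_coords[site], distance=dist,
            uncertainty=unc, donor_site=site))
    return constraints
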