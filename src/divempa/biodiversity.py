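"""Weighted biodiversity-persistence score under protection scenarios.

The score is the weighted sum over species of a persistence value that grows as
more of the species' native range is placed under full/high protection and the
abatable (fishing) share of its impact is removed.  A score of 1 means all
species are free from any threats.  The persistence functional form used here,

    persistence(p) = (1 - q * (1 - p) - u) ** z,

with ``p`` the fully/highly-protected fraction of the range, ``q`` the abatable
impact share, ``u`` an optional unabatable impact share, and concavity exponent
``z`` (default 0.25), is this package's documented reconstruction of the
conservation-planning persistence curves this family of MPA models builds on;
both ``z`` and the function itself are pluggable.
"""
from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

#: Printed aggregate taxon weights (shares of the total biodiversity weight).
DEFAULT_TAXON_WEIGHTS: dict[str, float] = {
    "Elasmobranchii": 0.340,
    "Actinopterygii": 0.273,
    "Anthozoa": 0.165,
    "birds": 0.052,
    "mammals": 0.050,
    "Malacostraca": 0.038,
    "cephalopods": 0.021,
    "other": 0.061,
}

DEFAULT_Z = 0.25


def species_persistence(p, q, z: float = DEFAULT_Z, u=0.0):
    """Persistence in [0, 1] of one species (vectorised).

    Parameters
    ----------
    p : protected fraction of the species' range under full/high protection.
    q : abatable share of the species' impact (removable by MPAs).
    z : concavity exponent of the persistence curve.
    u : unabatable impact share retained regardless of protection.
    """
    p, q, u = (np.asarray(x, dtype=float) for x in (p, q, u))
    for name, x in (("p", p), ("q", q), ("u", u)):
        if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
            raise ValueError(f"{name} must lie in [0, 1]")
    base = np.clip(1.0 - q * (1.0 - p) - u, 0.0, 1.0)
    out = base ** z
    return float(out) if out.ndim == 0 else out


def assign_species_weights(
    species: pd.DataFrame, taxon_table: Mapping[str, float] | None = None
) -> np.ndarray:
    """Per-species weights: uniform within taxa, aggregates matching the table.

    Species with a taxon absent from the table are mapped to ``"other"``.
    Table entries for taxa with no species present are renormalized away so
    weights still sum to 1.
    """
    table = dict(taxon_table or DEFAULT_TAXON_WEIGHTS)
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"taxon weights must sum to 1 (got {total})")
    taxa = species["taxon_group"].where(
        species["taxon_group"].isin(table), other="other")
    counts = taxa.value_counts()
    present_total = sum(table[t] for t in counts.index)
    w = np.array([table[t] / counts[t] / present_total for t in taxa])
    return w


def protected_fractions(
    species_ranges: pd.DataFrame, protected_pixels: set[int] | np.ndarray
) -> pd.Series:
    """Fraction of each species' range inside fully/highly protected pixels."""
    protected = set(int(p) for p in protected_pixels)
    inside = species_ranges["pixel_id"].isin(protected)
    grp = species_ranges.assign(inside=inside).groupby("species_id")["inside"]
    return grp.mean()


def biodiversity_score(
    species: pd.DataFrame,
    species_ranges: pd.DataFrame,
    protected_pixels,
    z: float = DEFAULT_Z,
    persistence_fn: Callable | None = None,
) -> float:
    """Weighted biodiversity score in [0, 1] for one protection scenario.

    ``protected_pixels`` is the set of fully/highly protected pixels under the
    scenario (the tourism benefits modelled here are unique to full/high
    protection).  An empty species set scores 0.
    """
    if len(species) == 0:
        return 0.0
    w = species["weight"].to_numpy(float)
    s = w.sum()
    if abs(s - 1.0) > 1e-9:
        w = w / s
    p = protected_fractions(species_ranges, protected_pixels)
    p = p.reindex(species["species_id"]).fillna(0.0).to_numpy()
    q = species["q_abatable"].to_numpy(float)
    u = species.get("u_unabatable", pd.Series(0.0, index=species.index)).to_numpy(float)
    fn = persistence_fn or (lambda p_, q_, u_: species_persistence(p_, q_, z=z, u=u_))
    # weight normalization can leave the sum a few ulp above 1
    return float(np.clip(np.sum(w * fn(p, q, u)), 0.0, 1.0))


def delta_score(
    species: pd.DataFrame,
    species_ranges: pd.DataFrame,
    bau_protected,
    scenario_protected,
    z: float = DEFAULT_Z,
) -> tuple[float, float, float]:
    """(BAU score, scenario score, gain) for a protection upgrade."""
    bau = biodiversity_score(species, species_ranges, bau_protected, z=z)
    new = biodiversity_score(species, species_ranges, scenario_protected, z=z)
    return bau, new, new - bau
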