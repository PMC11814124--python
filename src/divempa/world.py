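"""Spatial grid, protection-status rules, dive-price allocation, and world-bundle I/O.

The model world is an abstract lattice of ~50 km x 50 km ocean pixels identified by
integer ids, with great-circle distances between pixel centroids.  No projection or
CRS machinery is used: the biology and economics only ever need centroid distances
and nominal pixel areas, which are carried as data.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

EARTH_RADIUS_KM = 6371.0


class Protection(str, enum.Enum):
    """MPA protection classes, ordered from strongest to weakest."""

    FULLY_HIGHLY = "fully_highly"
    LESS_UNKNOWN = "less_unknown"
    DESIGNATED_UNIMPLEMENTED = "designated_unimplemented"
    PROPOSED_COMMITTED = "proposed_committed"
    UNPROTECTED = "unprotected"


#: numeric rank; higher = stronger protection
PROTECTION_RANK: dict[Protection, int] = {
    Protection.FULLY_HIGHLY: 4,
    Protection.LESS_UNKNOWN: 3,
    Protection.DESIGNATED_UNIMPLEMENTED: 2,
    Protection.PROPOSED_COMMITTED: 1,
    Protection.UNPROTECTED: 0,
}


class WorldError(ValueError):
    """Invalid world data or configuration."""


class WorldIOError(WorldError):
    """Schema problem while reading or writing a world bundle."""


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance (km) between points given in decimal degrees.

    Vectorised over numpy broadcasting rules.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


PIXEL_COLUMNS = [
    "pixel_id",
    "centroid_lon",
    "centroid_lat",
    "area_km2",
    "is_ocean",
    "has_diving",
    "protection_status",
    "region_label",
    "country_label",
    "dives",
]


@dataclass
class GridWorld:
    """Pixel lattice with geometry, ocean/dive masks and protection status.

    ``pixels`` is one row per pixel with the columns in :data:`PIXEL_COLUMNS`.
    ``dives`` is the annual number of recreational dives made in the pixel
    (zero outside dive pixels).
    """

    pixels: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PIXEL_COLUMNS if c not in self.pixels.columns]
        if missing:
            raise WorldIOError(f"pixel table missing required column(s): {missing}")
        px = self.pixels
        if px["pixel_id"].duplicated().any():
            raise WorldError("pixel ids must be unique")
        bad = px["has_diving"].astype(bool) & ~px["is_ocean"].astype(bool)
        if bad.any():
            raise WorldError(f"{int(bad.sum())} dive pixel(s) are not ocean")
        dive = px[px["has_diving"].astype(bool)]
        if dive["region_label"].isna().any():
            raise WorldError("every dive pixel needs a region label")
        self.pixels = px.reset_index(drop=True)
        self._index = pd.Index(self.pixels["pixel_id"].to_numpy())

    # -- accessors -----------------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def ocean_ids(self) -> np.ndarray:
        return self.pixels.loc[self.pixels["is_ocean"].astype(bool), "pixel_id"].to_numpy()

    @property
    def dive_ids(self) -> np.ndarray:
        return self.pixels.loc[self.pixels["has_diving"].astype(bool), "pixel_id"].to_numpy()

    def rows(self, pixel_ids: Iterable[int]) -> pd.DataFrame:
        idx = self._index.get_indexer(np.asarray(list(pixel_ids)))
        if (idx < 0).any():
            unknown = np.asarray(list(pixel_ids))[idx < 0]
            raise KeyError(f"unknown pixel id(s): {unknown[:5].tolist()}")
        return self.pixels.iloc[idx]

    def distance(self, i: int, j: int) -> float:
        """Great-circle distance d(j->i) in km between pixel centroids."""
        r = self.rows([i, j])
        lon = r["centroid_lon"].to_numpy()
        lat = r["centroid_lat"].to_numpy()
        return float(haversine_km(lon[0], lat[0], lon[1], lat[1]))

    def distance_matrix(self, pixel_ids: Iterable[int]) -> np.ndarray:
        """Symmetric matrix of centroid distances (km) for the given pixels."""
        r = self.rows(pixel_ids)
        lon = r["centroid_lon"].to_numpy()
        lat = r["centroid_lat"].to_numpy()
        return np.asarray(
            haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        )

    def status_of(self, pixel_ids: Iterable[int]) -> pd.Series:
        r = self.rows(pixel_ids)
        return pd.Series(r["protection_status"].to_numpy(), index=r["pixel_id"].to_numpy())


# ---------------------------------------------------------------------------
# Protection classification
# ---------------------------------------------------------------------------

def _validate_fraction(f: float) -> float:
    f = float(f)
    if not (0.0 <= f <= 1.0) or not np.isfinite(f):
        raise WorldError(f"coverage fraction {f} outside [0, 1]")
    return f


def classify_pixel_protection(
    coverage: Mapping[str, float] | pd.DataFrame,
    threshold: float = 0.5,
) -> Protection:
    """Protection status of one pixel from per-designation area fractions.

    A pixel is ``fully_highly`` iff the summed fully/highly-protected area
    fraction is at least ``threshold`` (default one half of the pixel).
    Otherwise the highest-ranked non-fully designation with positive coverage
    wins; a pixel with no positive coverage is ``unprotected``.  Sub-threshold
    fully/highly coverage on its own does not confer a status.
    """
    if isinstance(coverage, pd.DataFrame):
        frac = coverage.groupby("designation")["fraction"].sum().to_dict()
    else:
        frac = dict(coverage)
    frac = {Protection(k): _validate_fraction(v) for k, v in frac.items()}
    if frac.get(Protection.FULLY_HIGHLY, 0.0) >= threshold:
        return Protection.FULLY_HIGHLY
    present = [
        s for s, f in frac.items()
        if f > 0.0 and s not in (Protection.FULLY_HIGHLY, Protection.UNPROTECTED)
    ]
    if not present:
        return Protection.UNPROTECTED
    return max(present, key=PROTECTION_RANK.__getitem__)


def classify_site_protection(
    designations: Iterable[tuple[str | Protection, int]],
) -> tuple[Protection, int | None]:
    """Resolve overlapping designations at a single dive site.

    The designation conferring the highest protection wins; among equals the
    oldest designation year wins.  An empty list means unprotected.
    """
    items = [(Protection(c), int(y)) for c, y in designations]
    if not items:
        return Protection.UNPROTECTED, None
    status, year = min(items, key=lambda cy: (-PROTECTION_RANK[cy[0]], cy[1]))
    return status, year


def apply_protection(
    world: GridWorld, coverage: pd.DataFrame, threshold: float = 0.5
) -> GridWorld:
    """Return a world whose ``protection_status`` is derived from coverage."""
    status = pd.Series(Protection.UNPROTECTED.value, index=world.pixels["pixel_id"])
    for pid, grp in coverage.groupby("pixel_id"):
        status.loc[pid] = classify_pixel_protection(grp, threshold=threshold).value
    px = world.pixels.copy()
    px["protection_status"] = status.to_numpy()
    return GridWorld(px)


# ---------------------------------------------------------------------------
# Price allocation
# ---------------------------------------------------------------------------

PRICE_SCHEMES = ("global_median", "country_median", "interpolated")


def allocate_prices(
    observations: pd.DataFrame,
    world: GridWorld,
    scheme: str = "global_median",
    idw_power: float = 2.0,
) -> pd.Series:
    """Allocate a per-dive price (USD) to every ocean pixel.

    Three allocation schemes mirror the study's sensitivity axes:

    ``global_median``
        every ocean pixel takes the global median observed price;
    ``country_median``
        pixels take the median over operators in the pixel's country, falling
        back to the global median for countries without observations;
    ``interpolated``
        per-pixel medians are spread to all ocean pixels by inverse-distance
        weighting (power ``idw_power``); pixels with their own observations
        keep their own median.
    """
    if scheme not in PRICE_SCHEMES:
        raise WorldError(f"unknown price scheme {scheme!r}; choose from {PRICE_SCHEMES}")
    if len(observations) == 0:
        raise WorldError("price allocation needs at least one observation")
    prices = observations["price_per_dive"].astype(float)
    if (prices <= 0).any():
        raise WorldError("observed prices must be positive")
    ocean = world.ocean_ids
    global_median = float(np.median(prices.to_numpy()))

    if scheme == "global_median":
        return pd.Series(global_median, index=ocean, name="price_per_dive")

    if scheme == "country_median":
        op_rows = world.rows(observations["pixel_id"])
        by_country = (
            observations.assign(country=op_rows["country_label"].to_numpy())
            .groupby("country")["price_per_dive"]
            .median()
        )
        countries = world.rows(ocean)["country_label"].to_numpy()
        out = np.array([by_country.get(c, global_median) for c in countries], dtype=float)
        return pd.Series(out, index=ocean, name="price_per_dive")

    # interpolated
    pix_median = observations.groupby("pixel_id")["price_per_dive"].median()
    src = world.rows(pix_median.index)
    dst = world.rows(ocean)
    d = haversine_km(
        dst["centroid_lon"].to_numpy()[:, None],
        dst["centroid_lat"].to_numpy()[:, None],
        src["centroid_lon"].to_numpy()[None, :],
        src["centroid_lat"].to_numpy()[None, :],
    )
    w = 1.0 / np.maximum(d, 1e-9) ** idw_power
    vals = (w * pix_median.to_numpy()[None, :]).sum(axis=1) / w.sum(axis=1)
    out = pd.Series(vals, index=ocean, name="price_per_dive")
    # pixels that host observations keep their own median exactly
    out.loc[pix_median.index] = pix_median.to_numpy()
    return out


# ---------------------------------------------------------------------------
# World bundle I/O
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["pixel_id", "designation", "fraction", "year"]
PRICE_COLUMNS = ["operator_id", "pixel_id", "price_per_dive"]
STOCK_COLUMNS = [
    "stock_id", "r", "K", "length_cm", "trophic_level", "movement_keyword",
    "is_elasmobranch", "depletion", "range_size",
    "home_range_true", "pld_true", "home_range_emp", "pld_emp", "is_empirical",
]
STOCK_RANGE_COLUMNS = ["stock_id", "pixel_id"]
SPECIES_COLUMNS = ["species_id", "taxon_group", "weight", "q_abatable", "u_unabatable"]
SPECIES_RANGE_COLUMNS = ["species_id", "pixel_id"]


@dataclass
class WorldBundle:
    """Everything a scenario run consumes: grid, coverage, prices, biology."""

    world: GridWorld
    coverage: pd.DataFrame
    prices: pd.DataFrame
    stocks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STOCK_COLUMNS))
    stock_ranges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STOCK_RANGE_COLUMNS))
    species: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPECIES_COLUMNS))
    species_ranges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SPECIES_RANGE_COLUMNS))
    config: dict = field(default_factory=dict)

    def range_pixels(self, table: str, key: str, ident) -> np.ndarray:
        ranges = self.stock_ranges if table == "stock" else self.species_ranges
        return ranges.loc[ranges[key] == ident, "pixel_id"].to_numpy()


_TABLES = {
    "pixels.csv": PIXEL_COLUMNS,
    "coverage.csv": COVERAGE_COLUMNS,
    "prices.csv": PRICE_COLUMNS,
    "stocks.csv": STOCK_COLUMNS,
    "stock_ranges.csv": STOCK_RANGE_COLUMNS,
    "species.csv": SPECIES_COLUMNS,
    "species_ranges.csv": SPECIES_RANGE_COLUMNS,
}


def write_world(path: str | Path, bundle: WorldBundle) -> Path:
    """Write a bundle as a directory of CSV tables plus a YAML config."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = {
        "pixels.csv": bundle.world.pixels,
        "coverage.csv": bundle.coverage,
        "prices.csv": bundle.prices,
        "stocks.csv": bundle.stocks,
        "stock_ranges.csv": bundle.stock_ranges,
        "species.csv": bundle.species,
        "species_ranges.csv": bundle.species_ranges,
    }
    for name, df in frames.items():
        df.to_csv(path / name, index=False)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    return path


def _read_table(path: Path, name: str, required: list[str]) -> pd.DataFrame:
    fp = path / name
    if not fp.exists():
        raise WorldIOError(f"bundle at {path} is missing table {name}")
    df = pd.read_csv(fp)
    for col in required:
        if col not in df.columns:
            raise WorldIOError(f"{name}: missing required column '{col}'")
    # unknown extra columns are preserved and otherwise ignored
    return df


def read_world(path: str | Path) -> WorldBundle:
    """Read a bundle written by :func:`write_world` (round-trip identity)."""
    path = Path(path)
    tables = {name: _read_table(path, name, cols) for name, cols in _TABLES.items()}
    cfg_path = path / "config.yaml"
    config = {}
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh) or {}
    return WorldBundle(
        world=GridWorld(tables["pixels.csv"]),
        coverage=tables["coverage.csv"],
        prices=tables["prices.csv"],
        stocks=tables["stocks.csv"],
        stock_ranges=tables["stock_ranges.csv"],
        species=tables["species.csv"],
        species_ranges=tables["species_ranges.csv"],
        config=config,
    )
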