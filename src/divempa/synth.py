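"""Seeded synthetic worlds: grids, MPAs, dive counts, prices, stocks, species.

The generators emulate the statistical structure of the study inputs — clustered
coastal dive pixels covering ~1.2% of the ocean, 67.35% of dive sites inside MPAs
with 15.48% fully/highly protected, heavy-tailed dive counts summing to a global
total scaled from 33.1 million marine dives per year, lognormal dive prices with a
US$58.75 median, and fish stocks with log-linear trait ground truth — so that every
downstream stage can be exercised and tested without any external data.

All generators are pure functions of (config, seed).  Per-generator random streams
are derived from one master seed with fixed ``spawn_key`` offsets
(0 = world, 1 = stocks, 2 = species), so adding one generator never perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri

from . import biodiversity
from .traits import trait_features
from .world import (
    GridWorld,
    Protection,
    WorldBundle,
    WorldError,
    apply_protection,
)

DEG_PER_PIXEL = 50.0 / 111.1949  # ~50 km at the equator

#: number of 50 km x 50 km dive pixels in the real study (4.54e6 km^2 / 2500 km^2);
#: used to scale the 33.1e6 global marine dives down to synthetic worlds.
REFERENCE_DIVE_PIXELS = 1816
REFERENCE_MARINE_DIVES = 33.1e6


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (sums exactly)."""
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be nonnegative")
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


@dataclass
class TraitCoefficients:
    """Log-linear generative model linking stock features to dispersal traits.

    ``log(trait) = intercept + sum_k coef_k * feature_k``; features are
    log r, log K, log length, trophic level, movement keyword (ordered integer),
    and log range size (pixels).  Chosen so home ranges span ~10^2–10^4 km^2
    (adult radii of ~15–100 km around the 50 km pixel scale) and PLDs span
    ~10–60 days.
    """

    home_range: dict = field(default_factory=lambda: {
        "intercept": -2.5, "log_r": -0.2, "log_K": 0.1, "log_length": 1.6,
        "trophic_level": 0.3, "movement_keyword": 2.0, "log_range_size": 0.3,
    })
    pld: dict = field(default_factory=lambda: {
        "intercept": 1.0, "log_r": -0.3, "log_K": 0.05, "log_length": 0.3,
        "trophic_level": 0.1, "movement_keyword": 0.1, "log_range_size": 0.0,
    })


def trait_generative_model(stocks: pd.DataFrame, coeffs: dict) -> np.ndarray:
    """Evaluate ``exp(intercept + X @ beta)`` for one trait."""
    X = trait_features(stocks)
    log_trait = np.full(len(X), float(coeffs["intercept"]))
    for name, beta in coeffs.items():
        if name == "intercept":
            continue
        log_trait += float(beta) * X[name].to_numpy()
    return np.exp(log_trait)


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

@dataclass
class WorldGenConfig:
    """Study conditions for a synthetic world.

    MPA targets, dive-pixel share, price median and the per-pixel dive
    intensity default to the global figures of the study they emulate.
    """

    nx: int = 40
    ny: int = 40
    ocean_fraction: float = 0.66
    dive_fraction: float = 0.012          # share of ocean pixels with diving
    mpa_fraction: float = 0.6735          # dive pixels inside any MPA
    fully_fraction: float = 0.1548        # dive pixels fully/highly protected
    total_dives: float | None = None      # None -> scaled from 33.1e6
    price_median: float = 58.75           # USD per dive
    price_sigma: float = 0.5              # lognormal log-sd of prices
    n_operators: int = 600
    dive_sigma: float = 1.5               # lognormal log-sd of per-pixel dives
    land_smoothing: float = 3.0           # pixels; controls coastline scale
    coastal_decay: float = 2.0            # pixels; dive-site distance-to-coast decay
    cluster_strength: float = 1.5
    n_regions: int = 5
    n_countries: int = 8
    ocean_mpa_rate: float = 0.05          # non-dive ocean pixels with weak MPAs
    ocean_fully_rate: float = 0.01        # non-dive ocean pixels fully protected
    seed: int = 0

    def validate(self) -> None:
        for name in ("ocean_fraction", "dive_fraction", "mpa_fraction", "fully_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise WorldError(f"{name}={v} outside [0, 1]")
        if self.fully_fraction > self.mpa_fraction:
            raise WorldError("fully/highly target cannot exceed overall MPA target")
        if self.dive_fraction > self.ocean_fraction:
            raise WorldError("dive-pixel fraction cannot exceed ocean fraction")
        if self.price_median <= 0:
            raise WorldError("price median must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_world(config: WorldGenConfig) -> WorldBundle:
    """Generate grid, protection coverage, price observations, and dive counts."""
    config.validate()
    rng = _rng(config.seed, 0)
    nx, ny = config.nx, config.ny
    n = nx * ny

    # --- land/ocean: threshold a smoothed Gaussian field ---------------------
    if config.ocean_fraction >= 1.0:
        ocean = np.ones((ny, nx), dtype=bool)
    else:
        fieldv = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), config.land_smoothing)
        cut = np.quantile(fieldv, config.ocean_fraction)
        ocean = fieldv <= cut

    rows, cols = np.divmod(np.arange(n), nx)
    lat = (rows - (ny - 1) / 2.0) * DEG_PER_PIXEL
    lon = (cols - (nx - 1) / 2.0) * DEG_PER_PIXEL
    ocean_flat = ocean.ravel()

    # --- dive pixels: clustered near the coast ------------------------------
    n_ocean = int(ocean_flat.sum())
    n_dive = int(round(config.dive_fraction * n_ocean))
    dive_flat = np.zeros(n, dtype=bool)
    if n_dive > 0:
        if ocean.all():
            dist_land = np.ones((ny, nx))
        else:
            dist_land = ndimage.distance_transform_cdt(ocean, metric="taxicab")
        cluster = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), 2.0)
        w = np.exp(-(dist_land - 1.0) / config.coastal_decay)
        w *= np.exp(config.cluster_strength * cluster)
        w = np.where(ocean, w, 0.0).ravel()
        chosen = rng.choice(n, size=n_dive, replace=False, p=w / w.sum())
        dive_flat[chosen] = True

    # --- labels: longitude-band regions, nearest-seed countries -------------
    region = pd.cut(cols, bins=config.n_regions,
                    labels=[f"R{i + 1}" for i in range(config.n_regions)]).astype(str)
    seeds = rng.choice(np.flatnonzero(ocean_flat), size=min(config.n_countries, n_ocean),
                       replace=False) if n_ocean else np.array([0])
    d2 = (rows[:, None] - rows[seeds][None, :]) ** 2 + (cols[:, None] - cols[seeds][None, :]) ** 2
    country = np.array([f"C{k + 1}" for k in d2.argmin(axis=1)])

    pixels = pd.DataFrame({
        "pixel_id": np.arange(n),
        "centroid_lon": lon,
        "centroid_lat": lat,
        "area_km2": 2500.0,
        "is_ocean": ocean_flat,
        "has_diving": dive_flat,
        "protection_status": Protection.UNPROTECTED.value,
        "region_label": region,
        "country_label": country,
        "dives": 0,
    })

    # --- MPA coverage --------------------------------------------------------
    cov_rows: list[tuple[int, str, float, int]] = []
    dive_ids = np.flatnonzero(dive_flat)
    perm = rng.permutation(dive_ids)
    n_fully = int(round(config.fully_fraction * n_dive))
    n_mpa = int(round(config.mpa_fraction * n_dive))
    weak_classes = [Protection.LESS_UNKNOWN, Protection.DESIGNATED_UNIMPLEMENTED,
                    Protection.PROPOSED_COMMITTED]
    for k, pid in enumerate(perm[:n_mpa]):
        year = int(rng.integers(1970, 2021))
        if k < n_fully:
            cov_rows.append((int(pid), Protection.FULLY_HIGHLY.value,
                             float(rng.uniform(0.5, 0.95)), year))
        else:
            cls = weak_classes[rng.choice(3, p=[0.7, 0.15, 0.15])]
            cov_rows.append((int(pid), cls.value, float(rng.uniform(0.2, 0.95)), year))
    other_ocean = np.flatnonzero(ocean_flat & ~dive_flat)
    if len(other_ocean):
        n_weak = int(round(config.ocean_mpa_rate * len(other_ocean)))
        n_full = int(round(config.ocean_fully_rate * len(other_ocean)))
        extra = rng.choice(other_ocean, size=min(n_weak + n_full, len(other_ocean)),
                           replace=False)
        for k, pid in enumerate(extra):
            year = int(rng.integers(1970, 2021))
            if k < n_full:
                cov_rows.append((int(pid), Protection.FULLY_HIGHLY.value,
                                 float(rng.uniform(0.5, 0.95)), year))
            else:
                cov_rows.append((int(pid), Protection.LESS_UNKNOWN.value,
                                 float(rng.uniform(0.2, 0.95)), year))
    coverage = pd.DataFrame(cov_rows, columns=["pixel_id", "designation", "fraction", "year"])

    # --- dive counts: heavy-tailed, exact total -----------------------------
    total = config.total_dives
    if total is None:
        total = REFERENCE_MARINE_DIVES * n_dive / REFERENCE_DIVE_PIXELS
    total = int(round(total))
    if n_dive > 0 and total > 0:
        wts = rng.lognormal(0.0, config.dive_sigma, size=n_dive)
        if total >= n_dive:
            counts = 1 + largest_remainder(wts, total - n_dive)
        else:
            counts = largest_remainder(wts, total)
        pixels.loc[dive_ids, "dives"] = counts

    # --- price observations: stratified lognormal quantiles -----------------
    prices = pd.DataFrame(columns=["operator_id", "pixel_id", "price_per_dive"])
    if n_dive > 0 and config.n_operators > 0:
        m = config.n_operators
        q = (np.arange(m) + 0.5) / m
        vals = config.price_median * np.exp(config.price_sigma * ndtri(q))
        rng.shuffle(vals)
        dive_w = pixels.loc[dive_ids, "dives"].to_numpy(float) + 1.0
        op_pix = rng.choice(dive_ids, size=m, replace=True, p=dive_w / dive_w.sum())
        prices = pd.DataFrame({
            "operator_id": np.arange(m),
            "pixel_id": op_pix,
            "price_per_dive": vals,
        })

    world = apply_protection(GridWorld(pixels), coverage)
    cfg = asdict(config)
    cfg["total_dives"] = total
    return WorldBundle(world=world, coverage=coverage, prices=prices,
                       config={"world": cfg})


# ---------------------------------------------------------------------------
# Stock generation
# ---------------------------------------------------------------------------

@dataclass
class StockGenConfig:
    n_stocks: int = 50
    r_median: float = 0.35
    r_sigma: float = 0.4
    K_median: float = 5000.0        # tonnes
    K_sigma: float = 1.0
    length_median: float = 45.0     # cm
    length_sigma: float = 0.5
    trophic_range: tuple[float, float] = (2.0, 4.5)
    movement_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # sedentary/roaming/migratory
    elasmobranch_fraction: float = 0.1
    range_median: float = 30.0      # pixels
    range_sigma: float = 0.7
    range_min: int = 4
    depletion_range: tuple[float, float] = (0.1, 0.9)  # B/K under business as usual
    empirical_fraction: float = 0.4
    noise_scale: float = 0.3        # log-sd of empirical trait measurement noise
    coeffs: TraitCoefficients = field(default_factory=TraitCoefficients)

    def validate(self) -> None:
        lo, hi = self.depletion_range
        if not (0.0 < lo <= hi <= 1.0):
            raise WorldError("depletion range must lie in (0, 1]")
        if self.n_stocks < 0:
            raise WorldError("n_stocks must be nonnegative")


def _grow_blob(rng: np.random.Generator, ocean: np.ndarray, seed_rc: tuple[int, int],
               size: int) -> list[tuple[int, int]]:
    """Grow a 4-connected contiguous blob on ocean cells from a seed cell."""
    ny, nx = ocean.shape
    blob = {seed_rc}
    frontier = set()

    def neighbors(rc):
        r, c = rc
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and ocean[rr, cc]:
                yield rr, cc

    frontier.update(set(neighbors(seed_rc)) - blob)
    while len(blob) < size and frontier:
        ordered = sorted(frontier)
        pick = ordered[int(rng.integers(len(ordered)))]
        frontier.discard(pick)
        blob.add(pick)
        frontier.update(set(neighbors(pick)) - blob)
    return sorted(blob)


def generate_stocks(config: StockGenConfig, bundle: WorldBundle,
                    seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate fished stocks with contiguous ranges and trait ground truth.

    Each stock's range is seeded at a dive pixel (so it intersects at least one)
    and grown 4-connected over ocean cells.  A configurable fraction of stocks
    carries noisy "empirical" home-range/PLD labels generated from the log-linear
    feature relationship; elasmobranch-flagged stocks get no PLD.
    """
    config.validate()
    wc = bundle.config["world"]
    nx, ny = wc["nx"], wc["ny"]
    if seed is None:
        seed = wc["seed"]
    rng = _rng(seed, 1)
    m = config.n_stocks

    px = bundle.world.pixels
    ocean = px["is_ocean"].to_numpy(bool).reshape(ny, nx)
    dive_ids = bundle.world.dive_ids
    if m and len(dive_ids) == 0:
        raise WorldError("cannot place stocks in a world without dive pixels")

    lo, hi = config.trophic_range
    stocks = pd.DataFrame({
        "stock_id": np.arange(m),
        "r": config.r_median * rng.lognormal(0.0, config.r_sigma, m),
        "K": config.K_median * rng.lognormal(0.0, config.K_sigma, m),
        "length_cm": config.length_median * rng.lognormal(0.0, config.length_sigma, m),
        "trophic_level": rng.uniform(lo, hi, m),
        "movement_keyword": rng.choice(3, size=m, p=list(config.movement_probs)),
        "is_elasmobranch": rng.random(m) < config.elasmobranch_fraction,
        "depletion": rng.uniform(*config.depletion_range, m),
    })

    # ranges: grow blobs; record realized sizes as the range-size feature
    sizes = np.maximum(
        config.range_min,
        np.round(config.range_median * rng.lognormal(0.0, config.range_sigma, m)).astype(int),
    )
    range_rows = []
    realized = np.zeros(m, dtype=int)
    for s in range(m):
        pid = int(rng.choice(dive_ids))
        blob = _grow_blob(rng, ocean, (pid // nx, pid % nx), int(sizes[s]))
        realized[s] = len(blob)
        range_rows.extend((s, r * nx + c) for r, c in blob)
    stocks["range_size"] = realized
    ranges = pd.DataFrame(range_rows, columns=["stock_id", "pixel_id"])

    # trait ground truth and noisy empirical labels
    stocks["home_range_true"] = trait_generative_model(stocks, config.coeffs.home_range)
    pld_true = trait_generative_model(stocks, config.coeffs.pld)
    pld_true[stocks["is_elasmobranch"].to_numpy(bool)] = np.nan
    stocks["pld_true"] = pld_true

    emp = rng.random(m) < config.empirical_fraction
    stocks["is_empirical"] = emp
    hr_noise = np.exp(config.noise_scale * rng.normal(size=m))
    pld_noise = np.exp(config.noise_scale * rng.normal(size=m))
    stocks["home_range_emp"] = np.where(emp, stocks["home_range_true"] * hr_noise, np.nan)
    stocks["pld_emp"] = np.where(emp, stocks["pld_true"] * pld_noise, np.nan)
    return stocks, ranges


# ---------------------------------------------------------------------------
# Species generation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesGenConfig:
    n_species: int = 200
    range_median: float = 40.0      # pixels
    range_sigma: float = 0.8
    range_min: int = 2
    q_abatable_range: tuple[float, float] = (0.3, 1.0)


def generate_species(
    n_species: int | SpeciesGenConfig,
    taxon_table: dict[str, float] | None,
    bundle: WorldBundle,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate biodiversity-scored species with ranges and taxon weights.

    Species counts per taxon follow the aggregate weight table (largest-remainder
    allocation), so the realized aggregate weight per taxon matches the table
    exactly once weights are assigned uniformly within taxa.
    """
    cfg = n_species if isinstance(n_species, SpeciesGenConfig) else SpeciesGenConfig(n_species=int(n_species))
    if taxon_table is None:
        taxon_table = dict(biodiversity.DEFAULT_TAXON_WEIGHTS)
    total_w = sum(taxon_table.values())
    if abs(total_w - 1.0) > 1e-9:
        raise WorldError(f"taxon aggregate weights must sum to 1, got {total_w}")
    wc = bundle.config["world"]
    nx, ny = wc["nx"], wc["ny"]
    if seed is None:
        seed = wc["seed"]
    rng = _rng(seed, 2)

    n = cfg.n_species
    if n == 0:
        return (pd.DataFrame(columns=["species_id", "taxon_group", "weight",
                                      "q_abatable", "u_unabatable"]),
                pd.DataFrame(columns=["species_id", "pixel_id"]))

    taxa = list(taxon_table)
    counts = largest_remainder(np.array([taxon_table[t] for t in taxa]), n)
    taxon_col = np.repeat(taxa, counts)
    rng.shuffle(taxon_col)

    ocean = bundle.world.pixels["is_ocean"].to_numpy(bool).reshape(ny, nx)
    ocean_ids = bundle.world.ocean_ids
    sizes = np.maximum(
        cfg.range_min,
        np.round(cfg.range_median * rng.lognormal(0.0, cfg.range_sigma, n)).astype(int),
    )
    rows = []
    for s in range(n):
        pid = int(rng.choice(ocean_ids))
        blob = _grow_blob(rng, ocean, (pid // nx, pid % nx), int(sizes[s]))
        rows.extend((s, r * nx + c) for r, c in blob)
    ranges = pd.DataFrame(rows, columns=["species_id", "pixel_id"])

    species = pd.DataFrame({
        "species_id": np.arange(n),
        "taxon_group": taxon_col,
        "q_abatable": rng.uniform(*cfg.q_abatable_range, n),
        "u_unabatable": 0.0,
    })
    species["weight"] = biodiversity.assign_species_weights(species, taxon_table)
    return species, ranges


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

def generate_bundle(
    world_config: WorldGenConfig | None = None,
    stock_config: StockGenConfig | None = None,
    species_config: SpeciesGenConfig | None = None,
    taxon_table: dict[str, float] | None = None,
    seed: int | None = None,
) -> WorldBundle:
    """Generate a complete world bundle (grid + MPAs + prices + stocks + species)."""
    world_config = world_config or WorldGenConfig()
    if seed is not None:
        world_config.seed = int(seed)
    stock_config = stock_config or StockGenConfig()
    species_config = species_config or SpeciesGenConfig()
    bundle = generate_world(world_config)
    bundle.stocks, bundle.stock_ranges = generate_stocks(stock_config, bundle)
    bundle.species, bundle.species_ranges = generate_species(
        species_config, taxon_table, bundle)
    bundle.config["stocks"] = _yaml_safe(asdict(stock_config))
    bundle.config["species"] = _yaml_safe(asdict(species_config))
    return bundle


def _yaml_safe(obj):
    """Recursively convert tuples to lists so configs round-trip through YAML."""
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    return obj
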