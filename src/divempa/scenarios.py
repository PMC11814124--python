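"""Scenario orchestration: BAU vs protect-all, fee sweeps, Monte Carlo, sensitivity.

The pipeline runs the biology once per world (trait imputation, dispersal
matrices, biomass equilibria, biodiversity scores) and then maps the resulting
biomass and biodiversity gains through the willingness-to-pay demand shifts to
per-pixel economics.  Fee sweeps, neutral-fee searches and Monte-Carlo draws of
the global dive total reuse the prepared biology, since the biological outcome
does not depend on the number of dives.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import biodiversity, biomass, economics, traits
from .economics import WTPParams
from .world import WorldBundle, WorldError

log = logging.getLogger(__name__)

POLICIES = ("bau", "protect_all")


@dataclass
class ScenarioConfig:
    """One policy/fee evaluation on a world bundle."""

    policy: str = "protect_all"
    fee: float | str = 0.0            # uniform USD per dive, or "neutral"
    price_scheme: str = "global_median"
    dive_total: float | None = None   # rescale Q* so dives sum to this
    choke_percentile: float = 99.0
    n_iter: int = 100
    renormalize_larvae: bool = True
    z: float = biodiversity.DEFAULT_Z
    wtp: WTPParams = field(default_factory=WTPParams)
    taxon_weights: dict | None = None
    foreign_fraction: float = 0.61    # default share of surplus to foreign divers
    rf_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.policy not in POLICIES:
            raise WorldError(f"unknown policy {self.policy!r}")
        if not isinstance(self.fee, str) and self.fee < 0:
            raise WorldError("fee must be nonnegative")
        if self.n_iter < 1:
            raise WorldError("n_iter must be >= 1")


def _check_bundle(bundle: WorldBundle) -> None:
    missing = []
    if bundle.world.pixels.empty:
        missing.append("pixels")
    if len(bundle.world.dive_ids) and bundle.prices.empty:
        missing.append("prices")
    if missing:
        raise WorldError(f"incomplete world bundle; missing tables: {missing}")


# ---------------------------------------------------------------------------
# Prepared biology + market state
# ---------------------------------------------------------------------------

@dataclass
class PreparedWorld:
    """Biology and baseline market state reused across fee/dive-total variants."""

    bundle: WorldBundle
    config: ScenarioConfig
    econ: pd.DataFrame                  # pixel_id, Q_star, P_star, C
    traits: pd.DataFrame
    biomass_change: biomass.BiomassChange | None
    score_bau: float
    score_new: float
    d_biomass: pd.Series                # fractional gain per dive pixel
    d_score: float
    sum_wtp: pd.Series                  # protect-all WTP shift per dive pixel, USD
    wtp_parts: pd.DataFrame             # biomass/biodiversity/name dollars per pixel
    timings: dict = field(default_factory=dict)

    @property
    def d_score_pct(self) -> float:
        return 100.0 * self.d_score / self.score_bau if self.score_bau > 0 else 0.0


def _fit_trait_models(bundle: WorldBundle, cfg: ScenarioConfig):
    """Fit home-range and PLD imputers on the empirical subset (if feasible)."""
    stocks = bundle.stocks
    feats = traits.trait_features(stocks) if len(stocks) else None

    def _fit(label_col: str, exclude_elasmo: bool):
        if not len(stocks):
            return None
        mask = stocks["is_empirical"].astype(bool) & stocks[label_col].notna()
        if exclude_elasmo:
            mask &= ~stocks["is_elasmobranch"].astype(bool)
        if mask.sum() < 10:
            log.warning("only %d empirical rows for %s; skipping model",
                        int(mask.sum()), label_col)
            return None
        return traits.fit_trait_model(
            feats[mask], stocks.loc[mask, label_col],
            seed=cfg.seed, n_estimators=cfg.rf_trees)

    return _fit("home_range_emp", False), _fit("pld_emp", True)


def prepare_world(bundle: WorldBundle, config: ScenarioConfig | None = None) -> PreparedWorld:
    """Run trait resolution, biomass equilibria, scores, and baseline economics."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    _check_bundle(bundle)
    world = bundle.world
    dive_ids = world.dive_ids
    timings: dict[str, float] = {}

    # --- economics baseline --------------------------------------------------
    t0 = time.perf_counter()
    from .world import allocate_prices
    prices = allocate_prices(bundle.prices, world, scheme=cfg.price_scheme)
    choke = economics.choke_price(bundle.prices["price_per_dive"], cfg.choke_percentile)
    econ = economics.pixel_economics(world, prices, choke)
    if cfg.dive_total is not None and econ["Q_star"].sum() > 0:
        econ["Q_star"] *= cfg.dive_total / econ["Q_star"].sum()
    timings["economics_baseline_s"] = time.perf_counter() - t0

    # --- biology -------------------------------------------------------------
    t0 = time.perf_counter()
    hr_model, pld_model = _fit_trait_models(bundle, cfg)
    if len(bundle.stocks):
        traits_df = traits.resolve_traits(bundle.stocks, hr_model, pld_model)
        disp = traits.dispersal_matrices(world, traits_df, bundle.stock_ranges,
                                         renormalize=cfg.renormalize_larvae)
        bio = biomass.run_biology(bundle, disp, policy="protect_all", n_iter=cfg.n_iter)
        change = biomass.percent_biomass_change(bio, dive_ids)
    else:
        traits_df = pd.DataFrame()
        change = None
    timings["biology_s"] = time.perf_counter() - t0

    # --- biodiversity --------------------------------------------------------
    t0 = time.perf_counter()
    bau_set = biomass.policy_masks(bundle, "bau")
    new_set = biomass.policy_masks(bundle, "protect_all")
    score_bau, score_new, d_score = biodiversity.delta_score(
        bundle.species, bundle.species_ranges, bau_set, new_set,
        z=cfg.z) if len(bundle.species) else (0.0, 0.0, 0.0)
    if cfg.taxon_weights is not None and len(bundle.species):
        sp = bundle.species.copy()
        sp["weight"] = biodiversity.assign_species_weights(sp, cfg.taxon_weights)
        score_bau, score_new, d_score = biodiversity.delta_score(
            sp, bundle.species_ranges, bau_set, new_set, z=cfg.z)
    timings["biodiversity_s"] = time.perf_counter() - t0

    # --- WTP shift under protect-all ----------------------------------------
    idx = econ["pixel_id"].to_numpy()
    if change is not None:
        d_bio = (change.per_pixel / 100.0).reindex(idx).fillna(0.0)
    else:
        d_bio = pd.Series(0.0, index=idx)
    d_bio = d_bio.clip(lower=-1.0)
    parts = economics.wtp_components(
        d_bio.to_numpy(), max(d_score, 0.0), True, cfg.wtp,
        econ["P_star"].to_numpy())
    wtp_parts = pd.DataFrame(
        {"biomass": parts[0], "biodiversity": parts[1], "name_effect": parts[2]},
        index=idx)
    sum_wtp = wtp_parts.sum(axis=1)

    return PreparedWorld(
        bundle=bundle, config=cfg, econ=econ, traits=traits_df,
        biomass_change=change, score_bau=score_bau, score_new=score_new,
        d_biomass=d_bio, d_score=d_score, sum_wtp=sum_wtp,
        wtp_parts=wtp_parts, timings=timings)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    prepared: PreparedWorld,
    policy: str = "protect_all",
    fee: float | str = 0.0,
    dive_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-pixel economic outcome for one (policy, fee) combination.

    In the ``bau`` branch there is no protection upgrade, so the WTP shift is
    zero and any positive fee simply moves down the unshifted demand curve.
    """
    econ = prepared.econ
    Q = econ["Q_star"].to_numpy() * dive_scale
    P = econ["P_star"].to_numpy()
    C = econ["C"].to_numpy()
    if policy == "protect_all":
        sum_wtp = prepared.sum_wtp.to_numpy()
    else:
        sum_wtp = np.zeros(len(econ))
    F = sum_wtp.copy() if isinstance(fee, str) and fee == "neutral" else np.full(len(econ), float(fee))
    dQ = economics.delta_dives(Q, P, C, sum_wtp, F)
    out = pd.DataFrame({
        "pixel_id": econ["pixel_id"].to_numpy(),
        "Q_star": Q, "P_star": P, "C": C,
        "sum_wtp": sum_wtp, "fee": F,
        "delta_dives": dQ,
        "delta_revenue": economics.delta_dive_revenue(P, dQ),
        "fee_revenue": economics.fee_revenue(F, Q, dQ),
        "delta_cs": economics.delta_consumer_surplus(Q, P, C, dQ),
    })
    return out


AGG_COLUMNS = ["delta_dives", "delta_revenue", "fee_revenue", "delta_cs"]


@dataclass
class ScenarioResult:
    """Aggregate + per-pixel outcome of one scenario run."""

    config: ScenarioConfig
    per_pixel: pd.DataFrame
    aggregates: dict
    attribution: dict
    origin_split: pd.DataFrame
    biomass_mean_pct: float
    biomass_sd_pct: float
    score_bau: float
    score_new: float
    d_score: float
    timings: dict

    def summary(self) -> dict:
        cfg = asdict(self.config)
        cfg["wtp"] = asdict(self.config.wtp)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "aggregates": self.aggregates,
            "attribution": self.attribution,
            "origin_split": {
                r["region"]: {"foreign": r["foreign"], "local": r["local"]}
                for _, r in self.origin_split.iterrows()
            },
            "biomass": {"mean_pct": self.biomass_mean_pct, "sd_pct": self.biomass_sd_pct},
            "biodiversity": {"score_bau": self.score_bau, "score_new": self.score_new,
                             "delta": self.d_score},
        }


def run_scenario(
    bundle: WorldBundle,
    config: ScenarioConfig | None = None,
    prepared: PreparedWorld | None = None,
) -> ScenarioResult:
    """Full policy evaluation: biology, scores, WTP, per-pixel economics."""
    cfg = config or ScenarioConfig()
    prep = prepared or prepare_world(bundle, cfg)
    per_pixel = evaluate(prep, policy=cfg.policy, fee=cfg.fee)

    base_rev, base_cs = economics.baseline_surplus_and_revenue(prep.econ)
    aggregates = {c: float(per_pixel[c].sum()) for c in AGG_COLUMNS}
    total_dives = float(per_pixel["Q_star"].sum())
    aggregates.update({
        "n_dive_pixels": int(len(per_pixel)),
        "total_dives": total_dives,
        "baseline_revenue": base_rev,
        "baseline_consumer_surplus": base_cs,
        "pct_change_dives": (100.0 * aggregates["delta_dives"] / total_dives
                             if total_dives else 0.0),
        "mean_fee": (float((per_pixel["fee"] * per_pixel["Q_star"]).sum() / total_dives)
                     if total_dives else 0.0),
    })

    if cfg.policy == "protect_all":
        weights = per_pixel["Q_star"].to_numpy() / (per_pixel["C"] - per_pixel["P_star"]).to_numpy()
        attribution, ok = economics.attribute_components(
            prep.d_biomass.to_numpy(), max(prep.d_score, 0.0), True,
            cfg.wtp, per_pixel["P_star"].to_numpy(), weights=weights)
        attribution["defined"] = ok
        bio_mean, bio_sd = ((prep.biomass_change.mean, prep.biomass_change.sd)
                            if prep.biomass_change is not None else (0.0, 0.0))
        d_score = prep.d_score
        score_new = prep.score_new
    else:
        attribution = {"biodiversity": 0.0, "biomass": 0.0, "name_effect": 0.0,
                       "defined": False}
        bio_mean = bio_sd = 0.0
        d_score = 0.0
        score_new = prep.score_bau

    regions = bundle.world.rows(per_pixel["pixel_id"])["region_label"]
    regions.index = per_pixel.index
    fractions = {r: cfg.foreign_fraction for r in regions.unique()}
    origin = economics.split_surplus_by_origin(
        per_pixel["delta_cs"], regions, fractions)

    return ScenarioResult(
        config=cfg, per_pixel=per_pixel, aggregates=aggregates,
        attribution=attribution, origin_split=origin,
        biomass_mean_pct=bio_mean, biomass_sd_pct=bio_sd,
        score_bau=prep.score_bau, score_new=score_new, d_score=d_score,
        timings=prep.timings)


# ---------------------------------------------------------------------------
# Fee sweep, neutral fee, Monte Carlo, sensitivity
# ---------------------------------------------------------------------------

def default_fee_grid(prepared: PreparedWorld, step: float = 1.0) -> np.ndarray:
    """US$`step` increments from 0 to twice the choke margin (covers the dome)."""
    margin = float((prepared.econ["C"] - prepared.econ["P_star"]).max())
    return np.arange(0.0, 2.0 * margin + step, step)


def fee_sweep(
    prepared: PreparedWorld, fees=None, dive_scale: float = 1.0
) -> pd.DataFrame:
    """Aggregate outcomes over a fee grid, with and without the MPA upgrade."""
    fees = default_fee_grid(prepared) if fees is None else np.asarray(fees, dtype=float)
    if np.any(np.diff(fees) < 0) or np.any(fees < 0):
        raise WorldError("fee grid must be sorted and nonnegative")
    rows = []
    for branch in ("protect_all", "bau"):
        for F in fees:
            pp = evaluate(prepared, policy=branch, fee=float(F), dive_scale=dive_scale)
            rows.append({
                "policy": branch, "fee": float(F),
                **{c: float(pp[c].sum()) for c in AGG_COLUMNS},
            })
    return pd.DataFrame(rows)


def neutral_fee(prepared: PreparedWorld) -> tuple[pd.Series, float]:
    """Per-pixel fee equal to the WTP shift (holds dives constant) + mean fee.

    Verifies the neutrality contract |dQ| < 1e-9 in every pixel and returns
    the dive-weighted mean fee (the analogue of a single headline fee).
    """
    per_pixel = evaluate(prepared, policy="protect_all", fee="neutral")
    if not (per_pixel["delta_dives"].abs() < 1e-9).all():
        raise AssertionError("neutral fee failed to hold dive numbers constant")
    Q = per_pixel["Q_star"]
    mean = float((per_pixel["fee"] * Q).sum() / Q.sum()) if Q.sum() else 0.0
    return per_pixel.set_index("pixel_id")["fee"], mean


def monte_carlo(
    prepared: PreparedWorld,
    n_runs: int = 500,
    dive_bounds: tuple[float, float] | None = None,
    seed: int = 0,
    fees=None,
) -> pd.DataFrame:
    """Ensemble over uniformly drawn global dive totals.

    Per run the pixel dive counts are rescaled proportionally to the drawn
    total and the fee sweep is re-evaluated in both branches.  Reported per
    run: the revenue-maximising fee and revenue per branch and the
    MPA-minus-no-MPA fee-revenue difference at the MPA optimum.
    """
    if n_runs < 1:
        raise WorldError("n_runs must be >= 1")
    base_total = float(prepared.econ["Q_star"].sum())
    if dive_bounds is None:
        # study bounds 17.1e6..54.0e6 around a 33.1e6 central value, rescaled
        dive_bounds = (base_total * 17.1 / 33.1, base_total * 54.0 / 33.1)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    fees = default_fee_grid(prepared) if fees is None else np.asarray(fees, dtype=float)
    rows = []
    for run in range(n_runs):
        total = float(rng.uniform(*dive_bounds))
        scale = total / base_total if base_total else 0.0
        sweep = fee_sweep(prepared, fees=fees, dive_scale=scale)
        mpa = sweep[sweep["policy"] == "protect_all"]
        bau = sweep[sweep["policy"] == "bau"]
        i_mpa = int(mpa["fee_revenue"].idxmax())
        i_bau = int(bau["fee_revenue"].idxmax())
        rows.append({
            "run": run, "dive_total": total,
            "opt_fee_mpa": float(mpa.loc[i_mpa, "fee"]),
            "max_fee_revenue_mpa": float(mpa.loc[i_mpa, "fee_revenue"]),
            "opt_fee_bau": float(bau.loc[i_bau, "fee"]),
            "max_fee_revenue_bau": float(bau.loc[i_bau, "fee_revenue"]),
            "fee_revenue_advantage": float(
                mpa.loc[i_mpa, "fee_revenue"] - bau.loc[i_bau, "fee_revenue"]),
        })
    return pd.DataFrame(rows)


def sensitivity_suite(
    bundle: WorldBundle,
    base_config: ScenarioConfig | None = None,
    dive_totals: dict[str, float] | None = None,
    price_schemes=("global_median", "country_median", "interpolated"),
    taxon_tables: dict[str, dict | None] | None = None,
) -> pd.DataFrame:
    """Max-fee-revenue outcomes over dive totals x price schemes x weights."""
    cfg0 = base_config or ScenarioConfig()
    prep0 = prepare_world(bundle, cfg0)
    base_total = float(prep0.econ["Q_star"].sum())
    if dive_totals is None:
        dive_totals = {"lower": base_total * 17.1 / 33.1, "central": base_total,
                       "upper": base_total * 54.0 / 33.1}
    if taxon_tables is None:
        uniform = {t: 1.0 / len(biodiversity.DEFAULT_TAXON_WEIGHTS)
                   for t in biodiversity.DEFAULT_TAXON_WEIGHTS}
        taxon_tables = {"default": None, "uniform": uniform}
    rows = []
    for scheme in price_schemes:
        for wname, table in taxon_tables.items():
            cfg = ScenarioConfig(**{**asdict(cfg0), "wtp": cfg0.wtp})
            cfg.price_scheme = scheme
            cfg.taxon_weights = table
            prep = prepare_world(bundle, cfg)
            for dname, total in dive_totals.items():
                scale = total / base_total if base_total else 0.0
                sweep = fee_sweep(prep, dive_scale=scale)
                mpa = sweep[sweep["policy"] == "protect_all"]
                i = int(mpa["fee_revenue"].idxmax())
                _, mean_neutral = neutral_fee(prep)
                rows.append({
                    "price_scheme": scheme, "weights": wname,
                    "dive_total_case": dname, "dive_total": total * 1.0,
                    "opt_fee": float(mpa.loc[i, "fee"]),
                    "max_fee_revenue": float(mpa.loc[i, "fee_revenue"]),
                    "neutral_mean_fee": mean_neutral,
                    "d_score": prep.d_score,
                })
    return pd.DataFrame(rows)


def write_summary(path: str | Path, result: ScenarioResult) -> Path:
    """Write a scenario summary as deterministic JSON (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return path
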