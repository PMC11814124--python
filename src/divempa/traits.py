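"""Dispersal traits: home-range / PLD imputation and movement & larval matrices.

Adult mobility treats a stock's home range (km^2) as the area of a circle, so
adult biomass can redistribute only within the radius ``zeta = sqrt(HR / pi)``.
Larvae spread from their source pixel following an isotropic Gaussian kernel
whose spread grows with pelagic larval duration (PLD, days) as
``sigma = 1.33 * sqrt(pi/2) * PLD**1.3`` (the empirical relationship of Siegel
et al.).  Elasmobranchs lack a pelagic larval stage: they carry no PLD and their
larval settlement is natal-pixel-only.

Traits observed in the literature ("empirical") take priority; all other stocks
get values imputed by a random-forest regression on life-history features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .world import GridWorld

log = logging.getLogger(__name__)

SIGMA_COEF = 1.33 * np.sqrt(np.pi / 2.0)

TRAIT_FEATURES = [
    "log_r", "log_K", "log_length", "trophic_level", "movement_keyword",
    "log_range_size",
]


def trait_features(stocks: pd.DataFrame) -> pd.DataFrame:
    """Life-history feature frame for trait imputation.

    Features: intrinsic growth rate, carrying capacity, species length, trophic
    level, movement keyword (ordered categorical encoded as an integer), and
    geographic range size; scale covariates enter on the log axis.
    """
    return pd.DataFrame({
        "log_r": np.log(stocks["r"].to_numpy(float)),
        "log_K": np.log(stocks["K"].to_numpy(float)),
        "log_length": np.log(stocks["length_cm"].to_numpy(float)),
        "trophic_level": stocks["trophic_level"].to_numpy(float),
        "movement_keyword": stocks["movement_keyword"].to_numpy(float),
        "log_range_size": np.log(stocks["range_size"].to_numpy(float)),
    }, index=stocks.index)


def aggregate_empirical_trait(values) -> float:
    """Geometric mean of repeated trait measurements for one species."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty set of trait values")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("trait values must be positive and finite")
    return float(gmean(arr))


def larval_sigma(pld) -> np.ndarray | float:
    """Larval-kernel spread (km) from pelagic larval duration (days).

    ``sigma = 1.33 * sqrt(pi/2) * PLD**1.3``.
    """
    arr = np.asarray(pld, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("PLD must be nonnegative")
    out = SIGMA_COEF * arr ** 1.3
    return float(out) if np.isscalar(pld) else out


class TraitImputer(RegressorMixin, BaseEstimator):
    """Random-forest regressor for a positive trait, fitted on the log scale.

    Parameters
    ----------
    n_estimators : int, default 500
        Trees in the forest.
    holdout_fraction : float, default 0.25
        Share of the training data held out to report an out-of-sample R^2
        (on the log-trait scale).
    random_state : int or None
        Seeds both the holdout split and the forest; fixed seed means
        deterministic predictions.

    Attributes
    ----------
    forest_ : fitted ``RandomForestRegressor``
    feature_names_ : list of feature columns seen in ``fit``
    holdout_r2_ : float
        Held-out R^2 on log-trait (``nan`` when the holdout is degenerate).
    """

    def __init__(self, n_estimators: int = 500, holdout_fraction: float = 0.25,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    def _check_X(self, X: pd.DataFrame, fitting: bool = False) -> np.ndarray:
        cols = TRAIT_FEATURES if fitting else self.feature_names_
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        arr = X[cols].to_numpy(float)
        if not np.isfinite(arr).all():
            raise ValueError("features must be complete and finite")
        return arr

    def fit(self, X: pd.DataFrame, y) -> "TraitImputer":
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError(f"need at least 10 training rows, got {len(y)}")
        if (y <= 0).any():
            raise ValueError("trait values must be positive")
        self.feature_names_ = list(TRAIT_FEATURES)
        arr = self._check_X(X, fitting=True)
        logy = np.log(y)

        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.random_state)
        if 0.0 < self.holdout_fraction < 1.0 and len(y) * self.holdout_fraction >= 2:
            Xtr, Xte, ytr, yte = train_test_split(
                arr, logy, test_size=self.holdout_fraction,
                random_state=self.random_state)
            probe = RandomForestRegressor(
                n_estimators=self.n_estimators, random_state=self.random_state)
            probe.fit(Xtr, ytr)
            var = float(np.var(yte))
            self.holdout_r2_ = (
                r2_score(yte, probe.predict(Xte)) if var > 0 else float("nan"))
        else:
            self.holdout_r2_ = float("nan")
        self.forest_.fit(arr, logy)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return np.exp(self.forest_.predict(self._check_X(X)))


def fit_trait_model(features: pd.DataFrame, trait, seed: int = 0,
                    n_estimators: int = 500) -> TraitImputer:
    """Fit a :class:`TraitImputer` on (features, trait) training pairs."""
    return TraitImputer(n_estimators=n_estimators, random_state=seed).fit(features, trait)


# ---------------------------------------------------------------------------
# Trait resolution
# ---------------------------------------------------------------------------

def resolve_traits(
    stocks: pd.DataFrame,
    hr_model: TraitImputer | None = None,
    pld_model: TraitImputer | None = None,
) -> pd.DataFrame:
    """Resolve per-stock dispersal traits, preferring empirical values.

    Empirically derived home ranges / PLDs are used where flagged; other stocks
    get model predictions.  Elasmobranchs carry no PLD (no pelagic larval
    stage): their ``sigma_larvae`` is NaN and ``natal_only`` is set, meaning
    larval settlement happens in the natal pixel only.  Stocks with neither an
    empirical value nor predictable features are excluded with a logged
    warning (the "complete biological parameters" retention rule).
    """
    feats = trait_features(stocks)
    predictable = np.isfinite(feats.to_numpy(float)).all(axis=1)

    def _resolve(emp_col: str, model: TraitImputer | None) -> tuple[np.ndarray, np.ndarray]:
        emp = stocks[emp_col].to_numpy(float) if emp_col in stocks else np.full(len(stocks), np.nan)
        have_emp = np.isfinite(emp) & stocks.get("is_empirical", pd.Series(True, index=stocks.index)).to_numpy(bool)
        vals = np.where(have_emp, emp, np.nan)
        prov = np.where(have_emp, "empirical", "none").astype(object)
        need = ~have_emp & predictable
        if model is not None and need.any():
            vals[need] = model.predict(feats[need])
            prov[need] = "predicted"
        return vals, prov

    hr, hr_prov = _resolve("home_range_emp", hr_model)
    pld, pld_prov = _resolve("pld_emp", pld_model)

    elasmo = stocks.get("is_elasmobranch", pd.Series(False, index=stocks.index)).to_numpy(bool)
    pld[elasmo] = np.nan
    pld_prov[elasmo] = "none"

    out = pd.DataFrame({
        "stock_id": stocks["stock_id"].to_numpy(),
        "home_range": hr,
        "zeta": np.sqrt(np.maximum(hr, 0.0) / np.pi),
        "pld": pld,
        "sigma_larvae": np.where(np.isfinite(pld), SIGMA_COEF * np.where(np.isfinite(pld), pld, 0.0) ** 1.3, np.nan),
        "natal_only": elasmo,
        "hr_provenance": hr_prov,
        "pld_provenance": pld_prov,
    })
    keep = np.isfinite(out["home_range"]) & (np.isfinite(out["pld"]) | elasmo)
    if (~keep).any():
        dropped = out.loc[~keep, "stock_id"].tolist()
        log.warning("excluding %d stock(s) without resolvable traits: %s",
                    len(dropped), dropped[:10])
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Dispersal matrices
# ---------------------------------------------------------------------------

@dataclass
class StockDispersal:
    """Movement and larval matrices of one stock over its range pixels.

    ``movement[j, i]`` is the share of adult biomass moving from range pixel j
    to range pixel i (rows sum to 1 exactly); ``larval[j, i]`` is the share of
    viable larvae produced in j that settles in i.  ``settlement`` caches the
    column sums of ``larval``.
    """

    pixels: np.ndarray
    movement: np.ndarray
    larval: np.ndarray

    @property
    def settlement(self) -> np.ndarray:
        return self.larval.sum(axis=0)


def build_movement_matrix(world: GridWorld, range_pixels, zeta: float) -> np.ndarray:
    """Uniform adult redistribution over range pixels within radius ``zeta``.

    Each source pixel spreads its biomass uniformly over all range pixels whose
    centroid lies within ``zeta`` km (always including itself); if no neighbour
    qualifies the biomass stays put.  Rows sum to 1 exactly by construction.
    """
    range_pixels = np.asarray(list(range_pixels))
    D = world.distance_matrix(range_pixels)
    within = D <= max(float(zeta), 0.0)
    np.fill_diagonal(within, True)
    M = within.astype(float)
    M /= M.sum(axis=1, keepdims=True)
    # pin row sums to exactly 1 despite 1/m rounding (a couple of ulp nudges
    # on the last nonzero entry, measured against numpy's own summation)
    for j in range(len(M)):
        last = np.flatnonzero(M[j])[-1]
        for _ in range(5):
            err = M[j].sum() - 1.0
            if err == 0.0:
                break
            M[j, last] -= err
    return M


def build_larval_matrix(
    world: GridWorld,
    range_pixels,
    sigma: float,
    renormalize: bool = True,
    natal_only: bool = False,
) -> np.ndarray:
    """Discretized Gaussian larval kernel over the stock's range.

    The isotropic kernel ``exp(-d^2 / 2 sigma^2) / (2 pi sigma^2)`` is evaluated
    at centroid distances and multiplied by the destination pixel area (km^2).
    At 50 km pixels this badly under-resolves small ``sigma``, so rows are
    renormalized to sum to 1 by default, preserving total larval output within
    the range.  ``sigma = 0`` or ``natal_only`` gives identity rows (settlement
    in the natal pixel only).
    """
    range_pixels = np.asarray(list(range_pixels))
    n = len(range_pixels)
    if natal_only or not np.isfinite(sigma) or sigma <= 0:
        return np.eye(n)
    D = world.distance_matrix(range_pixels)
    area = world.rows(range_pixels)["area_km2"].to_numpy(float)
    rho = np.exp(-(D ** 2) / (2.0 * sigma ** 2)) / (2.0 * np.pi * sigma ** 2)
    rho = rho * area[None, :]
    if renormalize:
        rho = rho / rho.sum(axis=1, keepdims=True)
    return rho


def dispersal_matrices(
    world: GridWorld,
    traits_df: pd.DataFrame,
    stock_ranges: pd.DataFrame,
    renormalize: bool = True,
) -> dict[int, StockDispersal]:
    """Build per-stock movement and larval matrices from resolved traits."""
    out: dict[int, StockDispersal] = {}
    by_stock = stock_ranges.groupby("stock_id")["pixel_id"]
    for _, row in traits_df.iterrows():
        sid = row["stock_id"]
        pixels = np.sort(by_stock.get_group(sid).to_numpy())
        movement = build_movement_matrix(world, pixels, row["zeta"])
        larval = build_larval_matrix(
            world, pixels, row["sigma_larvae"],
            renormalize=renormalize, natal_only=bool(row["natal_only"]))
        out[sid] = StockDispersal(pixels=pixels, movement=movement, larval=larval)
    return out


# ---------------------------------------------------------------------------
# Sparse-matrix text persistence
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, pixels: np.ndarray, M: np.ndarray) -> None:
    """Persist a dispersal matrix as coordinate-triplet text (from,to,value)."""
    j, i = np.nonzero(M)
    pd.DataFrame({
        "from_pixel": pixels[j], "to_pixel": pixels[i], "value": M[j, i],
    }).to_csv(path, index=False)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a coordinate-triplet matrix; returns (pixels, dense matrix)."""
    df = pd.read_csv(path)
    pixels = np.unique(np.concatenate([df["from_pixel"], df["to_pixel"]]))
    idx = {p: k for k, p in enumerate(pixels)}
    M = np.zeros((len(pixels), len(pixels)))
    for f, t, v in df.itertuples(index=False):
        M[idx[f], idx[t]] = v
    return pixels, M
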