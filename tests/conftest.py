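import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from divempa import ScenarioConfig, scenarios, synth
from divempa.world import GridWorld, Protection

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


def grid_world_from_coords(lonlat, dive=None, dives=None, area=2500.0,
                           country=None) -> GridWorld:
    """Hand-built world from a list of (lon, lat) centroids; all ocean."""
    n = len(lonlat)
    dive = set(dive or [])
    px = pd.DataFrame({
        "pixel_id": np.arange(n),
        "centroid_lon": [c[0] for c in lonlat],
        "centroid_lat": [c[1] for c in lonlat],
        "area_km2": area,
        "is_ocean": True,
        "has_diving": [i in dive for i in range(n)],
        "protection_status": Protection.UNPROTECTED.value,
        "region_label": "R1",
        "country_label": country if country is not None else "C1",
        "dives": dives if dives is not None else 0,
    })
    return GridWorld(px)


def small_bundle(seed: int, n_stocks: int = 8, n_species: int = 40):
    """Quick-to-build world for scenario-level tests: all traits empirical."""
    wcfg = synth.WorldGenConfig(nx=24, ny=24, dive_fraction=0.03, n_operators=200,
                                seed=seed)
    scfg = synth.StockGenConfig(n_stocks=n_stocks, empirical_fraction=1.0,
                                range_median=12.0)
    pcfg = synth.SpeciesGenConfig(n_species=n_species, range_median=15.0)
    return synth.generate_bundle(wcfg, scfg, pcfg)


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic world (40x40, 50 stocks, 200 species)."""
    return synth.generate_bundle(seed=7)


@pytest.fixture(scope="session")
def prepared(bundle):
    return scenarios.prepare_world(bundle, ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def small_prepared():
    b = small_bundle(seed=11)
    return scenarios.prepare_world(b, ScenarioConfig(seed=11))
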