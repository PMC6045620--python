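"""NetCDF and YAML plumbing for the command-line interface."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from .synthetic import SyntheticScenario

#: backend usable with a plain scipy install (classic NetCDF, CF metadata)
NETCDF_ENGINE = "scipy"


def write_netcdf(obj, path) -> None:
    obj.to_netcdf(path, engine=NETCDF_ENGINE, format="NETCDF3_64BIT")


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine=NETCDF_ENGINE).load()


def scenario_from_yaml(path, seed: int | None = None) -> SyntheticScenario:
    """Build a scenario from a YAML mapping of constructor fields."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        cfg["seed"] = seed
    return SyntheticScenario(**cfg)


def truth_dataset(scenario: SyntheticScenario) -> xr.Dataset:
    """Per-cell ground-truth table of a scenario as a dataset."""
    coords = {"lat": scenario.latitudes(), "lon": scenario.longitudes()}
    fields = {
        "beta_true": scenario.beta_true,
        "t_true": scenario.t_true.astype(float),
        "lag_true": scenario.lag_true.astype(float),
        "noise_sd": scenario.noise_sd,
        "trend_slope": scenario.trend_slope,
        "ba_baseline": scenario.ba_baseline,
        "zero_inflation_prob": scenario.zero_inflation_prob,
    }
    return xr.Dataset(
        {k: (("lat", "lon"), np.asarray(v, float)) for k, v in fields.items()},
        coords=coords,
    )
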