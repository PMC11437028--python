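"""File ingestion, result emission and run configuration.

CSV is the interchange format.  Time series come in two layouts:

* **long** — ``date, wavelength_nm, value`` plus optional per-record
  metadata columns (``tilt_deg``, ``depth_offset_m``, ``time_gmt``,
  ``cloud_flag``, ``quality_indicator``, ``manual_flag``, ``ed``);
* **wide** — ``date`` plus one numeric column per wavelength (used for
  Rrs spectra and for the boundary tables).

Dates are ISO-8601, interpreted as GMT.  Duplicate dates keep the first
record with a warning.  Results can additionally be written as NetCDF
(classic format through xarray's scipy backend) with CF-style time
coordinates and unit attributes.

The run configuration is a YAML document layered over the packaged REF
defaults; unknown keys are rejected with a field-level message and the
effective configuration can be echoed alongside any output for
provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .inversion import InversionSettings
from .optics import (
    BioOpticalConfig,
    CDOMParams,
    NAPParams,
    PhotoacclimationParams,
    PhytoOpticalParams,
    WaterIOP,
    WavelengthGrid,
)

RESULT_UNITS = {
    "chl": "mg m-3",
    "cdom": "mg C m-3",
    "nap": "mg C m-3",
    "j_final": "sr-2",
    "rrs": "sr-1",
    "kd": "m-1",
    "bbp": "m-1",
}

#: tolerance when matching observation bands to model wavelengths
WAVELENGTH_TOL_NM = 0.5


# ---------------------------------------------------------------------------
# Time-series ingestion
# ---------------------------------------------------------------------------

def _parse_dates(raw: pd.Series, path) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(pd.to_datetime(raw, format="ISO8601"))
    except (ValueError, TypeError):
        pass
    parsed = pd.to_datetime(raw, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(f"{path}: unparseable date at line {line}: {raw[bad].iloc[0]!r}")
    return pd.DatetimeIndex(parsed)


def read_timeseries(path, layout: str = "auto") -> pd.DataFrame:
    """Read a dated series in long or wide layout.

    Long layout returns the table as-is with parsed dates; wide layout
    returns a table indexed by date with the original value columns.
    ``layout='auto'`` sniffs for a ``wavelength_nm`` column.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'date'")
    if layout == "auto":
        layout = "long" if "wavelength_nm" in df.columns else "wide"
    if layout == "long":
        if "wavelength_nm" not in df.columns:
            raise SchemaError(f"{path}: long layout requires column 'wavelength_nm'")
        if "value" not in df.columns:
            raise SchemaError(f"{path}: long layout requires column 'value'")
        df = df.assign(date=_parse_dates(df["date"], path))
        dup = df.duplicated(subset=["date", "wavelength_nm"], keep="first")
        if dup.any():
            warnings.warn(f"{path}: duplicate (date, wavelength) rows kept first")
            df = df[~dup]
        return df.reset_index(drop=True)
    if layout != "wide":
        raise ConfigError(f"unknown layout {layout!r}")
    idx = _parse_dates(df["date"], path)
    out = df.drop(columns=["date"]).set_index(idx)
    if out.index.has_duplicates:
        warnings.warn(f"{path}: duplicate dates kept first")
        out = out[~out.index.duplicated(keep="first")]
    return out.sort_index()


def long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long series to a wide date × wavelength table."""
    wide = df.pivot_table(
        index="date", columns="wavelength_nm", values="value", aggfunc="first"
    )
    wide.columns = [f"{c:g}" for c in wide.columns]
    return wide


def write_results(results: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a dated result table as CSV or NetCDF.

    CSV keeps the documented column order; NetCDF (classic format) carries
    a CF-style ``time`` coordinate and unit attributes.  Empty results
    produce a header-only file.
    """
    path = Path(path)
    if format == "csv":
        results.to_csv(path, index=True, index_label=results.index.name or "date")
        return
    if format != "netcdf":
        raise ConfigError(f"unknown output format {format!r}")
    import xarray as xr

    ds = xr.Dataset.from_dataframe(
        results.rename_axis("time") if results.index.name != "time" else results
    )
    for name in ds.data_vars:
        key = str(name).split("_")[0]
        if key in RESULT_UNITS:
            ds[name].attrs["units"] = RESULT_UNITS[key]
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully validated run configuration."""

    bio_optics: BioOpticalConfig
    geometry: dict
    surface: dict
    inversion: InversionSettings
    qc: dict
    log_level: str
    raw: dict

    def echo(self) -> str:
        """The effective configuration as YAML, for provenance."""
        return yaml.safe_dump(self.raw, sort_keys=False)


def _default_config_dict() -> dict:
    with resources.files("tristream.data").joinpath("ref_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(defaults: dict, override: dict, prefix: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        where = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where}: expected a mapping")
            out[key] = _merge(defaults[key], value, prefix=f"{where}.")
        else:
            out[key] = value
    return out


def load_config(path=None, iop_table=None) -> RunConfig:
    """Load the run configuration: packaged REF defaults overlaid with an
    optional user YAML file and an optional replacement IOP table (CSV with
    the same columns as the packaged one)."""
    raw = _default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        raw = _merge(raw, user)

    grid = WavelengthGrid(tuple(float(v) for v in raw["wavelengths"]))
    if iop_table is not None:
        table = pd.read_csv(iop_table)
        required = {
            "wavelength_nm", "a_w", "b_w", "b_bw",
            "a_star_ph", "b_star_ph", "b_star_bph",
        }
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"{iop_table}: missing columns {sorted(missing)}")
    else:
        from .optics import load_ref_table

        table = load_ref_table()
    table_grid = WavelengthGrid(tuple(table["wavelength_nm"]))
    if table_grid.wavelengths != grid.wavelengths:
        raise ConfigError("IOP table wavelengths do not match configured grid")

    try:
        bio = BioOpticalConfig(
            grid=grid,
            water=WaterIOP(
                grid,
                table["a_w"].to_numpy(),
                table["b_w"].to_numpy(),
                table["b_bw"].to_numpy(),
            ),
            phyto=PhytoOpticalParams(
                grid,
                table["a_star_ph"].to_numpy(),
                table["b_star_ph"].to_numpy(),
                table["b_star_bph"].to_numpy(),
            ),
            cdom=CDOMParams(**raw["cdom"]),
            nap=NAPParams(**raw["nap"]),
            photo=PhotoacclimationParams(**raw["photoacclimation"]),
        )
    except TypeError as exc:
        raise ConfigError(f"invalid parameter block: {exc}") from exc

    inv = raw["inversion"]
    settings = InversionSettings(
        bounds={
            "chl": tuple(float(v) for v in inv["chl_bounds"]),
            "cdom": tuple(float(v) for v in inv["cdom_bounds"]),
            "nap": tuple(float(v) for v in inv["nap_bounds"]),
        },
        n_starts=int(inv["n_starts"]),
        seed=int(inv["seed"]),
        maxiter=int(inv["maxiter"]),
        ftol=float(inv["ftol"]),
        min_wavelengths=int(inv["min_wavelengths"]),
        surface_mode=raw["surface"]["mode"],
    )
    return RunConfig(
        bio_optics=bio,
        geometry=dict(raw["geometry"]),
        surface=dict(raw["surface"]),
        inversion=settings,
        qc=dict(raw["qc"]),
        log_level=str(raw["logging"]["level"]),
        raw=raw,
    )
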