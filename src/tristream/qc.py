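"""Quality control of radiometric time series.

Implements the observational preprocessing chain applied before inversion
and validation: single-pass 3-σ outlier clipping, Savitzky–Golay (SG)
smoothing of daily series, and the record-level filters for moored-buoy
Kd data (acquisition time window, instrument tilt, sensor depth offset,
minimum irradiance, negative-spectrum rejection) and for satellite Rrs
(cloud flag, quality-indicator clipping).

Series are long-format pandas DataFrames with columns ``date``,
``wavelength_nm``, ``value`` plus optional per-record metadata
(``tilt_deg``, ``depth_offset_m``, ``time_gmt``, ``cloud_flag``,
``quality_indicator``, ``manual_flag``, ``ed``).  Every stage is
non-expansive (never adds records) and reports how many records it
removed; smoothing changes values, never counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError, EmptyOutputError

logger = logging.getLogger(__name__)

TIME_WINDOW_GMT = ("10:00", "14:00")  # closed interval
MAX_TILT_DEG = 10.0                   # closed: 10.0 kept
MAX_DEPTH_OFFSET_M = 2.0              # closed: 2.0 kept
MIN_ED = 0.005                        # uW cm^-2 nm^-1
SG_WINDOW = 11                        # samples; 10-day span on daily data
SG_POLYORDER = 3
SIGMA_K = 3.0


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def sigma_clip(values: pd.Series, k: float = SIGMA_K) -> tuple[pd.Series, int]:
    """Single-pass k-σ clip about the series mean (sample std, ddof=1).

    Removes points with \\|v − mean\\| > k·sd; mean and sd are computed once
    over the whole series.  Returns ``(filtered, n_removed)``.
    """
    finite = values[np.isfinite(values)]
    if len(finite) < 3:
        raise DataError("sigma_clip needs at least 3 finite values")
    mean = finite.mean()
    sd = finite.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return values, 0
    keep = ~(np.abs(values - mean) > k * sd)
    return values[keep], int((~keep).sum())


def sg_smooth(
    series: pd.Series,
    poly_order: int = SG_POLYORDER,
    window: int = SG_WINDOW,
) -> tuple[pd.Series, pd.Series]:
    """Savitzky–Golay smoothing of a daily series, per contiguous segment.

    ``series`` is indexed by date (daily resolution).  Each maximal run of
    consecutive days at least ``window`` samples long is smoothed with a
    centred least-squares polynomial filter; shorter segments are passed
    through unsmoothed and flagged.  Returns ``(smoothed, unsmoothed_flag)``.

    An odd window is required for a symmetric centred filter; the default
    11-sample window realises a 10-day smoothing span on daily data.
    """
    if window % 2 == 0 or window < 3:
        raise ConfigError("SG window must be odd and >= 3")
    if poly_order >= window:
        raise ConfigError("SG polynomial order must be < window length")
    if series.empty:
        return series.copy(), pd.Series(dtype=bool)

    series = series.sort_index()
    dates = pd.DatetimeIndex(series.index)
    gap = dates.to_series().diff().dt.days.fillna(1).to_numpy()
    segment = np.cumsum(gap != 1)

    out = series.copy().astype(float)
    flag = pd.Series(False, index=series.index)
    for _, idx in pd.Series(series.index).groupby(segment):
        seg_index = idx.to_numpy()
        if len(seg_index) >= window:
            out.loc[seg_index] = savgol_filter(
                series.loc[seg_index].to_numpy(dtype=float), window, poly_order
            )
        else:
            flag.loc[seg_index] = True
    return out, flag


def daily_average(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of finite values per calendar day (GMT) and wavelength.

    ``df`` needs ``date`` (timestamps), ``wavelength_nm`` and ``value``.
    """
    _require(df, ("date", "wavelength_nm", "value"))
    work = df.copy()
    work["date"] = pd.to_datetime(work["date"]).dt.normalize()
    grouped = (
        work.groupby(["date", "wavelength_nm"])["value"]
        .mean()  # pandas mean skips NaN: mean of finite values only
        .reset_index()
    )
    return grouped


# ---------------------------------------------------------------------------
# Record-level filter stages
# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"series is missing required columns {missing}")


def _parse_minutes(value) -> float:
    if isinstance(value, str):
        hh, mm = value.split(":")[:2]
        return int(hh) * 60 + int(mm)
    t = pd.to_datetime(value)
    return t.hour * 60 + t.minute


def _drop(df, keep_mask, stage, report):
    removed = int((~keep_mask).sum())
    report["removed"][stage] = removed
    out = df[keep_mask]
    if out.empty:
        raise EmptyOutputError(stage)
    return out


def _clip_per_wavelength(df, column, stage, report, k):
    keep = pd.Series(True, index=df.index)
    for _, group in df.groupby("wavelength_nm"):
        vals = group[column].astype(float)
        if len(vals[np.isfinite(vals)]) < 3:
            continue
        kept, _ = sigma_clip(vals, k=k)
        keep.loc[group.index.difference(kept.index)] = False
    return _drop(df, keep, stage, report)


def _smooth_per_wavelength(df, poly_order, window, report):
    out = df.copy()
    n_unsmoothed = 0
    for _, group in df.groupby("wavelength_nm"):
        series = pd.Series(
            group["value"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(pd.to_datetime(group["date"])),
        )
        smoothed, flag = sg_smooth(series, poly_order=poly_order, window=window)
        out.loc[group.index, "value"] = smoothed.to_numpy()
        n_unsmoothed += int(flag.sum())
    report["removed"]["smoothing"] = 0  # smoothing never changes counts
    report["n_unsmoothed_records"] = n_unsmoothed
    return out


def _new_report(df) -> dict:
    return {"n_in": int(len(df)), "removed": {}}


def _finalize(df, report) -> dict:
    report["n_out"] = int(len(df))
    assert report["n_in"] - sum(report["removed"].values()) == report["n_out"]
    return report


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

def qc_rrs_series(
    df: pd.DataFrame,
    k: float = SIGMA_K,
    poly_order: int = SG_POLYORDER,
    window: int = SG_WINDOW,
) -> tuple[pd.DataFrame, dict]:
    """QC chain for satellite Rrs: cloud screening → quality-indicator σ-clip
    per wavelength → SG smoothing per wavelength.

    Missing ``cloud_flag``/``quality_indicator`` columns are treated as
    all-pass (logged).  An optional truthy ``manual_flag`` column removes
    visually rejected records first.  Returns ``(series, report)``.
    """
    _require(df, ("date", "wavelength_nm", "value"))
    df = df.sort_values(["wavelength_nm", "date"])
    report = _new_report(df)

    if "manual_flag" in df.columns:
        df = _drop(df, ~df["manual_flag"].fillna(False).astype(bool), "manual", report)

    if "cloud_flag" in df.columns:
        df = _drop(df, ~df["cloud_flag"].fillna(False).astype(bool), "cloud", report)
    else:
        logger.info("no cloud_flag column: cloud screening skipped")
        report["removed"]["cloud"] = 0

    if "quality_indicator" in df.columns:
        df = _clip_per_wavelength(df, "quality_indicator", "indicator_outlier", report, k)
    else:
        logger.info("no quality_indicator column: indicator clipping skipped")
        report["removed"]["indicator_outlier"] = 0

    df = _smooth_per_wavelength(df, poly_order, window, report)
    return df, _finalize(df, report)


def qc_kd_series(
    df: pd.DataFrame,
    k: float = SIGMA_K,
    poly_order: int = SG_POLYORDER,
    window: int = SG_WINDOW,
    time_window: tuple[str, str] = TIME_WINDOW_GMT,
    max_tilt: float = MAX_TILT_DEG,
    max_depth_offset: float = MAX_DEPTH_OFFSET_M,
    min_ed: float = MIN_ED,
) -> tuple[pd.DataFrame, dict]:
    """QC chain for buoy Kd series.

    Stages (each applied only when its metadata column is present):
    acquisition-time window [10:00, 14:00] GMT (closed) → absolute tilt
    ≤ 10° (closed) → sensor depth offset ≤ 2 m (closed) → minimum upstream
    irradiance E_d ≥ 0.005 µW cm⁻² nm⁻¹ → σ-clip per wavelength →
    rejection of non-positive Kd → SG smoothing.  Returns
    ``(series, report)``.
    """
    _require(df, ("date", "wavelength_nm", "value"))
    df = df.sort_values(["wavelength_nm", "date"])
    report = _new_report(df)

    if "manual_flag" in df.columns:
        df = _drop(df, ~df["manual_flag"].fillna(False).astype(bool), "manual", report)

    if "time_gmt" in df.columns:
        lo = _parse_minutes(time_window[0])
        hi = _parse_minutes(time_window[1])
        minutes = df["time_gmt"].map(_parse_minutes)
        df = _drop(df, (minutes >= lo) & (minutes <= hi), "time_window", report)

    if "tilt_deg" in df.columns:
        df = _drop(df, df["tilt_deg"].abs() <= max_tilt, "tilt", report)

    if "depth_offset_m" in df.columns:
        df = _drop(df, df["depth_offset_m"].abs() <= max_depth_offset, "depth", report)

    if "ed" in df.columns:
        df = _drop(df, df["ed"] >= min_ed, "min_irradiance", report)

    df = _clip_per_wavelength(df, "value", "sigma_clip", report, k)
    df = _drop(df, df["value"] > 0, "non_positive", report)
    df = _smooth_per_wavelength(df, poly_order, window, report)
    return df, _finalize(df, report)
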