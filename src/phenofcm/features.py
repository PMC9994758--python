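"""Predictor variables and the clustering element space.

Each field-date element is described by up to 32 candidate features:

* 11 vegetation indices (VIs) computed from field-mean Sentinel-2
  surface reflectances,
* their 11 cumulative integrals over the season (prefix ``I_``),
* 8 accumulated weather/soil variables (prefix ``acc_``), including
  accumulated growing degree days (AGDD, base 15.6 degC for cotton),
* the sine and cosine encoding of the acquisition day of year.

Accumulations start at DoY 100 (around the earliest sowing date) and,
crucially, only ever use data up to the element's own date, so the same
feature rows serve after-season training and within-season prediction.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "VI_NAMES",
    "WEATHER_ACC_VARIABLES",
    "FEATURE_VOCABULARY",
    "DOY_FEATURES",
    "START_DOY",
    "T_BASE_COTTON",
    "compute_vi",
    "gdd",
    "doy_encoding",
    "interpolate_gaps",
    "accumulate_weather",
    "cumulative_integral_vi",
    "assemble_element_space",
]

BANDS = ("B02", "B03", "B04", "B06", "B08", "B11", "B12")

#: Cotton base temperature (degC) below which development stops.
T_BASE_COTTON = 15.6

#: Season start for all accumulations: DoY 100 (10 April), around the
#: earliest sowing date in the study region.
START_DOY = 100

DOY_PERIOD = 365.25

_EPS = 1e-12


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division; zero denominators yield NaN (gap-filled later)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) > _EPS
    np.divide(num, den, out=out, where=ok)
    return out


# Table of VI formulas on field-mean reflectances. Constants as commonly
# printed: SAVI soil factor 0.428, WDRVI alpha 0.2, GVMI offsets 0.1/0.02.
_VI_FORMULAS: Dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "NDVI": lambda b: _safe_div(b.B08 - b.B04, b.B08 + b.B04),
    "NDWI": lambda b: _safe_div(b.B03 - b.B08, b.B08 + b.B03),
    "NDMI": lambda b: _safe_div(b.B08 - b.B11, b.B08 + b.B11),
    "PSRI": lambda b: _safe_div(b.B04 - b.B02, b.B06),
    "SAVI": lambda b: _safe_div(b.B08 - b.B04, b.B08 + b.B04 + 0.428) * (1.0 + 0.428),
    "EVI": lambda b: _safe_div(2.5 * (b.B08 - b.B04), (b.B08 + 6.0 * b.B04 - 7.5 * b.B02) + 1.0),
    "VARIgreen": lambda b: _safe_div(b.B03 - b.B04, b.B03 + b.B04 - b.B02),
    "GARI": lambda b: _safe_div(b.B08 - (b.B03 - (b.B02 - b.B04)), b.B08 - (b.B03 + (b.B02 - b.B04))),
    "SIPI": lambda b: _safe_div(b.B08 - b.B02, b.B08 - b.B04),
    "WDRVI": lambda b: _safe_div(0.2 * b.B08 - b.B04, 0.2 * b.B08 + b.B04),
    "GVMI": lambda b: _safe_div((b.B08 + 0.1) - (b.B12 + 0.02), (b.B08 + 0.1) + (b.B12 + 0.02)),
}

VI_NAMES = tuple(_VI_FORMULAS)

#: Daily weather/soil quantities offered as accumulated features.  Soil
#: moisture is accumulated as the daily mean of its min/max pair.
WEATHER_ACC_VARIABLES = (
    "gdd",
    "tsurf_min",
    "tsurf_max",
    "tsoil_min",
    "tsoil_max",
    "soilmoist",
    "precip",
    "swrad",
)

DOY_FEATURES = ("sin_doy", "cos_doy")

FEATURE_VOCABULARY = (
    VI_NAMES
    + tuple(f"I_{v}" for v in VI_NAMES)
    + tuple(f"acc_{v}" for v in WEATHER_ACC_VARIABLES)
    + DOY_FEATURES
)

WEATHER_COLUMNS = (
    "t2m_min",
    "t2m_max",
    "tsurf_min",
    "tsurf_max",
    "tsoil_min",
    "tsoil_max",
    "soilmoist_min",
    "soilmoist_max",
    "precip",
    "swrad",
)


def compute_vi(sample, vi_name: str):
    """Evaluate one vegetation index on a band record or band table.

    ``sample`` may be a mapping / Series with band keys or a DataFrame
    with band columns; returns a float (scalar input) or ndarray.
    Zero-denominator cases return NaN, to be gap-filled downstream.
    """
    if vi_name not in _VI_FORMULAS:
        raise ValueError(f"unknown vegetation index {vi_name!r}")
    if isinstance(sample, pd.DataFrame):
        frame = sample
        scalar = False
    else:
        frame = pd.DataFrame({b: [float(sample[b])] for b in BANDS if b in sample})
        scalar = True
    out = np.asarray(_VI_FORMULAS[vi_name](frame), dtype=float)
    return float(out[0]) if scalar else out


def gdd(t2m_max, t2m_min, t_base: float = T_BASE_COTTON):
    """Daily growing degree days: max(0, (Tmax + Tmin)/2 - Tbase).

    Thermal time accumulated above the cotton base temperature
    (15.6 degC); days whose mean temperature falls below the base
    contribute zero rather than negative development.
    """
    t2m_max = np.asarray(t2m_max, dtype=float)
    t2m_min = np.asarray(t2m_min, dtype=float)
    if np.any(t2m_min > t2m_max + 1e-9):
        raise ValueError("daily minimum temperature exceeds the maximum")
    out = np.maximum(0.0, (t2m_max + t2m_min) / 2.0 - t_base)
    return float(out) if out.ndim == 0 else out


def doy_encoding(doy):
    """Cyclic (sin, cos) encoding of day of year with a one-year period."""
    doy_arr = np.asarray(doy, dtype=float)
    if np.any((doy_arr < 1) | (doy_arr > 366)):
        raise ValueError("day of year must lie in 1..366")
    angle = 2.0 * np.pi * doy_arr / DOY_PERIOD
    s, c = np.sin(angle), np.cos(angle)
    if s.ndim == 0:
        return float(s), float(c)
    return s, c


def interpolate_gaps(series: pd.Series) -> pd.Series:
    """Fill NaNs in a DoY-indexed series by linear interpolation.

    Interior gaps are interpolated linearly in DoY between defined
    neighbours; leading/trailing gaps take the nearest defined value.
    At least two defined points are required.
    """
    values = series.to_numpy(dtype=float)
    doys = series.index.to_numpy(dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError(
            "fewer than 2 defined points in the series; field must be excluded"
        )
    filled = np.interp(doys, doys[defined], values[defined])
    return pd.Series(filled, index=series.index, name=series.name)


def accumulate_weather(
    series: pd.DataFrame,
    variable: str,
    start_doy: int = START_DOY,
    upto_doy: Optional[int] = None,
):
    """Sum a daily weather variable over [start_doy, upto_doy] for one field.

    ``variable`` is one of :data:`WEATHER_ACC_VARIABLES`; ``gdd`` sums
    the daily growing-degree-day values and ``soilmoist`` the daily mean
    of the min/max soil-moisture pair.  Every day in the window must be
    present.
    """
    daily = daily_accumulation_basis(series, variable)
    if upto_doy is None:
        upto_doy = int(daily.index.max())
    window = np.arange(start_doy, upto_doy + 1)
    missing = np.setdiff1d(window, daily.index.to_numpy())
    if missing.size:
        raise ValueError(
            f"daily coverage incomplete for {variable!r}: missing DoYs {missing.tolist()}"
        )
    return float(daily.loc[window[0]: window[-1]].sum())


def daily_accumulation_basis(series: pd.DataFrame, variable: str) -> pd.Series:
    """Daily values underlying an accumulated feature, indexed by DoY."""
    if variable not in WEATHER_ACC_VARIABLES:
        raise ValueError(f"unknown accumulated weather variable {variable!r}")
    df = series.sort_values("doy").set_index("doy")
    if variable == "gdd":
        daily = pd.Series(
            gdd(df["t2m_max"].to_numpy(), df["t2m_min"].to_numpy()), index=df.index
        )
    elif variable == "soilmoist":
        daily = (df["soilmoist_min"] + df["soilmoist_max"]) / 2.0
    else:
        daily = df[variable]
    return daily


def cumulative_integral_vi(
    series: pd.Series,
    start_doy: int = START_DOY,
    upto_doy: Optional[int] = None,
) -> float:
    """Trapezoidal integral of a gap-filled VI series over DoY.

    Integrates from ``start_doy`` (or the first acquisition, if later)
    up to ``upto_doy``; a zero-width window integrates to 0.
    """
    if upto_doy is None:
        upto_doy = int(series.index.max())
    if upto_doy < start_doy:
        raise ValueError("upto_doy precedes start_doy")
    doys = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    mask = (doys >= start_doy) & (doys <= upto_doy)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(vals[mask], doys[mask]))


def _resolve_feature_set(feature_set: Optional[Iterable[str]]) -> list:
    if feature_set is None:
        return list(FEATURE_VOCABULARY)
    feats = list(dict.fromkeys(feature_set))
    unknown = [f for f in feats if f not in FEATURE_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    for required in DOY_FEATURES:
        if required not in feats:
            feats.append(required)
    return feats


def assemble_element_space(
    bands: pd.DataFrame,
    weather: pd.DataFrame,
    feature_set: Optional[Sequence[str]] = None,
    start_doy: int = START_DOY,
) -> pd.DataFrame:
    """Build the K x E clustering element space from band and weather tables.

    Parameters
    ----------
    bands : DataFrame
        Long table with columns ``field_id``, ``doy`` and the seven
        Sentinel-2 band reflectances; one row per available acquisition
        (cloudy dates may be absent — VI series are gap-filled onto the
        union of acquisition DoYs).
    weather : DataFrame
        Daily table with ``field_id``, ``doy`` and the ten weather
        columns, covering [start_doy, last acquisition] per field.
    feature_set : sequence of str, optional
        Subset of the 32-name vocabulary; ``sin_doy``/``cos_doy`` are
        always included.  Default: the full vocabulary.
    start_doy : int
        Season start for accumulations and integrals.

    Returns
    -------
    DataFrame indexed by (field_id, doy) with one column per feature and
    no missing values; K = n_fields x n_acquisition_DoYs.
    """
    feats = _resolve_feature_set(feature_set)
    grid = np.sort(bands.loc[bands["doy"] >= start_doy, "doy"].unique())
    if grid.size < 2:
        raise ValueError("need at least two acquisition DoYs at or after start_doy")
    field_ids = sorted(bands["field_id"].unique())

    vi_wanted = sorted(
        {f for f in feats if f in VI_NAMES}
        | {f[2:] for f in feats if f.startswith("I_")}
    )
    acc_wanted = [f[4:] for f in feats if f.startswith("acc_")]

    index = pd.MultiIndex.from_product([field_ids, grid], names=["field_id", "doy"])
    out = pd.DataFrame(index=index, columns=feats, dtype=float)

    sin_d, cos_d = doy_encoding(grid.astype(float))
    doy_lookup = pd.DataFrame({"sin_doy": sin_d, "cos_doy": cos_d}, index=grid)

    bands_by_field = dict(tuple(bands.groupby("field_id")))
    weather_by_field = (
        dict(tuple(weather.groupby("field_id"))) if acc_wanted else {}
    )

    for fid in field_ids:
        fb = bands_by_field[fid].sort_values("doy")
        raw = fb.set_index("doy").reindex(grid)  # NaN rows where clouds dropped dates
        for vi in vi_wanted:
            series = pd.Series(compute_vi(raw, vi), index=grid)
            filled = interpolate_gaps(series)
            if vi in feats:
                out.loc[(fid,), vi] = filled.to_numpy()
            iname = f"I_{vi}"
            if iname in feats:
                out.loc[(fid,), iname] = [
                    cumulative_integral_vi(filled, start_doy, int(d)) for d in grid
                ]
        if acc_wanted:
            fw = weather_by_field[fid]
            for var in acc_wanted:
                daily = daily_accumulation_basis(fw, var)
                window = np.arange(start_doy, int(grid[-1]) + 1)
                missing = np.setdiff1d(window, daily.index.to_numpy())
                if missing.size:
                    raise ValueError(
                        f"field {fid}: missing daily weather for DoYs {missing.tolist()}"
                    )
                csum = daily.loc[start_doy:].cumsum()
                out.loc[(fid,), f"acc_{var}"] = csum.reindex(grid).to_numpy()
        out.loc[(fid,), "sin_doy"] = doy_lookup["sin_doy"].to_numpy()
        out.loc[(fid,), "cos_doy"] = doy_lookup["cos_doy"].to_numpy()

    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"element space has unfilled values in columns {bad}")
    return out
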