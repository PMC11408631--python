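"""Otolith-d18O isoscapes and interval-mask geolocation.

An isoscape is a spatial grid of the otolith d18O a fish would have recorded
had it lived at each grid cell over a given ontogenetic window.  It is built
from gridded temperature and salinity at 10 m depth through two empirical
linear relations:

* seawater d18O (VSMOW) from salinity, per region:
  ``d18O_w = slope_region * S + intercept_region``;
* otolith d18O (VPDB) from temperature and seawater d18O:
  ``d18O_oto = frac_slope * T + frac_intercept + d18O_w + water_scale_offset``
  with ``frac_slope < 0`` (otolith d18O decreases with temperature); the
  constant ``water_scale_offset`` carries the VSMOW-to-VPDB scale handling.

The default coefficients shipped here are documented placeholders of the
right order of magnitude for temperate Pacific waters, used by tests and the
synthetic generator; for any real-data application they are mandatory inputs
taken from the calibration literature for the species and region at hand.

Potential nursery areas are the grid cells whose predicted otolith d18O falls
within the observed group mean +/- 1 SD, computed per assumed hatch date and
aggregated into a match-count grid over the hatch-date grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr


class CoverageError(ValueError):
    """The requested window is not covered by the environmental day axis."""


@dataclass(frozen=True)
class IsotopeModelParams:
    """Coefficients of the two empirical linear relations.

    Defaults are NON-AUTHORITATIVE placeholders (plausible magnitudes for
    temperate NW-Pacific waters) for synthetic work; real applications must
    supply calibrated values via configuration.
    """

    frac_slope: float = -0.18  # permil / degC, must be negative
    frac_intercept: float = 2.7  # permil
    water_scale_offset: float = -0.27  # permil, VSMOW -> VPDB handling
    salinity_relations: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (0.28, -9.4)}  # permil/psu, permil
    )

    def __post_init__(self) -> None:
        if not self.frac_slope < 0:
            raise ValueError(
                "frac_slope must be negative: otolith d18O decreases with temperature"
            )
        if not self.salinity_relations:
            raise ValueError("at least one regional salinity relation is required")


@dataclass
class Isoscape:
    """Grid of predicted otolith d18O for one hatch date and window."""

    d18O: xr.DataArray  # dims (lat, lon), permil VPDB, NaN where missing
    hatch_date: pd.Timestamp
    window: tuple[int, int]
    params: IsotopeModelParams


@dataclass
class AssignmentResult:
    """Per-hatch-date boolean masks and their aggregated match counts."""

    masks: xr.DataArray  # dims (hatch_date, lat, lon), bool
    counts: xr.DataArray  # dims (lat, lon), int
    hatch_dates: list[pd.Timestamp]
    band: tuple[float, float]  # (mu, sigma) used


def hatch_date_grid(
    start: str | pd.Timestamp, end: str | pd.Timestamp, step_days: int = 3
) -> list[pd.Timestamp]:
    """Arithmetic date sequence from ``start`` to at most ``end`` inclusive."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError(f"start {start.date()} is after end {end.date()}")
    if step_days < 1:
        raise ValueError("step_days must be >= 1")
    return list(pd.date_range(start, end, freq=f"{step_days}D"))


def window_mean_fields(
    env: xr.Dataset,
    hatch_date: str | pd.Timestamp,
    window: tuple[int, int],
    min_coverage: float = 1.0,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Per-cell mean temperature and salinity over a dph window.

    The window ``(a, b)`` is closed in days post hatch: days
    ``hatch_date + a ... hatch_date + b`` inclusive.  Under strict missing-data
    handling (``min_coverage=1.0``, default) a cell missing on any day is
    missing in the output; lower ``min_coverage`` (e.g. 0.8) averages over the
    available days where the covered fraction is at least that.
    """
    hatch = pd.Timestamp(hatch_date)
    a, b = int(window[0]), int(window[1])
    lo, hi = hatch + pd.Timedelta(days=a), hatch + pd.Timedelta(days=b)
    days = pd.to_datetime(env["day"].values)
    if lo < days.min() or hi > days.max():
        raise CoverageError(
            f"window [{lo.date()}, {hi.date()}] outside environment day axis "
            f"[{days.min().date()}, {days.max().date()}]"
        )
    sub = env.sel(day=slice(lo, hi))
    n_days = sub.sizes["day"]
    tbar = sub["temp_10m"].mean("day", skipna=True)
    sbar = sub["sal_10m"].mean("day", skipna=True)
    frac = sub["temp_10m"].notnull().sum("day") / n_days
    ok = frac >= min_coverage - 1e-12
    return tbar.where(ok), sbar.where(ok)


def predict_water_d18O(
    sal: xr.DataArray | np.ndarray | float,
    region_id: xr.DataArray | np.ndarray | int,
    params: IsotopeModelParams,
) -> xr.DataArray | np.ndarray | float:
    """Seawater d18O (VSMOW) from salinity through the regional linear relation."""
    rid = np.asarray(region_id)
    present = set(np.unique(rid).astype(int).tolist())
    unknown = present - set(params.salinity_relations)
    if unknown:
        raise KeyError(f"no salinity relation for region id(s) {sorted(unknown)}")
    slope = np.zeros(rid.shape, dtype=float)
    intercept = np.zeros(rid.shape, dtype=float)
    for r, (m, c) in params.salinity_relations.items():
        slope = np.where(rid == r, m, slope)
        intercept = np.where(rid == r, c, intercept)
    sal_vals = sal.values if isinstance(sal, xr.DataArray) else np.asarray(sal, dtype=float)
    out = sal_vals * slope + intercept
    if isinstance(sal, xr.DataArray):
        return xr.DataArray(out, coords=sal.coords, dims=sal.dims)
    if np.isscalar(sal) or out.ndim == 0:
        return float(out)
    return out


def predict_otolith_d18O(
    T: xr.DataArray | np.ndarray | float,
    d18O_w: xr.DataArray | np.ndarray | float,
    params: IsotopeModelParams,
) -> xr.DataArray | np.ndarray | float:
    """Otolith d18O (VPDB) from temperature and seawater d18O (linear
    thermometry form)."""
    return params.frac_slope * T + params.frac_intercept + d18O_w + params.water_scale_offset


def _region_grid(env: xr.Dataset) -> np.ndarray:
    if "region_id" in env:
        return env["region_id"].values
    return np.zeros((env.sizes["lat"], env.sizes["lon"]), dtype=int)


def build_isoscape(
    env: xr.Dataset,
    hatch_date: str | pd.Timestamp,
    window: tuple[int, int],
    params: IsotopeModelParams,
    order: Literal["average_first", "transform_first"] = "average_first",
    min_coverage: float = 1.0,
) -> Isoscape:
    """Predicted otolith-d18O grid for one hatch date and ontogenetic window.

    ``average_first`` (default) averages the environment over the window and
    then applies the two linear relations; ``transform_first`` transforms each
    day and averages the predictions.  Both relations being linear, the two
    orders agree exactly on complete data and differ only in missing-data
    handling.
    """
    rid = _region_grid(env)
    if order == "average_first":
        tbar, sbar = window_mean_fields(env, hatch_date, window, min_coverage)
        d18O_w = predict_water_d18O(sbar.values, rid, params)
        grid = predict_otolith_d18O(tbar.values, d18O_w, params)
        out = xr.DataArray(grid, coords=tbar.coords, name="otolith_d18O")
    elif order == "transform_first":
        hatch = pd.Timestamp(hatch_date)
        lo = hatch + pd.Timedelta(days=int(window[0]))
        hi = hatch + pd.Timedelta(days=int(window[1]))
        days = pd.to_datetime(env["day"].values)
        if lo < days.min() or hi > days.max():
            raise CoverageError("window outside environment day axis")
        sub = env.sel(day=slice(lo, hi))
        d18O_w = predict_water_d18O(sub["sal_10m"].values, rid[None, :, :], params)
        daily = predict_otolith_d18O(sub["temp_10m"].values, d18O_w, params)
        n_days = sub.sizes["day"]
        frac = np.isfinite(daily).sum(axis=0) / n_days
        with np.errstate(invalid="ignore"):
            grid = np.nanmean(daily, axis=0)
        grid = np.where(frac >= min_coverage - 1e-12, grid, np.nan)
        out = xr.DataArray(
            grid,
            coords={"lat": env["lat"], "lon": env["lon"]},
            dims=("lat", "lon"),
            name="otolith_d18O",
        )
    else:
        raise ValueError(f"unknown order {order!r}")
    return Isoscape(
        d18O=out, hatch_date=pd.Timestamp(hatch_date), window=(int(window[0]), int(window[1])), params=params
    )


def assignment_mask(isoscape: Isoscape, mu: float, sigma: float) -> xr.DataArray:
    """Cells whose predicted otolith d18O lies within [mu - sigma, mu + sigma]
    (closed interval).  Missing cells are False and counted in the
    ``n_missing`` attribute."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    vals = isoscape.d18O
    mask = (vals >= mu - sigma) & (vals <= mu + sigma)
    mask = mask.where(vals.notnull(), False).astype(bool)
    mask.attrs["n_missing"] = int(vals.isnull().sum())
    mask.name = "match"
    return mask


def aggregate_hatch_masks(
    masks: Sequence[xr.DataArray],
    hatch_dates: Sequence[pd.Timestamp] | None = None,
    band: tuple[float, float] = (np.nan, np.nan),
) -> AssignmentResult:
    """Stack per-hatch-date masks and count, per cell, over how many hatch
    dates the environment matches the observed band."""
    if not masks:
        raise ValueError("no masks to aggregate")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks have mismatching shapes: {shapes}")
    if hatch_dates is None:
        hatch_dates = [pd.Timestamp("NaT")] * len(masks)
    stacked = xr.concat(
        [m.astype(bool) for m in masks],
        dim=pd.Index(list(hatch_dates), name="hatch_date"),
    )
    counts = stacked.sum("hatch_date").astype(int)
    counts.name = "match_count"
    return AssignmentResult(
        masks=stacked, counts=counts, hatch_dates=list(hatch_dates), band=tuple(band)
    )


def mask_to_table(mask: xr.DataArray) -> pd.DataFrame:
    """Matching cell coordinates of a boolean mask as a (lat, lon) table."""
    lat, lon = np.meshgrid(mask["lat"].values, mask["lon"].values, indexing="ij")
    sel = mask.values.astype(bool)
    return pd.DataFrame({"lat": lat[sel], "lon": lon[sel]})
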