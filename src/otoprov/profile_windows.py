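"""Rescale heterogeneous micromill profiles onto fixed ontogenetic windows.

Micromill profiles come at whatever resolution the milling allowed (typically
5-30 days or 30-160 um per segment).  The analysis works on two ontogenetic
windows: the larval stage, 0-60 days post hatch (dph), and the juvenile
stage, 106-120 dph.  A segment contributes to a window when the median of its
estimated age range falls inside the closed window; contributing segments are
averaged weighted by the width of the milled area (um by default; a day-span
weighting is available as a config switch).

For otoliths without daily-increment readings, segment age ranges are
estimated from distance to the core through a radius-age curve fitted to the
mean radius-at-age of increment-read fish from the same capture year, season
(calendar quarter) and region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from otoprov.data_io import (
    AcidTemp,
    Dataset,
    Label,
    MillSegment,
    OtolithProfile,
    Region,
)

#: Larval-stage window, closed interval in days post hatch.
LARVAL_WINDOW: tuple[float, float] = (0.0, 60.0)
#: Juvenile-stage window, closed interval in days post hatch.
JUVENILE_WINDOW: tuple[float, float] = (106.0, 120.0)

#: Offset (permil) subtracted from d18O measured after 72 degC acid digestion,
#: accounting for the temperature dependence of the calcite/aragonite acid
#: fractionation factor difference, so values are comparable with 25 degC runs.
ACID_CORRECTION_72C_PERMIL = -0.09


class DoubleCorrectionError(RuntimeError):
    """The acid-fractionation correction was applied to already-corrected data."""


def correct_acid_fractionation(d18O: float, acid_temp: AcidTemp | str) -> float:
    """Return d18O adjusted onto the 25 degC acid-digestion scale.

    Values analysed at 72 degC are shifted by ``ACID_CORRECTION_72C_PERMIL``
    (-0.09 permil); values analysed at 25 degC are already comparable and are
    returned unchanged.  d13C needs no such adjustment.
    """
    temp = AcidTemp(acid_temp)
    if temp is AcidTemp.T72:
        return d18O + ACID_CORRECTION_72C_PERMIL
    return d18O


def apply_acid_correction(dataset: Dataset) -> Dataset:
    """Apply the acid-fractionation correction to every segment of a dataset.

    Returns a new dataset whose 72 degC segments are shifted and re-tagged as
    25 degC-comparable; raises :class:`DoubleCorrectionError` if the dataset
    is already corrected (the shift is purely additive, so double application
    would silently bias every value).
    """
    if dataset.acid_corrected:
        raise DoubleCorrectionError("dataset is already acid-corrected")
    seg = dataset.segments.copy()
    mask = seg["acid_temp"] == AcidTemp.T72.value
    seg.loc[mask, "d18O_permil"] = seg.loc[mask, "d18O_permil"] + ACID_CORRECTION_72C_PERMIL
    seg.loc[mask, "acid_temp"] = AcidTemp.T25.value
    return Dataset(
        samples=dataset.samples,
        segments=seg,
        rejects=dataset.rejects,
        warnings=list(dataset.warnings),
        acid_corrected=True,
    )


# ---------------------------------------------------------------------------
# Radius-age curves

def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: the L2-closest non-decreasing sequence."""
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    w = np.ones(n)
    # blocks as (value, weight) merged until monotone
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            vals[i : i + 2] = [merged]
            wts[i : i + 2] = [tot]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty(n)
    k = 0
    for v, wt in zip(vals, wts):
        cnt = int(round(wt))
        out[k : k + cnt] = v
        k += cnt
    return out


@dataclass(frozen=True)
class RadiusAgeCurve:
    """Piecewise-linear monotone mapping from otolith radius (um) to age (dph).

    Built from mean radius at each observed age; queries outside the anchor
    hull are clamped (with a warning) rather than extrapolated.
    """

    radii_um: np.ndarray
    ages_dph: np.ndarray
    cohort: tuple | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_um, dtype=float)
        a = np.asarray(self.ages_dph, dtype=float)
        if len(r) < 2:
            raise ValueError("radius-age curve needs at least 2 anchor points")
        if not (np.diff(r) > 0).all() or not (np.diff(a) > 0).all():
            raise ValueError("radius-age anchors must be strictly increasing")
        object.__setattr__(self, "radii_um", r)
        object.__setattr__(self, "ages_dph", a)

    def __call__(self, radius_um: float | np.ndarray) -> float | np.ndarray:
        r = np.asarray(radius_um, dtype=float)
        if (r < self.radii_um[0] - 1e-9).any() or (r > self.radii_um[-1] + 1e-9).any():
            warnings.warn(
                f"radius query outside anchor hull "
                f"[{self.radii_um[0]}, {self.radii_um[-1]}] um; clamping",
                stacklevel=2,
            )
        out = np.interp(r, self.radii_um, self.ages_dph)
        return float(out) if np.isscalar(radius_um) else out

    def age_at(self, radius_um: float) -> float:
        return float(self(radius_um))


class CurveFitError(ValueError):
    """Raised when a reference cohort has no usable radius-age pairs."""


def fit_radius_age_curve(
    pairs: Iterable[tuple[float, float]],
    cohort: tuple | None = None,
) -> RadiusAgeCurve:
    """Fit a monotone piecewise-linear radius->age curve.

    ``pairs`` are increment-based (radius_um, age_dph) observations, pooled
    over the reference fish of one (year, season, region) cohort.  Radii at
    duplicate ages are averaged into a single anchor; any residual
    non-monotonicity of mean radius against age is resolved by an isotonic
    (pool-adjacent-violators) adjustment.
    """
    df = pd.DataFrame(list(pairs), columns=["radius_um", "age_dph"])
    if df.empty:
        raise CurveFitError(f"no radius-age pairs for cohort {cohort!r}")
    anchors = (
        df.groupby("age_dph", sort=True)["radius_um"].mean().reset_index()
    )
    if len(anchors) < 2:
        raise CurveFitError(
            f"cohort {cohort!r}: need >= 2 distinct ages, got {len(anchors)}"
        )
    radii = _pava_increasing(anchors["radius_um"].to_numpy())
    # after PAVA ties may remain; nudge exact ties apart is unsound, drop dup anchors
    ages = anchors["age_dph"].to_numpy(dtype=float)
    keep = np.concatenate([[True], np.diff(radii) > 0])
    radii, ages = radii[keep], ages[keep]
    if len(radii) < 2:
        raise CurveFitError(f"cohort {cohort!r}: anchors collapse to a point")
    return RadiusAgeCurve(radii_um=radii, ages_dph=ages, cohort=cohort)


def radius_age_pairs(profile: OtolithProfile) -> list[tuple[float, float]]:
    """Increment-based (radius, age) pairs from one profile's segment bounds."""
    pairs = []
    for s in profile.segments:
        if s.est_age_start_dph is not None:
            pairs.append((s.dist_start_um, s.est_age_start_dph))
        if s.est_age_end_dph is not None:
            pairs.append((s.dist_end_um, s.est_age_end_dph))
    return pairs


def assign_segment_ages(profile: OtolithProfile, curve: RadiusAgeCurve) -> OtolithProfile:
    """Estimate age ranges for segments lacking them via a radius-age curve.

    Segments that already carry measured (increment-based) age ranges are left
    untouched.  Distances outside the curve's hull are clamped.
    """
    new_segments = []
    for s in profile.segments:
        if s.est_age_start_dph is not None and s.est_age_end_dph is not None:
            new_segments.append(s)
        else:
            new_segments.append(
                replace(
                    s,
                    est_age_start_dph=curve.age_at(s.dist_start_um),
                    est_age_end_dph=curve.age_at(s.dist_end_um),
                )
            )
    return OtolithProfile(
        fish_id=profile.fish_id,
        segments=new_segments,
        radius_at_60dph_um=profile.radius_at_60dph_um,
        has_increment_reading=profile.has_increment_reading,
        acid_corrected=profile.acid_corrected,
    )


# ---------------------------------------------------------------------------
# Window rescaling

WeightMode = Literal["width_um", "day_span"]


def window_value(
    profile: OtolithProfile,
    window: tuple[float, float],
    quantity: Literal["d18O", "d13C"] = "d18O",
    weight: WeightMode = "width_um",
) -> float | None:
    """Weighted mean of segment values whose age-range median falls in ``window``.

    The window is a closed interval in dph; a segment qualifies iff the median
    of its estimated age range lies inside it (no partial-overlap proration).
    Qualifying segments are averaged weighted by milling width in um (default)
    or by day span.  Returns ``None`` when no segment qualifies — absence is a
    value, not an error.
    """
    lo, hi = window
    values, weights = [], []
    for s in profile.segments:
        med = s.age_median_dph
        if med is None or not (lo <= med <= hi):
            continue
        v = s.d18O_permil if quantity == "d18O" else s.d13C_permil
        if weight == "width_um":
            w = s.width_um
        elif weight == "day_span":
            w = s.est_age_end_dph - s.est_age_start_dph  # type: ignore[operator]
        else:
            raise ValueError(f"unknown weight mode {weight!r}")
        values.append(v)
        weights.append(w)
    if not values:
        return None
    return float(np.average(values, weights=weights))


def _capture_cohort_key(row: pd.Series) -> tuple:
    date = pd.Timestamp(row["capture_date"])
    return (date.year, (date.month - 1) // 3 + 1, row["region"])


def fit_cohort_curves(dataset: Dataset) -> dict[tuple, RadiusAgeCurve]:
    """Fit one radius-age curve per (capture year, quarter, region) cohort from
    the profiles that carry increment-based age readings."""
    meta = dataset.samples.set_index("fish_id")
    pools: dict[tuple, list[tuple[float, float]]] = {}
    for profile in dataset.iter_profiles():
        if not profile.has_increment_reading or profile.fish_id not in meta.index:
            continue
        key = _capture_cohort_key(meta.loc[profile.fish_id])
        pools.setdefault(key, []).extend(radius_age_pairs(profile))
    curves = {}
    for key, pairs in pools.items():
        try:
            curves[key] = fit_radius_age_curve(pairs, cohort=key)
        except CurveFitError:
            continue
    return curves


def extract_stage_values(
    dataset: Dataset,
    weight: WeightMode = "width_um",
    curves: dict[tuple, RadiusAgeCurve] | None = None,
) -> pd.DataFrame:
    """One row of stage values per fish: larval d18O/d13C (0-60 dph), juvenile
    d18O (106-120 dph), radius at 60 dph and an initial provenance label.

    Requires an acid-corrected dataset.  Profiles without increment readings
    are age-mapped through the cohort curves (fitted on demand when not
    supplied).  Fish with no qualifying larval segment are excluded with a
    warning, since they cannot enter any downstream analysis.
    """
    if not dataset.acid_corrected:
        raise ValueError("extract_stage_values requires an acid-corrected dataset")
    if curves is None:
        curves = fit_cohort_curves(dataset)
    meta = dataset.samples.set_index("fish_id")
    rows = []
    for profile in dataset.iter_profiles():
        if profile.fish_id not in meta.index:
            continue
        sample = meta.loc[profile.fish_id]
        if not profile.has_increment_reading:
            key = _capture_cohort_key(sample)
            if key in curves:
                profile = assign_segment_ages(profile, curves[key])
        larval = window_value(profile, LARVAL_WINDOW, "d18O", weight)
        if larval is None:
            warnings.warn(
                f"fish {profile.fish_id}: no qualifying larval segment; excluded",
                stacklevel=2,
            )
            continue
        label = (
            Label.pacific_offshore
            if sample["region"] == Region.PacificOffshore.value
            else Label.unclassified
        )
        larval_c = window_value(profile, LARVAL_WINDOW, "d13C", weight)
        juvenile = window_value(profile, JUVENILE_WINDOW, "d18O", weight)
        rows.append(
            {
                "fish_id": profile.fish_id,
                "larval_d18O": larval,
                "larval_d13C": np.nan if larval_c is None else larval_c,
                "juvenile_d18O": np.nan if juvenile is None else juvenile,
                "radius_at_60dph_um": profile.radius_at_60dph_um
                if profile.radius_at_60dph_um is not None
                else np.nan,
                "has_increment_reading": profile.has_increment_reading,
                "label": label.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id",
            "larval_d18O",
            "larval_d13C",
            "juvenile_d18O",
            "radius_at_60dph_um",
            "has_increment_reading",
            "label",
        ],
    )
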