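"""Domain types, dataset validation and readers/writers for tabular and gridded data.

Two CSV tables carry the per-fish data:

``samples.csv``
    ``fish_id, region, capture_date, year_class, age, standard_length_mm, batch_id``

``segments.csv``
    ``fish_id, dist_start_um, dist_end_um, d18O_permil, d13C_permil, acid_temp,
    est_age_start_dph, est_age_end_dph, radius_at_60dph_um``
    (the last three optional / may be empty; ``radius_at_60dph_um`` is a per-fish
    property repeated on every row of that fish)

Gridded environmental fields (temperature and salinity at 10 m depth) travel as
netCDF with dims ``(day, lat, lon)`` and variables ``temp_10m`` (degC) and
``sal_10m`` (psu).

All CSV I/O is UTF-8, comma-separated, dot-decimal, ISO-8601 dates.  Rows that
fail to parse are quarantined into a rejects table rather than aborting the
run, mirroring exploratory use on heterogeneous field data.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import xarray as xr


class Region(str, enum.Enum):
    """Sampling regions. The first three form the Sea of Japan / East China Sea
    (SJ-ECS) coastal system; PacificOffshore is the subarctic offshore group."""

    WestKyushu = "WestKyushu"
    OkiIslands = "OkiIslands"
    NotoPeninsula = "NotoPeninsula"
    PacificOffshore = "PacificOffshore"


#: Regions belonging to the Sea of Japan / East China Sea coastal system.
SJ_ECS_REGIONS = frozenset(
    {Region.WestKyushu, Region.OkiIslands, Region.NotoPeninsula}
)


class AcidTemp(str, enum.Enum):
    """Phosphoric-acid reaction temperature of the carbonate analysis line."""

    T25 = "25C"
    T72 = "72C"


class Label(str, enum.Enum):
    """Provenance labels."""

    local = "local"
    nonlocal_ = "nonlocal"
    pacific_offshore = "pacific_offshore"
    unclassified = "unclassified"


SAMPLES_COLUMNS = [
    "fish_id",
    "region",
    "capture_date",
    "year_class",
    "age",
    "standard_length_mm",
    "batch_id",
]

SEGMENTS_COLUMNS = [
    "fish_id",
    "dist_start_um",
    "dist_end_um",
    "d18O_permil",
    "d13C_permil",
    "acid_temp",
]

SEGMENTS_OPTIONAL_COLUMNS = [
    "est_age_start_dph",
    "est_age_end_dph",
    "radius_at_60dph_um",
]


class SchemaError(ValueError):
    """A mandatory column is missing or has an unusable dtype."""


class IntegrityError(ValueError):
    """Cross-row consistency is broken (e.g. duplicated fish_id)."""


@dataclass(frozen=True)
class FishSample:
    fish_id: str
    region: Region
    capture_date: pd.Timestamp
    year_class: int
    age: int
    standard_length_mm: float
    batch_id: str = ""


@dataclass(frozen=True)
class MillSegment:
    """One micromilled segment of an otolith profile.

    Distances are measured from the core along the milling axis (um); isotope
    values are permil VPDB.  Estimated age bounds (dph) are absent until the
    profile has been mapped through a radius-age curve.
    """

    dist_start_um: float
    dist_end_um: float
    d18O_permil: float
    d13C_permil: float
    acid_temp: AcidTemp = AcidTemp.T72
    est_age_start_dph: float | None = None
    est_age_end_dph: float | None = None

    def __post_init__(self) -> None:
        if not self.dist_start_um < self.dist_end_um:
            raise ValueError(
                f"segment distances must satisfy start < end, got "
                f"[{self.dist_start_um}, {self.dist_end_um}]"
            )
        if not (np.isfinite(self.d18O_permil) and np.isfinite(self.d13C_permil)):
            raise ValueError("segment isotope values must be finite")

    @property
    def width_um(self) -> float:
        return self.dist_end_um - self.dist_start_um

    @property
    def age_median_dph(self) -> float | None:
        if self.est_age_start_dph is None or self.est_age_end_dph is None:
            return None
        return 0.5 * (self.est_age_start_dph + self.est_age_end_dph)


@dataclass
class OtolithProfile:
    """Ordered micromill segments for one fish."""

    fish_id: str
    segments: list[MillSegment]
    radius_at_60dph_um: float | None = None
    has_increment_reading: bool = False
    acid_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"profile {self.fish_id}: at least one segment required")
        if self.radius_at_60dph_um is not None and not self.radius_at_60dph_um > 0:
            raise ValueError(f"profile {self.fish_id}: radius_at_60dph must be > 0")
        self.segments = sorted(self.segments, key=lambda s: s.dist_start_um)


@dataclass
class Dataset:
    """Samples joined to their micromill profiles, plus quarantined rejects."""

    samples: pd.DataFrame
    segments: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["file", "line", "reason"])
    )
    warnings: list[str] = field(default_factory=list)
    acid_corrected: bool = False

    def profile(self, fish_id: str) -> OtolithProfile | None:
        seg = self.segments[self.segments["fish_id"] == fish_id]
        if seg.empty:
            return None
        return _profile_from_rows(fish_id, seg, self.acid_corrected)

    def iter_profiles(self) -> Iterator[OtolithProfile]:
        for fish_id, seg in self.segments.groupby("fish_id", sort=True):
            yield _profile_from_rows(str(fish_id), seg, self.acid_corrected)


def _profile_from_rows(
    fish_id: str, seg: pd.DataFrame, acid_corrected: bool
) -> OtolithProfile:
    segments = [
        MillSegment(
            dist_start_um=float(r.dist_start_um),
            dist_end_um=float(r.dist_end_um),
            d18O_permil=float(r.d18O_permil),
            d13C_permil=float(r.d13C_permil),
            acid_temp=AcidTemp(r.acid_temp),
            est_age_start_dph=None
            if pd.isna(getattr(r, "est_age_start_dph", np.nan))
            else float(r.est_age_start_dph),
            est_age_end_dph=None
            if pd.isna(getattr(r, "est_age_end_dph", np.nan))
            else float(r.est_age_end_dph),
        )
        for r in seg.itertuples()
    ]
    radius = None
    if "radius_at_60dph_um" in seg.columns:
        vals = seg["radius_at_60dph_um"].dropna().unique()
        if len(vals):
            radius = float(vals[0])
    has_incr = all(s.est_age_start_dph is not None for s in segments)
    return OtolithProfile(
        fish_id=fish_id,
        segments=segments,
        radius_at_60dph_um=radius,
        has_increment_reading=has_incr,
        acid_corrected=acid_corrected,
    )


# ---------------------------------------------------------------------------
# CSV loading

def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _parse_samples(raw: pd.DataFrame, rejects: list[dict]) -> pd.DataFrame:
    rows = []
    for idx, r in raw.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            region = Region(str(r["region"]).strip())
            date = pd.Timestamp(str(r["capture_date"]))
            age = int(r["age"])
            if age not in (0, 1):
                raise ValueError(f"age must be 0 or 1, got {age}")
            rows.append(
                {
                    "fish_id": str(r["fish_id"]),
                    "region": region.value,
                    "capture_date": date,
                    "year_class": int(r["year_class"]),
                    "age": age,
                    "standard_length_mm": float(r["standard_length_mm"]),
                    "batch_id": "" if pd.isna(r.get("batch_id")) else str(r["batch_id"]),
                }
            )
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append({"file": "samples", "line": line, "reason": str(exc)})
    return pd.DataFrame(rows, columns=SAMPLES_COLUMNS)


def _parse_segments(raw: pd.DataFrame, rejects: list[dict]) -> pd.DataFrame:
    rows = []
    for idx, r in raw.iterrows():
        line = int(idx) + 2
        try:
            acid = AcidTemp(str(r["acid_temp"]).strip())
            row = {
                "fish_id": str(r["fish_id"]),
                "dist_start_um": float(r["dist_start_um"]),
                "dist_end_um": float(r["dist_end_um"]),
                "d18O_permil": float(r["d18O_permil"]),
                "d13C_permil": float(r["d13C_permil"]),
                "acid_temp": acid.value,
            }
            if not row["dist_start_um"] < row["dist_end_um"]:
                raise ValueError("dist_start_um must be < dist_end_um")
            if not (np.isfinite(row["d18O_permil"]) and np.isfinite(row["d13C_permil"])):
                raise ValueError("isotope values must be finite")
            for col in SEGMENTS_OPTIONAL_COLUMNS:
                v = r.get(col)
                row[col] = np.nan if (v is None or pd.isna(v)) else float(v)
            rows.append(row)
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append({"file": "segments", "line": line, "reason": str(exc)})
    return pd.DataFrame(rows, columns=SEGMENTS_COLUMNS + SEGMENTS_OPTIONAL_COLUMNS)


def load_dataset(samples_path: str | Path, segments_path: str | Path) -> Dataset:
    """Load and join the samples and segments tables.

    Unparseable rows are quarantined into ``dataset.rejects`` with their file
    and line number; the join is lossless for valid rows.  Raises
    :class:`SchemaError` for a missing mandatory column and
    :class:`IntegrityError` for duplicated ``fish_id`` in the samples table.
    """
    raw_samples = pd.read_csv(samples_path, dtype=str)
    raw_segments = pd.read_csv(segments_path, dtype=str)
    _require_columns(raw_samples, SAMPLES_COLUMNS[:-1], "samples")
    _require_columns(raw_segments, SEGMENTS_COLUMNS, "segments")

    rejects: list[dict] = []
    samples = _parse_samples(raw_samples, rejects)
    segments = _parse_segments(raw_segments, rejects)

    dup = samples["fish_id"][samples["fish_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate fish_id in samples: {sorted(set(dup))}")

    warnings = []
    orphan = set(segments["fish_id"]) - set(samples["fish_id"])
    if orphan:
        warnings.append(f"{len(orphan)} profile(s) without a sample row: {sorted(orphan)[:5]}")

    return Dataset(
        samples=samples,
        segments=segments.sort_values(["fish_id", "dist_start_um"]).reset_index(drop=True),
        rejects=pd.DataFrame(rejects, columns=["file", "line", "reason"]),
        warnings=warnings,
    )


def write_dataset(dataset: Dataset, samples_path: str | Path, segments_path: str | Path) -> None:
    """Write a dataset back to the two-CSV interchange format (round-trips with
    :func:`load_dataset`)."""
    out = dataset.samples.copy()
    out["capture_date"] = pd.to_datetime(out["capture_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(samples_path, index=False)
    dataset.segments.to_csv(segments_path, index=False)


# ---------------------------------------------------------------------------
# Validation

@dataclass(frozen=True)
class Violation:
    fish_id: str
    rule: str
    message: str


def _age_rule_violation(row: pd.Series) -> str | None:
    """Sampling protocol: age-0 fish are < 150 mm SL caught July-December;
    age-1 fish are < 160 mm SL caught January-June (strict inequalities).
    Year-class equals capture year for age 0 and capture year - 1 for age 1."""
    month = pd.Timestamp(row["capture_date"]).month
    sl = float(row["standard_length_mm"])
    age = int(row["age"])
    if age == 0:
        if month < 7:
            return "age/month rule: age-0 fish must be captured July-December"
        if not sl < 150.0:
            return "age/SL rule: age-0 fish must have SL < 150 mm"
    else:
        if month > 6:
            return "age/month rule: age-1 fish must be captured January-June"
        if not sl < 160.0:
            return "age/SL rule: age-1 fish must have SL < 160 mm"
    return None


def validate_dataset(dataset: Dataset) -> list[Violation]:
    """Report (never fix) rule violations: the age/SL/month sampling rule,
    year-class consistency, segment overlap and non-positive widths."""
    violations: list[Violation] = []
    for _, row in dataset.samples.iterrows():
        fid = row["fish_id"]
        msg = _age_rule_violation(row)
        if msg is not None:
            violations.append(Violation(fid, "age/month rule", msg))
        year = pd.Timestamp(row["capture_date"]).year
        expected_yc = year - int(row["age"])
        if int(row["year_class"]) != expected_yc:
            violations.append(
                Violation(
                    fid,
                    "year-class rule",
                    f"year_class {row['year_class']} != capture year {year} - age {row['age']}",
                )
            )
    for fish_id, seg in dataset.segments.groupby("fish_id"):
        seg = seg.sort_values("dist_start_um")
        widths = seg["dist_end_um"].to_numpy() - seg["dist_start_um"].to_numpy()
        if (widths <= 0).any():
            violations.append(Violation(str(fish_id), "segment width", "non-positive width"))
        starts = seg["dist_start_um"].to_numpy()[1:]
        ends = seg["dist_end_um"].to_numpy()[:-1]
        if (starts < ends - 1e-9).any():
            violations.append(Violation(str(fish_id), "segment overlap", "segments overlap"))
    return violations


# ---------------------------------------------------------------------------
# Result tables + manifest

def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
) -> dict:
    """Write one CSV per named table plus a JSON manifest with row counts and
    a hash of the run configuration.  Bit-stable given identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "tables": {}}
    for name in sorted(tables):
        df = tables[name]
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["tables"][name] = {"rows": int(len(df)), "file": path.name}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    return {
        name: pd.read_csv(out / entry["file"])
        for name, entry in manifest["tables"].items()
    }


# ---------------------------------------------------------------------------
# Gridded fields

def save_env_field(env: xr.Dataset, path: str | Path) -> None:
    """Write an environmental field to netCDF (classic format via the scipy
    backend, so files stay portable plain netCDF3)."""
    enc = {v: {"_FillValue": np.nan} for v in env.data_vars if env[v].dtype.kind == "f"}
    env.to_netcdf(path, engine="scipy", encoding=enc)


def load_env_field(path: str | Path) -> xr.Dataset:
    """Read an environmental field; missing-value attributes are honored by
    CF decoding (missing cells come back as NaN)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
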