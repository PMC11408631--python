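"""File-based orchestration of the analysis stages.

Each stage consumes and produces only files under the run directory, so any
stage can be rerun from disk:

``simulate``  -> data/samples.csv, data/segments.csv, data/truth.csv, data/environment.nc
``windows``   -> stage_values.csv, validation.csv
``classify``  -> thresholds.csv, classification.csv, loocv.json, proportions.csv
``stats``     -> stats_report.json, games_howell_<var>.csv
``isoscape``  -> isoscape_<window>.nc (one layer per hatch date)
``assign``    -> masks_<window>.nc, match_cells_<window>.csv
``report``    -> report.md, manifest.json

Configuration is a YAML mapping; every key has a default so a minimal config
is just an output directory and a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from otoprov import data_io, group_stats, isoscape_assign, profile_windows, provenance
from otoprov.data_io import Dataset, load_env_field, save_env_field
from otoprov.isoscape_assign import IsotopeModelParams
from otoprov.synthetic_data import GroupSpec, SimulationConfig, generate_cohort

log = logging.getLogger("otoprov")

STAGE_ORDER = ["simulate", "windows", "classify", "stats", "isoscape", "assign", "report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("out_dir", "results/run")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGE_ORDER))
    return cfg


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = cfg.get("simulate") or {}
    config = SimulationConfig(seed=int(cfg.get("seed", 0)))
    if "year_classes" in sim:
        config = replace(config, year_classes=tuple(int(y) for y in sim["year_classes"]))
    if "group_sizes" in sim:
        groups = {
            name: replace(spec, n=int(sim["group_sizes"].get(name, spec.n)))
            for name, spec in config.groups.items()
        }
        config = replace(config, groups=groups)
    if "calibrate_to_moments" in sim:
        config = replace(config, calibrate_to_moments=bool(sim["calibrate_to_moments"]))
    return config


def _iso_params(cfg: dict) -> IsotopeModelParams:
    p = (cfg.get("isoscape") or {}).get("params") or {}
    rel = {int(k): tuple(v) for k, v in (p.get("salinity_relations") or {0: (0.28, -9.4)}).items()}
    return IsotopeModelParams(
        frac_slope=float(p.get("frac_slope", -0.18)),
        frac_intercept=float(p.get("frac_intercept", 2.7)),
        water_scale_offset=float(p.get("water_scale_offset", -0.27)),
        salinity_relations=rel,
    )


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: dict, out: Path) -> dict:
    config = _sim_config(cfg)
    generate_cohort(config, out_dir=out / "data")
    log.info("simulate: wrote synthetic cohort under %s", out / "data")
    return {"n_fish": config.year_classes and sum(g.n for g in config.groups.values()) * len(config.year_classes)}

def _input_paths(cfg: dict, out: Path) -> dict[str, Path]:
    inputs = cfg.get("inputs") or {}
    return {
        "samples": Path(inputs.get("samples", out / "data" / "samples.csv")),
        "segments": Path(inputs.get("segments", out / "data" / "segments.csv")),
        "environment": Path(inputs.get("environment", out / "data" / "environment.nc")),
    }


def stage_windows(cfg: dict, out: Path) -> dict:
    paths = _input_paths(cfg, out)
    ds = data_io.load_dataset(paths["samples"], paths["segments"])
    violations = data_io.validate_dataset(ds)
    pd.DataFrame([v.__dict__ for v in violations]).to_csv(out / "validation.csv", index=False)
    if not ds.rejects.empty:
        ds.rejects.to_csv(out / "rejects.csv", index=False)
    corrected = profile_windows.apply_acid_correction(ds)
    weight = (cfg.get("windows") or {}).get("weight", "width_um")
    stage_values = profile_windows.extract_stage_values(corrected, weight=weight)
    stage_values.to_csv(out / "stage_values.csv", index=False)
    log.info("windows: %d fish with larval values, %d violations", len(stage_values), len(violations))
    return {"n_fish": len(stage_values), "n_violations": len(violations)}


def _load_stage_table(cfg: dict, out: Path) -> pd.DataFrame:
    paths = _input_paths(cfg, out)
    samples = pd.read_csv(paths["samples"], parse_dates=["capture_date"])
    stage_values = pd.read_csv(out / "stage_values.csv")
    return provenance.merge_stage_with_samples(stage_values, samples)


def stage_classify(cfg: dict, out: Path) -> dict:
    df = _load_stage_table(cfg, out)
    rules = provenance.compute_thresholds(df)
    pd.DataFrame(
        [
            {"year_class": r.year_class, "threshold_permil": r.threshold_permil, "n_reference": r.n_reference}
            for r in rules.values()
        ]
    ).to_csv(out / "thresholds.csv", index=False)
    labeled = provenance.assign_by_threshold(df, rules)
    model = provenance.fit_lda(labeled)
    report = provenance.loocv(labeled)
    final = provenance.classify_unlabeled(model, labeled)
    final[
        ["fish_id", "label", "label_source", "lda_score_local", "lda_score_nonlocal"]
    ].to_csv(out / "classification.csv", index=False)
    with open(out / "loocv.json", "w") as fh:
        json.dump(
            {
                "n": report.n,
                "n_correct": report.n_correct,
                "accuracy": report.accuracy,
                "n_skipped": report.n_skipped,
                "per_predicted": report.per_predicted.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    final.to_csv(out / "stage_values_labeled.csv", index=False)
    props = provenance.proportions_by_group(final, ("region", "year_class"))
    props.to_csv(out / "proportions.csv", index=False)
    log.info("classify: LOOCV accuracy %.3f over %d fish", report.accuracy, report.n)
    return {"loocv_accuracy": report.accuracy, "n_thresholds": len(rules)}


def stage_stats(cfg: dict, out: Path) -> dict:
    df = pd.read_csv(out / "stage_values_labeled.csv")
    learn = df[df["label"].isin(["local", "nonlocal", "pacific_offshore"])]
    # same exclusion as the discriminant learning set, extended by the offshore group
    keep = learn.dropna(subset=["larval_d18O", "larval_d13C", "radius_at_60dph_um"])
    keep = keep[(keep["label"] == "pacific_offshore") | keep["juvenile_d18O"].notna()]
    rep = group_stats.group_stats_report(keep)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(rep.to_json_dict(), fh, indent=2)
    for var, table in rep.games_howell.items():
        table.to_csv(out / f"games_howell_{var}.csv", index=False)
    log.info("stats: MANOVA F(%g, %g) = %.2f", rep.manova["df1"], rep.manova["df2"], rep.manova["F"])
    return {"manova_F": rep.manova["F"], "n": rep.manova["n"]}


def _hatch_grid(cfg: dict, year: int) -> list[pd.Timestamp]:
    iso = cfg.get("isoscape") or {}
    h = iso.get("hatch") or {}
    start = pd.Timestamp(h.get("start", f"{year}-04-15"))
    end = pd.Timestamp(h.get("end", f"{year}-05-15"))
    return isoscape_assign.hatch_date_grid(start, end, int(h.get("step_days", 3)))


def _iso_windows(cfg: dict) -> dict[str, tuple[int, int]]:
    iso = cfg.get("isoscape") or {}
    w = iso.get("windows") or {"larval": (0, 60), "juvenile": (106, 120)}
    return {name: (int(a), int(b)) for name, (a, b) in w.items()}


def stage_isoscape(cfg: dict, out: Path) -> dict:
    paths = _input_paths(cfg, out)
    env = load_env_field(paths["environment"])
    params = _iso_params(cfg)
    iso_cfg = cfg.get("isoscape") or {}
    year = int(iso_cfg.get("year", max(pd.to_datetime(env["day"].values).year)))
    hatch_dates = _hatch_grid(cfg, year)
    order = iso_cfg.get("order", "average_first")
    min_cov = float(iso_cfg.get("min_coverage", 1.0))
    n_cells = {}
    for name, window in _iso_windows(cfg).items():
        layers = [
            isoscape_assign.build_isoscape(env, h, window, params, order=order, min_coverage=min_cov).d18O
            for h in hatch_dates
        ]
        stacked = xr.concat(layers, dim=pd.Index(hatch_dates, name="hatch_date"))
        stacked.name = "otolith_d18O"
        save_env_field(stacked.to_dataset(), out / f"isoscape_{name}.nc")
        n_cells[name] = int(np.isfinite(stacked.values).sum())
    log.info("isoscape: wrote %d windows x %d hatch dates", len(n_cells), len(hatch_dates))
    return {"n_hatch_dates": len(hatch_dates), "finite_cells": n_cells}


def _observed_band(cfg: dict, out: Path, window_name: str) -> tuple[float, float]:
    iso = cfg.get("isoscape") or {}
    band = iso.get("band") or {}
    if "mu" in band:
        return float(band["mu"]), float(band["sigma"])
    group = band.get("group", "nonlocal")
    col = "larval_d18O" if window_name == "larval" else "juvenile_d18O"
    df = pd.read_csv(out / "stage_values_labeled.csv")
    sel = df[df["label"] == group]
    if "year_class" in band:
        sel = sel[sel["year_class"] == int(band["year_class"])]
    vals = sel[col].dropna()
    if len(vals) < 2:
        raise ValueError(f"cannot derive band for {group}/{window_name}: {len(vals)} values")
    return float(vals.mean()), float(vals.std(ddof=1))


def stage_assign(cfg: dict, out: Path) -> dict:
    areas = {}
    for name in _iso_windows(cfg):
        ds = load_env_field(out / f"isoscape_{name}.nc")
        iso_da = ds["otolith_d18O"]
        mu, sigma = _observed_band(cfg, out, name)
        masks = []
        hatch_dates = list(pd.to_datetime(iso_da["hatch_date"].values))
        for h in hatch_dates:
            layer = iso_da.sel(hatch_date=h)
            iso = isoscape_assign.Isoscape(
                d18O=layer, hatch_date=pd.Timestamp(h), window=(0, 0), params=_iso_params(cfg)
            )
            masks.append(isoscape_assign.assignment_mask(iso, mu, sigma))
        result = isoscape_assign.aggregate_hatch_masks(masks, hatch_dates, band=(mu, sigma))
        save_env_field(
            xr.Dataset(
                {"match": result.masks.astype(np.int8), "match_count": result.counts}
            ),
            out / f"masks_{name}.nc",
        )
        isoscape_assign.mask_to_table(result.counts > 0).to_csv(
            out / f"match_cells_{name}.csv", index=False
        )
        areas[name] = int((result.counts.values > 0).sum())
        log.info("assign/%s: band %.2f +/- %.2f, %d matching cells", name, mu, sigma, areas[name])
    return {"mask_cells": areas}


def stage_report(cfg: dict, out: Path) -> dict:
    lines = ["# Run report", ""]
    for name, fn in [
        ("thresholds", "thresholds.csv"),
        ("proportions", "proportions.csv"),
    ]:
        f = out / fn
        if f.exists():
            lines += [f"## {name}", "", pd.read_csv(f).to_string(index=False), ""]
    loocv_path = out / "loocv.json"
    if loocv_path.exists():
        with open(loocv_path) as fh:
            loocv = json.load(fh)
        lines += ["## LOOCV", "", f"accuracy {loocv['accuracy']:.3f} over n={loocv['n']}", ""]
    stats_path = out / "stats_report.json"
    if stats_path.exists():
        with open(stats_path) as fh:
            m = json.load(fh)["manova"]
        lines += [
            "## MANOVA",
            "",
            f"Wilks lambda {m['wilks_lambda']:.4f}, F({m['df1']:.0f}, {m['df2']:.1f}) = {m['F']:.2f}, p = {m['p']:.3g}",
            "",
        ]
    for name in _iso_windows(cfg):
        f = out / f"match_cells_{name}.csv"
        if f.exists():
            lines += [f"## assignment mask ({name})", "", f"{len(pd.read_csv(f))} matching cells", ""]
    (out / "report.md").write_text("\n".join(lines))
    return {"report": "report.md"}


STAGES: dict[str, Callable[[dict, Path], dict]] = {
    "simulate": stage_simulate,
    "windows": stage_windows,
    "classify": stage_classify,
    "stats": stage_stats,
    "isoscape": stage_isoscape,
    "assign": stage_assign,
    "report": stage_report,
}


def run_pipeline(cfg: dict) -> dict:
    """Execute the enabled stages in dependency order; write a manifest.

    A stage failure aborts the run with the stage name and cause; outputs of
    completed stages are retained and recorded in the manifest.
    """
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGE_ORDER if s in cfg.get("stages", STAGE_ORDER)]
    manifest: dict[str, Any] = {
        "config_hash": data_io._config_hash(cfg),
        "seed": cfg.get("seed"),
        "stages": {},
    }
    try:
        for stage in enabled:
            log.info("running stage %s", stage)
            manifest["stages"][stage] = STAGES[stage](cfg, out)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise StageError(stage, exc) from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
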