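"""Config-driven orchestration of the full analysis.

Chains the accounting, resource-distribution and Monte Carlo stages into
the study's three summary products: a per-class land-cover change table,
an extent-wide resource-change table (mean and Monte Carlo SE of the raw
and percent change), and a seasonal trend table. Runs either from the
bundled published tables (``region: mexico|texas``) or from user CSVs via
a YAML config; every output CSV embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import datasets
from .change import change_summary_from_components
from .montecarlo import MCConfig, MCResult, expected_change, mc_change
from .resources import normal_registry
from .trends import fit_trend

__all__ = [
    "load_config",
    "published_change_summary",
    "published_resource_change",
    "run_change_tables",
    "run_habitat_change",
    "run_trends",
    "run_all",
]

log = logging.getLogger("habitatshift")

RESOURCE_COLUMNS = {
    ("nectar", "fall"): ("fall_nectar_mean", "fall_nectar_sd"),
    ("nectar", "spring"): ("spring_nectar_mean", "spring_nectar_sd"),
    ("milkweed", "spring"): ("milkweed_mean", "milkweed_sd"),
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("inputs", "outputs"):
        for p in (cfg.get(key) or {}).values():
            if isinstance(p, str) and key == "inputs" and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: str | Path, cfg: dict, seed) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# habitatshift config_hash={_config_hash(cfg)} seed={seed}\n")
        df.to_csv(fh)
    log.info("wrote %s (%d rows)", path, len(df))


def published_change_summary(region: str) -> pd.DataFrame:
    """Per-class change statistics from the bundled published area table.

    Uses the annualization divisor of the published table (19 for Mexico's
    2000–2020 interval — surfaced as a warning because it differs from the
    calendar interval — 18 for Texas).
    """
    if region not in datasets.REGIONS:
        raise KeyError(f"unknown region {region!r}; choose from "
                       f"{sorted(datasets.REGIONS)}")
    info = datasets.REGIONS[region]
    t = datasets.load_change_table(region)
    if info.annualization_years != info.end_year - info.start_year:
        log.warning(
            "region %s: published annualization divides by %d although the "
            "interval %d–%d spans %d years; reproducing the published divisor",
            region, info.annualization_years, info.start_year, info.end_year,
            info.end_year - info.start_year)
    return change_summary_from_components(
        t["start_area_km2"], t["end_area_km2"], t["loss_km2"], t["gain_km2"],
        info.annualization_years)


def _registry(region: str, resource: str, season: str) -> dict:
    key = (resource, season)
    if key not in RESOURCE_COLUMNS:
        raise KeyError(f"no {resource!r} values for season {season!r}")
    mean_col, sd_col = RESOURCE_COLUMNS[key]
    units = "score" if resource == "nectar" else datasets.milkweed_units(region)
    return normal_registry(datasets.load_resource_table(region), season, resource,
                           mean_col, sd_col, units=units)


def published_resource_change(
    region: str,
    resource: str,
    season: str = "spring",
    n_reps: int = 5000,
    seed: int = 0,
    truncation: str | None = None,
    draw_policy: str = "shared_across_years",
) -> tuple[dict, MCResult]:
    """Extent-wide resource change from the bundled published tables.

    Builds normal distributions from the published per-class moments and
    propagates the two-date class areas through the Monte Carlo
    estimator; also returns the closed-form expectation. Density
    (plants/ha) reconstructions default to untruncated normals — the
    fitted families behind the published moments already enforce
    nonnegative support, and clipping would bias the reconstructed means —
    while score draws default to the [0, 1] clip policy.
    """
    dists = _registry(region, resource, season)
    if truncation is None:
        units = {d.units for d in dists.values()}
        truncation = "none" if "plants_per_ha" in units else "clip"
    areas = datasets.load_change_table(region)
    exp = expected_change(areas["start_area_km2"], areas["end_area_km2"], dists)
    mc = mc_change(areas["start_area_km2"], areas["end_area_km2"], dists,
                   MCConfig(n_reps=n_reps, seed=seed, truncation=truncation,
                            draw_policy=draw_policy))
    return exp, mc


def run_change_tables(cfg: dict) -> pd.DataFrame:
    """Land-cover change table (start, end, loss, gain, net, gross, annual,
    percent annual, percent total) from a region name or an area CSV."""
    t0 = time.perf_counter()
    if "region" in cfg:
        out = published_change_summary(cfg["region"])
    else:
        table = pd.read_csv(cfg["inputs"]["change_components"]).set_index("class")
        out = change_summary_from_components(
            table["start_area_km2"], table["end_area_km2"],
            table["loss_km2"], table["gain_km2"], int(cfg["interval_years"]))
    if "outputs" in cfg and cfg["outputs"].get("change_table"):
        _write_csv(out, cfg["outputs"]["change_table"], cfg, cfg.get("seed"))
    log.info("change table done in %.2fs", time.perf_counter() - t0)
    return out


def run_habitat_change(cfg: dict) -> pd.DataFrame:
    """Extent-wide resource change table for every configured resource."""
    t0 = time.perf_counter()
    region = cfg["region"]
    seed = int(cfg.get("seed", 0))
    n_reps = int(cfg.get("n_reps", 5000))
    rows = []
    tasks = cfg.get("resources", [
        {"resource": "nectar", "season": "fall"},
        {"resource": "nectar", "season": "spring"},
        {"resource": "milkweed", "season": "spring"},
    ])
    for i, task in enumerate(tasks):
        exp, mc = published_resource_change(
            region, task["resource"], task["season"], n_reps=n_reps,
            seed=seed + i, truncation=task.get("truncation"),
            draw_policy=cfg.get("draw_policy", "shared_across_years"))
        rows.append({
            "region": region, "resource": task["resource"], "season": task["season"],
            "total_t0_mean": mc.summary["total_t0"][0],
            "change_mean": mc.summary["change"][0],
            "change_se": mc.summary["change"][2],
            "percent_change_mean": mc.summary["percent_change"][0],
            "percent_change_se": mc.summary["percent_change"][2],
            "percent_change_of_totals": mc.summary["percent_change_of_totals"][0],
            "percent_change_of_totals_se": mc.summary["percent_change_of_totals"][2],
            "expected_change": exp["change"],
            "expected_percent_change": exp["percent_change"],
            "n_reps": n_reps,
        })
    out = pd.DataFrame(rows).set_index(["region", "resource", "season"])
    if "outputs" in cfg and cfg["outputs"].get("habitat_change"):
        _write_csv(out, cfg["outputs"]["habitat_change"], cfg, seed)
    log.info("habitat change done in %.2fs", time.perf_counter() - t0)
    return out


def run_trends(cfg: dict) -> pd.DataFrame:
    """Trend fits (slope, SE, t, p) per variable × season from a series CSV
    with columns variable, season, year, value."""
    t0 = time.perf_counter()
    series = pd.read_csv(cfg["inputs"]["series"])
    rows = []
    for (var, season), grp in series.groupby(["variable", "season"]):
        fit = fit_trend(grp.set_index("year")["value"])
        rows.append({"variable": var, "season": season, "slope": fit.slope,
                     "slope_se": fit.slope_se, "t_stat": fit.t_stat,
                     "p_value": fit.p_value, "n_years": fit.n_years})
    out = pd.DataFrame(rows).set_index(["variable", "season"])
    if "outputs" in cfg and cfg["outputs"].get("trends"):
        _write_csv(out, cfg["outputs"]["trends"], cfg, cfg.get("seed"))
    log.info("trend table done in %.2fs", time.perf_counter() - t0)
    return out


def run_all(cfg: dict) -> dict:
    out = {}
    if "region" in cfg or "change_components" in (cfg.get("inputs") or {}):
        out["change"] = run_change_tables(cfg)
    if "region" in cfg:
        out["habitat"] = run_habitat_change(cfg)
    if "series" in (cfg.get("inputs") or {}):
        out["trends"] = run_trends(cfg)
    return out
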