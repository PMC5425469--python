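"""End-to-end orchestration: weather linkage → exposure → models → tables.

``run_pipeline`` executes the full analysis on either CSV inputs or a
synthetic-generation block and writes the analysis tables (monthly DLR;
CR/AR/EIR and RR tables for the heat-index axis and the minimum-temperature
axis; the foregone-revenue summary), per-class weekly figure data, fit
reports, and a JSON manifest with seed, row counts, and the exact
accounting of every input record as modelled / baseline / excluded.

Two separate models are fitted — one for the HI axis, one for the
minimum-temperature axis — sharing the same baseline rows; extreme axes
are never pooled in one fit.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geoweather import Plant, Station, weekly_weather_table
from .heat_exposure import (
    COLD_LABELS,
    HI_LABELS,
    classify_week,
    override_category_bounds,
)
from .revenue import (
    excess_condemnations,
    fit_baseline_model,
    price_condemnations,
    summarize_ledger,
)
from .risk_metrics import build_risk_table, dead_loss_ratio, dlr_by_month, iso_week_month
from .synthetic_data import GeneratorConfig, SyntheticBundle, generate
from .zinb_glmm import ModelSpec, fit_zinb_glmm

log = logging.getLogger("transitloss")

TABLE_FILES = (
    "table2_dlr_by_month.csv",
    "table3_hi_risk.csv",
    "table4_hi_rr.csv",
    "table5_mintemp_risk.csv",
    "table6_mintemp_rr.csv",
    "table7_revenue.csv",
)
FIGURE_FILES = (
    "fig4_roaster_weekly.csv",
    "fig5_market_weekly.csv",
    "fig6_cull_sow_weekly.csv",
)


@dataclass
class RunConfig:
    """Run configuration: exactly one of ``inputs`` / ``synthetic`` is set."""

    outdir: str
    seed: int = 20170511
    inputs: dict | None = None       # paths: plants, stations, daily_weather, slaughter, prices
    synthetic: dict | None = None    # GeneratorConfig overrides
    max_miles: float = 100.0
    k_stations: int = 3
    min_days: int = 1
    quad_points: int = 15
    population_prediction: bool = False
    category_bounds: dict | None = None  # documented override hook

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of 'inputs' or 'synthetic'")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values() if not os.path.exists(p)]
            if missing:
                raise FileNotFoundError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


REQUIRED_COLUMNS = {
    "plants": ["plant_id", "lat", "lon", "volume_category"],
    "stations": ["station_id", "lat", "lon"],
    "daily_weather": ["station_id", "date", "t_avg", "t_min", "rh"],
    "slaughter": ["plant_id", "week", "swine_class", "total", "condemned"],
    "prices": ["month", "swine_class", "price_per_head"],
}


def validate_inputs(tables: dict) -> list:
    """Schema, range, and duplicate-key checks; returns violation records.

    ``tables`` maps stream name to DataFrame (or to a CSV path).  Each
    violation carries the table, a reason, and the offending row number.
    """
    violations = []
    frames = {}
    for name, obj in tables.items():
        df = pd.read_csv(obj) if isinstance(obj, (str, os.PathLike)) else obj
        frames[name] = df
        need = REQUIRED_COLUMNS.get(name, [])
        missing = [c for c in need if c not in df.columns]
        if missing:
            violations.append({"table": name, "row": None, "reason": f"missing columns {missing}"})
    sl = frames.get("slaughter")
    if sl is not None and not any(v["table"] == "slaughter" for v in violations):
        bad = sl.index[sl["condemned"] > sl["total"]]
        violations += [
            {"table": "slaughter", "row": int(i), "reason": "condemned > total"} for i in bad
        ]
        bad = sl.index[(sl["condemned"] < 0) | (sl["total"] < 1)]
        violations += [
            {"table": "slaughter", "row": int(i), "reason": "negative count or total < 1"}
            for i in bad
        ]
        dup = sl.index[sl.duplicated(["plant_id", "week", "swine_class"], keep=False)]
        violations += [
            {"table": "slaughter", "row": int(i), "reason": "duplicate (plant, week, class)"}
            for i in dup
        ]
    dw = frames.get("daily_weather")
    if dw is not None and not any(v["table"] == "daily_weather" for v in violations):
        with np.errstate(invalid="ignore"):
            bad = dw.index[(dw["rh"] < 0) | (dw["rh"] > 100)]
            violations += [
                {"table": "daily_weather", "row": int(i), "reason": "rh outside [0, 100]"}
                for i in bad
            ]
            bad = dw.index[dw["t_min"] > dw["t_avg"]]
            violations += [
                {"table": "daily_weather", "row": int(i), "reason": "t_min > t_avg"} for i in bad
            ]
    return violations


def _load_tables(config: RunConfig):
    if config.synthetic is not None:
        gc = GeneratorConfig(seed=config.seed, **config.synthetic)
        bundle = generate(gc)
        return bundle, {
            "plants": bundle.plants,
            "stations": bundle.stations,
            "daily_weather": bundle.daily_weather,
            "slaughter": bundle.slaughter,
            "prices": bundle.prices,
        }
    frames = {k: pd.read_csv(v) for k, v in config.inputs.items()}
    return None, frames


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs; returns the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        bundle, frames = _load_tables(config)

        stage("validate")
        violations = validate_inputs(frames)
        hard = [v for v in violations if v["row"] is None]
        if hard:
            raise ValueError(f"schema violations: {hard}")
        slaughter = frames["slaughter"]
        invalid_idx = sorted(
            {v["row"] for v in violations if v["table"] == "slaughter" and v["row"] is not None}
        )
        excluded_invalid = slaughter.loc[invalid_idx]
        slaughter = slaughter.drop(index=invalid_idx)
        manifest["n_input_records"] = int(len(frames["slaughter"]))
        manifest["n_excluded_invalid"] = int(len(excluded_invalid))

        stage("geoweather")
        plants = [
            Plant(r.plant_id, float(r.lat), float(r.lon), r.volume_category)
            for r in frames["plants"].itertuples(index=False)
        ]
        stations = [
            Station(r.station_id, float(r.lat), float(r.lon))
            for r in frames["stations"].itertuples(index=False)
        ]
        weather, orphan_plants = weekly_weather_table(
            plants,
            stations,
            frames["daily_weather"],
            max_miles=config.max_miles,
            k=config.k_stations,
            min_days=config.min_days,
        )
        manifest["n_plants"] = len(plants)
        manifest["plants_excluded_no_station"] = orphan_plants
        head_lost = int(
            slaughter.loc[slaughter["plant_id"].isin(orphan_plants), "total"].sum()
        )
        manifest["head_excluded_no_station"] = head_lost
        total_head = int(slaughter["total"].sum())
        manifest["percent_head_lost_to_weather_linkage"] = (
            100.0 * head_lost / total_head if total_head else 0.0
        )

        stage("exposure")
        merged = slaughter.merge(weather, on=["plant_id", "week"], how="left")
        has_weather = merged["t_avg_week"].notna()
        labels = np.full(len(merged), None, dtype=object)
        reasons = np.full(len(merged), None, dtype=object)
        pw = merged.loc[has_weather, ["t_avg_week", "t_min_week", "rh_week"]]
        cache: dict = {}
        prev_bounds = (
            override_category_bounds(config.category_bounds)
            if config.category_bounds
            else {}
        )
        try:
            for i, (ta, tm, rh) in zip(pw.index, pw.itertuples(index=False)):
                key = (round(ta, 2), round(tm, 2), round(rh, 1))
                hit = cache.get(key)
                if hit is None:
                    cat, reason = classify_week(ta, tm, rh)
                    hit = (cat.label if cat else None, reason)
                    cache[key] = hit
                labels[i], reasons[i] = hit
        finally:
            if prev_bounds:
                override_category_bounds(prev_bounds)
        merged["category"] = labels
        merged["exclusion_reason"] = reasons
        merged.loc[~has_weather, "exclusion_reason"] = "no weather"

        plants_df = frames["plants"][["plant_id", "volume_category"]]
        merged = merged.merge(plants_df, on="plant_id", how="left")

        modelled = merged[merged["category"].notna()].copy()
        n_no_weather = int((~has_weather).sum())
        n_out_of_cal = int((merged["category"].isna() & merged["t_avg_week"].notna()).sum())
        manifest["n_excluded_no_weather"] = n_no_weather
        manifest["n_excluded_out_of_calibration"] = n_out_of_cal
        manifest["n_baseline"] = int((modelled["category"] == "baseline").sum())
        manifest["n_modelled_hi"] = int(modelled["category"].isin(HI_LABELS).sum())
        manifest["n_modelled_min_temp"] = int(modelled["category"].isin(COLD_LABELS).sum())
        assert (
            manifest["n_baseline"]
            + manifest["n_modelled_hi"]
            + manifest["n_modelled_min_temp"]
            + n_no_weather
            + n_out_of_cal
            + manifest["n_excluded_invalid"]
            == manifest["n_input_records"]
        ), "record accounting does not partition the input"

        stage("table2_dlr")
        t2 = dlr_by_month(modelled, weather)
        t2.to_csv(os.path.join(config.outdir, TABLE_FILES[0]), index=False)
        manifest["dlr_all_percent"] = dead_loss_ratio(
            modelled["condemned"].sum(), modelled["total"].sum()
        )

        spec = ModelSpec()
        classes = sorted(set(modelled["swine_class"]))
        results = {}
        for axis, labels_ax, trisk, trr in (
            ("hi", HI_LABELS, TABLE_FILES[1], TABLE_FILES[2]),
            ("mintemp", COLD_LABELS, TABLE_FILES[3], TABLE_FILES[4]),
        ):
            stage(f"fit_{axis}")
            sub = modelled[modelled["category"].isin(("baseline",) + tuple(labels_ax))]
            fit = fit_zinb_glmm(sub, spec, quad_points=config.quad_points)
            if not fit.converged:
                raise RuntimeError(f"{axis} model did not converge: {fit.message}")
            fit.to_json(os.path.join(config.outdir, f"fit_{axis}.json"))
            with open(os.path.join(config.outdir, f"fit_{axis}.txt"), "w") as fh:
                fh.write(fit.summary() + "\n")
            cats_present = [
                lab for lab in labels_ax
                if all((c, lab) in fit.beta_names for c in classes)
            ]
            table = build_risk_table(fit, classes, cats_present)
            table.round(6).to_csv(os.path.join(config.outdir, trisk), index=False)
            rr = table[["swine_class", "category", "rr", "rr_lo", "rr_hi"]]
            rr.round(4).to_csv(os.path.join(config.outdir, trr), index=False)
            results[axis] = {"fit": fit, "risk_table": table}

        stage("revenue")
        baseline_rows = modelled[modelled["category"] == "baseline"]
        extreme_rows = modelled[modelled["category"] != "baseline"]
        base_fit = fit_baseline_model(baseline_rows, quad_points=config.quad_points)
        base_fit.to_json(os.path.join(config.outdir, "fit_baseline.json"))
        ledger = excess_condemnations(
            base_fit, extreme_rows, population=config.population_prediction
        )
        ledger = price_condemnations(ledger, frames["prices"])
        t7 = summarize_ledger(ledger)
        t7.round(4).to_csv(os.path.join(config.outdir, TABLE_FILES[5]), index=False)
        results["revenue"] = {"fit": base_fit, "ledger": ledger, "summary": t7}

        stage("figures")
        for cls, fname in zip(("roaster", "market", "cull_sow"), FIGURE_FILES):
            rows = modelled[modelled["swine_class"] == cls]
            if rows.empty:
                pd.DataFrame(columns=["week", "dlr", "foregone_usd"]).to_csv(
                    os.path.join(config.outdir, fname), index=False
                )
                continue
            weekly = (
                rows.groupby("week")
                .apply(
                    lambda g: dead_loss_ratio(g["condemned"].sum(), g["total"].sum()),
                    include_groups=False,
                )
                .rename("dlr")
                .reset_index()
            )
            led_cls = ledger[ledger["swine_class"] == cls]
            rev = led_cls.groupby("week")["foregone_usd"].sum().rename("foregone_usd")
            weekly = weekly.merge(rev.reset_index(), on="week", how="left").fillna(
                {"foregone_usd": 0.0}
            )
            weekly.round(6).to_csv(os.path.join(config.outdir, fname), index=False)

        manifest["ok"] = True
    except Exception as e:
        manifest["ok"] = False
        manifest["error"] = f"{manifest['stages'][-1] if manifest['stages'] else '?'}: {e}"
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    if bundle is not None:
        manifest["generator_truth_seed"] = bundle.truth["seed"]
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["_results"] = results
    return manifest
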