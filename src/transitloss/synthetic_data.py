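"""Synthetic slaughter-surveillance bundle with known ground truth.

Emulates the four input streams of the condemnation analysis — weekly
slaughter records per plant and swine class, a weather-station catalog,
daily station observations, and monthly price series — with the generating
parameters recorded so every pipeline stage can be tested against truth.

The count process is the fitted model's own data-generating process: for a
plant-week of ``N`` head in class ``c`` whose true exposure category is
``k`` (derived by running the real exposure code on the plant's weekly
weather, never by shortcut labelling),

    Y ~ ZINB(mu, theta, pi),   mu = N * CR(c, k) * exp(u_g) / (1 - pi)

so the unconditional mean at ``u=0`` is ``N * CR(c, k)``: the generating
CR is the population-level per-head rate the model's CR estimates.  The
random intercept ``u_g`` is drawn once per processing-volume category.

Default generating CRs are the published per-cell rates of the source
surveillance analysis (cull sows most heat-sensitive; roasters
cold-sensitive and heat-insensitive), so the default regime reproduces the
qualitative pattern of the real study.  Weather follows per-plant seasonal
sinusoids (warm summers, cold northern winters); prices follow seasonal
shapes with the market price peaking in summer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geoweather import VOLUME_CATEGORIES, iso_week_label
from .heat_exposure import classify_week
from .zinb_glmm import zinb_rvs

#: Published per-cell condemnation rates used as default generating truth.
DEFAULT_TRUE_RATES = {
    ("roaster", "baseline"): 0.00123,
    ("roaster", "moderate"): 0.00173,
    ("roaster", "hot"): 0.00098,
    ("roaster", "very_hot"): 0.00015,
    ("roaster", "cool"): 0.00149,
    ("roaster", "cold"): 0.00191,
    ("roaster", "very_cold"): 0.00271,
    ("market", "baseline"): 0.0030,
    ("market", "moderate"): 0.0038,
    ("market", "hot"): 0.0041,
    ("market", "very_hot"): 0.0035,
    ("market", "cool"): 0.0029,
    ("market", "cold"): 0.0033,
    ("market", "very_cold"): 0.0043,
    ("cull_sow", "baseline"): 0.0027,
    ("cull_sow", "moderate"): 0.0056,
    ("cull_sow", "hot"): 0.0052,
    ("cull_sow", "very_hot"): 0.0061,
    ("cull_sow", "cool"): 0.0022,
    ("cull_sow", "cold"): 0.0023,
    ("cull_sow", "very_cold"): 0.0029,
}

#: Weekly head ranges per processing-volume category.
HEAD_RANGES = {
    "VS": (30, 200),
    "S": (201, 2_000),
    "M": (2_001, 5_000),
    "L": (5_001, 15_000),
    "VL": (15_001, 110_000),
}

#: Class shares of weekly head by volume category: the largest plants are
#: (nearly) market-only; roasters come almost entirely from small plants.
CLASS_SHARES = {
    "VS": {"market": 0.30, "cull_sow": 0.20, "roaster": 0.50},
    "S": {"market": 0.50, "cull_sow": 0.20, "roaster": 0.30},
    "M": {"market": 0.70, "cull_sow": 0.30, "roaster": 0.0},
    "L": {"market": 0.80, "cull_sow": 0.20, "roaster": 0.0},
    "VL": {"market": 1.0, "cull_sow": 0.0, "roaster": 0.0},
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic bundle; defaults are the emulated study scale."""

    seed: int = 20170511
    n_plants: int = 149
    years: int = 6
    start_year: int = 2010
    volume_mix: dict = field(
        default_factory=lambda: {"VS": 0.22, "S": 0.38, "M": 0.10, "L": 0.10, "VL": 0.20}
    )
    true_rates: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    theta: float = 1.5
    pi: float = 0.45
    sigma_u: float = 0.3
    orphan_fraction: float = 0.05  # plants with no station within 100 mi
    stations_per_plant: tuple = (1, 4)
    # weather model: per-plant annual sinusoid in °F, peak near day 199 (July)
    lat_range: tuple = (31.0, 45.0)
    lon_range: tuple = (-100.0, -75.0)
    peak_doy: float = 199.0
    daily_sd: float = 5.0
    min_temp_spread: float = 12.0  # mean daily t_avg - t_min gap
    # price model, USD; market price per head peaks in summer
    market_price_base: float = 150.0
    market_price_amp: float = 30.0
    cull_price_base: float = 100.0
    cull_price_amp: float = 15.0
    dressed_cwt_base: float = 78.0
    dressed_cwt_amp: float = 14.0

    def validate(self) -> None:
        if self.n_plants < 1 or self.years < 1:
            raise ValueError("need at least one plant and one year")
        if abs(sum(self.volume_mix.values()) - 1.0) > 1e-9:
            raise ValueError("volume_mix proportions must sum to 1")
        for cell, r in self.true_rates.items():
            if not 0.0 < r < 1.0:
                raise ValueError(f"rate for {cell} outside (0, 1)")
        if self.theta <= 0 or not 0 <= self.pi < 1 or self.sigma_u < 0:
            raise ValueError("theta, pi, sigma_u outside their domains")
        if not 0.0 <= self.orphan_fraction < 1.0:
            raise ValueError("orphan_fraction must be in [0, 1)")


@dataclass
class SyntheticBundle:
    plants: pd.DataFrame
    stations: pd.DataFrame
    daily_weather: pd.DataFrame
    slaughter: pd.DataFrame
    prices: pd.DataFrame
    truth: dict


def _seasonal(doy, mean, amp, peak_doy):
    return mean + amp * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def _offset_latlon(lat, lon, dist_miles, bearing):
    dlat = dist_miles * np.cos(bearing) / 69.09
    dlon = dist_miles * np.sin(bearing) / (69.09 * np.cos(np.radians(lat)))
    return lat + dlat, lon + dlon


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Deterministically generate a full synthetic bundle from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- plants ---------------------------------------------------------
    cats = []
    for cat in VOLUME_CATEGORIES:
        cats += [cat] * int(round(config.volume_mix[cat] * config.n_plants))
    while len(cats) < config.n_plants:
        cats.append("S")
    cats = cats[: config.n_plants]
    n = config.n_plants
    plant_ids = [f"P{i + 1:03d}" for i in range(n)]
    lat = rng.uniform(*config.lat_range, n)
    lon = rng.uniform(*config.lon_range, n)
    n_orphan = int(np.floor(config.orphan_fraction * n))
    orphan = np.zeros(n, dtype=bool)
    if n_orphan:
        orphan[rng.choice(n, size=n_orphan, replace=False)] = True
        # orphan plants sit on a remote, widely spaced grid so that no
        # station in the catalog (their own included) is within the radius
        for j, i in enumerate(np.flatnonzero(orphan)):
            lat[i] = 25.0 + 7.0 * (j % 8)
            lon[i] = -140.0 - 12.0 * (j // 8)
    plants = pd.DataFrame(
        {
            "plant_id": plant_ids,
            "lat": np.round(lat, 4),
            "lon": np.round(lon, 4),
            "volume_category": cats,
        }
    )

    # --- stations -------------------------------------------------------
    st_rows = []
    for i in range(n):
        k = int(rng.integers(config.stations_per_plant[0], config.stations_per_plant[1] + 1))
        for j in range(k):
            d = rng.uniform(120.0, 150.0) if orphan[i] else rng.uniform(5.0, 90.0)
            b = rng.uniform(0.0, 2.0 * np.pi)
            slat, slon = _offset_latlon(lat[i], lon[i], d, b)
            st_rows.append(
                {
                    "station_id": f"{plant_ids[i]}-S{j + 1}",
                    "lat": round(float(slat), 4),
                    "lon": round(float(slon), 4),
                    "plant_idx": i,
                }
            )
    stations = pd.DataFrame(st_rows)

    # --- daily weather --------------------------------------------------
    start = np.datetime64(f"{config.start_year}-01-01")
    end = np.datetime64(f"{config.start_year + config.years - 1}-12-31")
    dates = np.arange(start, end + 1)
    doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
    nd = dates.size

    # Weather is a smooth function of location plus a spatially coherent
    # regional daily anomaly field (a national anomaly with gentle north-
    # south and east-west gradients).  Spatial coherence matters: a plant's
    # closest stations may belong to a neighbouring plant, and pooling them
    # must reproduce the plant's own weather up to instrument-scale noise,
    # as it does for real co-located observations.
    anom_t = rng.normal(0.0, config.daily_sd, nd)
    grad_lat = rng.normal(0.0, 1.2, nd)
    grad_lon = rng.normal(0.0, 1.2, nd)
    anom_spread = rng.normal(0.0, 2.0, nd)
    anom_rh = rng.normal(0.0, 5.0, nd)
    grad_rh = rng.normal(0.0, 1.5, nd)

    def _site_weather(loc_lat, loc_lon, noise_rng=None):
        zlat = (loc_lat - 38.0) / 7.0
        zlon = (loc_lon + 87.5) / 12.5
        t_mean = 68.0 - 1.35 * (loc_lat - 31.0)
        t_amp = 15.0 + 0.85 * (loc_lat - 31.0)
        t_avg = (
            _seasonal(doy, t_mean, t_amp, config.peak_doy)
            + anom_t + grad_lat * zlat + grad_lon * zlon
        )
        spread = np.clip(config.min_temp_spread + anom_spread, 4.0, None)
        rh = np.clip(
            _seasonal(doy, 55.0, 15.0, config.peak_doy) + anom_rh + grad_rh * zlat,
            5.0,
            100.0,
        )
        if noise_rng is not None:
            t_avg = t_avg + noise_rng.normal(0, 0.2, nd)
            rh = np.clip(rh + noise_rng.normal(0, 0.5, nd), 5.0, 100.0)
        return t_avg, np.minimum(t_avg - spread, t_avg), rh

    site_t_avg = np.empty((n, nd))
    site_t_min = np.empty((n, nd))
    site_rh = np.empty((n, nd))
    for i in range(n):
        site_t_avg[i], site_t_min[i], site_rh[i] = _site_weather(lat[i], lon[i])

    daily_rows = []
    for s in stations.itertuples(index=False):
        t_avg, t_min, rh = _site_weather(s.lat, s.lon, noise_rng=rng)
        daily_rows.append(
            pd.DataFrame(
                {
                    "station_id": s.station_id,
                    "date": dates,
                    "t_avg": np.round(t_avg, 2),
                    "t_min": np.round(t_min, 2),
                    "rh": np.round(rh, 1),
                }
            )
        )
    daily_weather = pd.concat(daily_rows, ignore_index=True)
    stations = stations.drop(columns="plant_idx")

    # --- true plant-week weather and categories -------------------------
    week_labels = iso_week_label(pd.Series(dates)).to_numpy()
    weeks_order = pd.unique(week_labels)
    truth_cat_rows = []
    for i in range(n):
        df = pd.DataFrame(
            {
                "week": week_labels,
                "t_avg": site_t_avg[i],
                "t_min": site_t_min[i],
                "rh": site_rh[i],
            }
        )
        agg = df.groupby("week", sort=False).mean()
        agg = agg.loc[[w for w in weeks_order if w in agg.index]]
        for wk, row in agg.iterrows():
            cat, reason = classify_week(row["t_avg"], row["t_min"], row["rh"])
            if cat is None:
                # out-of-calibration truth weather: clamp to nearest bin
                label = "very_hot" if "106" in reason else (
                    "very_cold" if "-17" in reason or "−17" in reason else "baseline"
                )
            else:
                label = cat.label
            truth_cat_rows.append(
                {
                    "plant_id": plant_ids[i],
                    "week": wk,
                    "true_category": label,
                    "true_t_avg": row["t_avg"],
                    "true_t_min": row["t_min"],
                    "true_rh": row["rh"],
                }
            )
    true_categories = pd.DataFrame(truth_cat_rows)

    # --- random intercepts and slaughter records ------------------------
    # realized group intercepts are centred to zero mean: with five groups
    # the mean of one realization is not separable from the fixed effects,
    # and the declared truth rates are population-level (u = 0) quantities
    u_draw = rng.normal(0.0, config.sigma_u, len(VOLUME_CATEGORIES))
    if config.sigma_u > 0:
        u_draw = u_draw - u_draw.mean()
    u_by_group = dict(zip(VOLUME_CATEGORIES, (float(v) for v in u_draw)))
    cat_by_pw = true_categories.set_index(["plant_id", "week"])["true_category"]

    slaughter_rows = []
    for i in range(n):
        vcat = cats[i]
        lo, hi = HEAD_RANGES[vcat]
        mean_head = float(np.exp(rng.uniform(np.log(lo + 1), np.log(hi))))
        pw = true_categories[true_categories["plant_id"] == plant_ids[i]]
        nw = len(pw)
        week_head = np.maximum(
            np.round(mean_head * np.exp(rng.normal(0, 0.15, nw))).astype(int), lo
        )
        p_weeks, p_cls, p_head, p_mu = [], [], [], []
        for (wk, label), head in zip(
            zip(pw["week"], pw["true_category"]), week_head
        ):
            for cls, share in CLASS_SHARES[vcat].items():
                nh = int(round(share * head))
                if nh < 1:
                    continue
                cr = config.true_rates[(cls, label)]
                p_weeks.append(wk)
                p_cls.append(cls)
                p_head.append(nh)
                p_mu.append(nh * cr * np.exp(u_by_group[vcat]) / (1.0 - config.pi))
        if not p_weeks:
            continue
        ys = zinb_rvs(np.asarray(p_mu), config.theta, config.pi, rng)
        slaughter_rows.append(
            pd.DataFrame(
                {
                    "plant_id": plant_ids[i],
                    "week": p_weeks,
                    "swine_class": p_cls,
                    "total": p_head,
                    "condemned": np.minimum(ys, p_head).astype(int),
                }
            )
        )
    slaughter = pd.concat(slaughter_rows, ignore_index=True)

    # --- monthly prices --------------------------------------------------
    # cover one month either side: boundary ISO weeks can price into the
    # neighbouring calendar year
    price_rows = []
    months = [(config.start_year - 1, 12)]
    months += [
        (y, m)
        for y in range(config.start_year, config.start_year + config.years)
        for m in range(1, 13)
    ]
    months.append((config.start_year + config.years, 1))
    for year, m in months:
            mkt = config.market_price_base + config.market_price_amp * np.cos(
                2 * np.pi * (m - 7) / 12.0
            ) + rng.normal(0, 3.0)
            cull = config.cull_price_base + config.cull_price_amp * np.cos(
                2 * np.pi * (m - 6) / 12.0
            ) + rng.normal(0, 2.0)
            cwt = config.dressed_cwt_base + config.dressed_cwt_amp * np.cos(
                2 * np.pi * (m - 7) / 12.0
            ) + rng.normal(0, 1.5)
            price_rows.append(
                {
                    "year": year,
                    "month": m,
                    "swine_class": "market",
                    "price_per_head": round(float(mkt), 2),
                    "dressed_price_per_cwt": round(float(cwt), 2),
                }
            )
            price_rows.append(
                {
                    "year": year,
                    "month": m,
                    "swine_class": "cull_sow",
                    "price_per_head": round(float(cull), 2),
                    "dressed_price_per_cwt": np.nan,
                }
            )
    prices = pd.DataFrame(price_rows)

    truth = {
        "seed": config.seed,
        "config": config,
        "true_rates": dict(config.true_rates),
        "theta": config.theta,
        "pi": config.pi,
        "sigma_u": config.sigma_u,
        "u_by_group": u_by_group,
        "orphan_plant_ids": [plant_ids[i] for i in range(n) if orphan[i]],
        "true_categories": true_categories,
    }
    return SyntheticBundle(
        plants=plants,
        stations=stations,
        daily_weather=daily_weather,
        slaughter=slaughter,
        prices=prices,
        truth=truth,
    )


def simulate_records(
    seed: int,
    n_rows: int,
    cells=None,
    true_rates: dict | None = None,
    theta: float = 1.5,
    pi: float = 0.45,
    sigma_u: float = 0.3,
    head_range: tuple = (100, 5_000),
    center_u: bool = True,
    u_override: dict | None = None,
):
    """Direct ZINB record simulation with known truth (no weather layer).

    Draws plant-week-class rows with uniform cell assignment and log-uniform
    head counts.  ``center_u=True`` centres the five realized group
    intercepts to zero mean: with only five groups the mean of the realized
    intercepts is not separable from the fixed effects, and recovery
    comparisons target the fixed effects.  Returns ``(records, truth)``.
    """
    rates = dict(true_rates or DEFAULT_TRUE_RATES)
    cells = list(cells or rates.keys())
    rng = np.random.default_rng(seed)
    groups = list(VOLUME_CATEGORIES)
    u = rng.normal(0.0, sigma_u, len(groups))
    if center_u and sigma_u > 0:
        u = u - u.mean()
    if u_override is not None:
        u = np.array([u_override[g] for g in groups])
    u_by_group = dict(zip(groups, u))
    idx = rng.integers(0, len(cells), n_rows)
    g_idx = rng.integers(0, len(groups), n_rows)
    head = np.exp(rng.uniform(np.log(head_range[0]), np.log(head_range[1]), n_rows))
    head = np.maximum(np.round(head), 1).astype(int)
    rate = np.array([rates[cells[i]] for i in idx])
    mu = head * rate * np.exp(u[g_idx]) / (1.0 - pi) if pi < 1 else head * rate
    y = zinb_rvs(mu, theta, pi, rng)
    records = pd.DataFrame(
        {
            "plant_id": "P000",
            "week": "2010-W01",
            "swine_class": [cells[i][0] for i in idx],
            "category": [cells[i][1] for i in idx],
            "volume_category": [groups[i] for i in g_idx],
            "total": head,
            "condemned": np.minimum(y, head).astype(int),
        }
    )
    truth = {
        "seed": seed,
        "true_rates": {c: rates[c] for c in cells},
        "theta": theta,
        "pi": pi,
        "sigma_u": sigma_u,
        "u_by_group": u_by_group,
    }
    return records, truth


def truth_report(bundle: SyntheticBundle) -> dict:
    """Every generating parameter of a bundle, for recovery comparisons."""
    t = dict(bundle.truth)
    rates = t["true_rates"]
    rr = {}
    for (cls, label), cr in rates.items():
        if label == "baseline":
            continue
        rr[(cls, label)] = cr / rates[(cls, "baseline")]
    t["true_rr"] = rr
    return t


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write the bundle as the CSV dialects the pipeline reads."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("plants", "stations", "daily_weather", "slaughter", "prices"):
        path = os.path.join(outdir, f"{name}.csv")
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    return paths
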