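"""Counterfactual foregone-revenue attribution for temperature extremes.

A second, class-only ZINB mixed model is fitted to baseline-temperature
weeks (weekly minimum above 50 °F, weekly average below 80 °F) to predict
how many "dead" condemnations each extreme-temperature plant-week would
have seen at baseline conditions.  The residual

    excess = observed condemned - expected condemned

is attributed to temperature, summed per class x exposure category, and
priced with monthly series: market and cull sows at the month's price per
head, roasters at the median roaster carcass weight (70 lbs) times the
market dressed price per hundredweight, i.e. 0.70 x $/cwt per head.
Residuals are summed signed; a category can show negative excess.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .heat_exposure import COLD_LABELS, HI_LABELS
from .risk_metrics import iso_week_month
from .zinb_glmm import ModelSpec, ZinbFit, fit_zinb_glmm

ROASTER_CARCASS_LBS = 70.0

BASELINE_SPEC = ModelSpec(fixed=("swine_class",))


def fit_baseline_model(baseline: pd.DataFrame, quad_points: int = 15) -> ZinbFit:
    """Fit the class-only counterfactual model on baseline-temperature weeks."""
    classes = sorted(set(baseline["swine_class"]))
    counts = baseline.groupby("swine_class").size()
    missing = [c for c in classes if counts.get(c, 0) == 0]
    if baseline.empty or missing:
        raise ValueError(f"no baseline weeks for classes: {missing or 'all'}")
    return fit_zinb_glmm(baseline, BASELINE_SPEC, quad_points=quad_points)


def expected_counts(fit: ZinbFit, rows: pd.DataFrame, population: bool = False) -> np.ndarray:
    """Model-expected condemnations for observed plant-weeks.

    Uses the estimated random-effect mode of each row's volume category
    (prediction for the observed groups); ``population=True`` sets the
    random effect to zero instead.
    """
    missing = set(rows["volume_category"]) - set(fit.u_hat)
    if missing:
        raise ValueError(f"volume categories absent from baseline fit: {sorted(missing)}")
    u = np.zeros(len(rows)) if population else rows["volume_category"].map(fit.u_hat).to_numpy(float)
    beta = np.array([fit.coef((c,)) for c in rows["swine_class"]])
    return (1.0 - fit.pi) * np.exp(beta + np.log(rows["total"].to_numpy(float)) + u)


def excess_condemnations(
    fit_baseline: ZinbFit, extreme_weeks: pd.DataFrame, population: bool = False
) -> pd.DataFrame:
    """Per-row excess condemnations on extreme-temperature weeks.

    ``extreme_weeks`` must carry ``plant_id, week, swine_class, category,
    volume_category, total, condemned``.  Returns the ledger rows with
    ``expected`` and signed ``excess`` columns.
    """
    if not fit_baseline.converged:
        raise RuntimeError("baseline model did not converge")
    need = {"plant_id", "week", "swine_class", "category", "volume_category", "total", "condemned"}
    lack = need - set(extreme_weeks.columns)
    if lack:
        raise ValueError(f"extreme-week table missing columns: {sorted(lack)}")
    ledger = extreme_weeks.copy()
    ledger["expected"] = expected_counts(fit_baseline, ledger, population=population)
    ledger["excess"] = ledger["condemned"] - ledger["expected"]
    return ledger


def price_condemnations(ledger: pd.DataFrame, prices: pd.DataFrame) -> pd.DataFrame:
    """Attach foregone revenue to ledger rows from a monthly price series.

    ``prices`` columns: ``year`` (optional), ``month``, ``swine_class``,
    ``price_per_head`` and, for market swine, ``dressed_price_per_cwt``.
    Each ledger week is priced at its majority calendar month (the month of
    the ISO week's Thursday).  Roaster rows use 70/100 of the market dressed
    price per hundredweight as the per-head price.
    """
    by_year = "year" in prices.columns
    key_cols = ["year", "month"] if by_year else ["month"]
    ptab = prices.set_index(key_cols + ["swine_class"])

    def lookup(year, month, cls, col):
        key = (year, month, cls) if by_year else (month, cls)
        try:
            return float(ptab.loc[key, col])
        except KeyError:
            return np.nan

    out = ledger.copy()
    ym = [iso_week_month(w) for w in out["week"]]
    out["price_year"] = [y for y, _ in ym]
    out["price_month"] = [m for _, m in ym]
    price = np.empty(len(out))
    for i, (y, m, cls) in enumerate(
        zip(out["price_year"], out["price_month"], out["swine_class"])
    ):
        if cls == "roaster":
            cwt = lookup(y, m, "market", "dressed_price_per_cwt")
            price[i] = ROASTER_CARCASS_LBS / 100.0 * cwt
        else:
            price[i] = lookup(y, m, cls, "price_per_head")
    if np.any(np.isnan(price)):
        bad = out.loc[np.isnan(price), ["price_year", "price_month", "swine_class"]]
        missing = sorted(set(map(tuple, bad.itertuples(index=False))))
        raise ValueError(f"price series missing months: {missing}")
    out["price_per_head"] = price
    out["foregone_usd"] = out["excess"] * price
    return out


def _axis_of(label: str) -> str:
    if label in HI_LABELS:
        return "HI"
    if label in COLD_LABELS:
        return "MIN_TEMP"
    return "BASELINE"


def summarize_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Per class x category totals with an axis total row per class.

    Columns: increased condemnations (signed sum of excess), foregone USD
    (thousands), head in category (thousands), and the percent of head in
    the category condemned due to temperature.
    """
    led = ledger.copy()
    led["axis"] = led["category"].map(_axis_of)
    rows = []

    def _summary_row(cls, axis, label, sub):
        excess = float(sub["excess"].sum())
        head = float(sub["total"].sum())
        return {
            "swine_class": cls,
            "axis": axis,
            "category": label,
            "increased_condemns": excess,
            "foregone_usd_thousands": float(sub["foregone_usd"].sum()) / 1_000.0,
            "head_thousands": head / 1_000.0,
            "percent_condemned": excess / head * 100.0 if head > 0 else np.nan,
        }

    for (cls, axis), sub_ax in led.groupby(["swine_class", "axis"], sort=True):
        for label, sub in sub_ax.groupby("category", sort=True):
            rows.append(_summary_row(cls, axis, label, sub))
        rows.append(_summary_row(cls, axis, "total", sub_ax))
    return pd.DataFrame(rows)


def category_percent(increased: float, head: float) -> float:
    """Percent of swine in a category condemned due to temperature."""
    if head <= 0:
        raise ValueError("head count must be positive")
    return increased / head * 100.0
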