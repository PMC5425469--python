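"""Epidemiological summaries: CR, EIR, AR, RR with 95% CIs, and DLR.

All metrics derive from the model-estimated condemnation rate (CR), the
per-head probability that an animal is condemned "dead" in a given swine
class and exposure category:

    EIR = round(CR x 10,000)            expected dead per 10,000 slaughtered
    AR  = CR_exposed - CR_baseline      risk difference within a class
    RR  = CR_exposed / CR_baseline      risk ratio within a class
    DLR = condemned / total x 100       observed dead-loss percentage

RR intervals are Wald intervals on the log scale from the delta-method
standard error of log RR.  Metrics are computed on unrounded values and
rounded only for display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .heat_exposure import COLD_LABELS, HI_LABELS
from .zinb_glmm import ZinbFit, predict_rate

BASELINE_LABEL = "baseline"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def expected_incidence(cr: float) -> int:
    """Expected incidence rate per 10,000 head: round(CR x 10,000)."""
    if not 0.0 <= cr <= 1.0:
        raise ValueError(f"condemnation rate {cr} outside [0, 1]")
    return _round_half_up(cr * 10_000)


def attributable_risk(cr_exposed: float, cr_baseline: float) -> float:
    """Risk difference (signed): exposed CR minus the class's baseline CR."""
    for v in (cr_exposed, cr_baseline):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"condemnation rate {v} outside [0, 1]")
    return cr_exposed - cr_baseline


def risk_ratio(cr_exposed: float, cr_baseline: float, se_log_rr: float | None = None):
    """Risk ratio vs the class baseline, optionally with a 95% Wald CI.

    Returns ``(rr, None)`` when no standard error is supplied, else
    ``(rr, (lo, hi))`` with ``exp(log RR +/- 1.96 se)``.
    """
    if cr_baseline <= 0:
        raise ValueError("baseline condemnation rate must be positive")
    rr = cr_exposed / cr_baseline
    if se_log_rr is None:
        return rr, None
    if se_log_rr < 0:
        raise ValueError("standard error must be non-negative")
    half = min(1.96 * se_log_rr, 700.0)  # avoid overflow on hopeless SEs
    return rr, (rr * np.exp(-half), rr * np.exp(half))


def dead_loss_ratio(condemned: float, total: float) -> float:
    """Dead loss ratio in percent: condemned / total x 100."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if condemned < 0 or condemned > total:
        raise ValueError("condemned must lie in [0, total]")
    return condemned / total * 100.0


def risk_table_from_rates(cr_by_cell: dict) -> pd.DataFrame:
    """Assemble the CR/AR/EIR/RR table from per-cell condemnation rates.

    ``cr_by_cell`` maps ``(swine_class, category_label)`` to a CR; every
    class must include a ``baseline`` entry.  This is the definitional part
    of the risk table (no intervals) and is also usable directly on
    published per-cell rates.
    """
    classes = sorted({c for c, _ in cr_by_cell})
    rows = []
    for cls in classes:
        if (cls, BASELINE_LABEL) not in cr_by_cell:
            raise ValueError(f"class {cls!r} has no baseline rate")
        base = cr_by_cell[(cls, BASELINE_LABEL)]
        for (c, label), cr in cr_by_cell.items():
            if c != cls:
                continue
            is_base = label == BASELINE_LABEL
            rr, _ = risk_ratio(cr, base)
            rows.append(
                {
                    "swine_class": cls,
                    "category": label,
                    "cr": cr,
                    "eir": expected_incidence(cr),
                    "ar": np.nan if is_base else attributable_risk(cr, base),
                    "rr": 1.0 if is_base else rr,
                }
            )
    return pd.DataFrame(rows)


_LABEL_ORDER = {
    lab: i
    for i, lab in enumerate(
        (BASELINE_LABEL,) + HI_LABELS + tuple(COLD_LABELS[::-1])
    )
}


def build_risk_table(fit: ZinbFit, classes, categories) -> pd.DataFrame:
    """One row per class x category: CR, EIR, AR, RR, and the RR 95% CI.

    ``categories`` are exposure labels fitted alongside ``baseline`` in the
    same model; the RR interval uses the delta-method SE of log RR from the
    coefficient covariance.
    """
    if not fit.converged:
        raise RuntimeError("model fit did not converge")
    rows = []
    for cls in classes:
        base_cr = predict_rate(fit, cls, BASELINE_LABEL)
        for label in (BASELINE_LABEL, *categories):
            cr = predict_rate(fit, cls, label)
            if label == BASELINE_LABEL:
                rows.append(
                    {
                        "swine_class": cls,
                        "category": label,
                        "cr": cr,
                        "eir": expected_incidence(cr),
                        "ar": np.nan,
                        "rr": 1.0,
                        "rr_lo": np.nan,
                        "rr_hi": np.nan,
                    }
                )
                continue
            se = fit.log_rr_se((cls, label), (cls, BASELINE_LABEL))
            rr, ci = risk_ratio(cr, base_cr, se)
            rows.append(
                {
                    "swine_class": cls,
                    "category": label,
                    "cr": cr,
                    "eir": expected_incidence(cr),
                    "ar": attributable_risk(cr, base_cr),
                    "rr": rr,
                    "rr_lo": ci[0],
                    "rr_hi": ci[1],
                }
            )
    out = pd.DataFrame(rows)
    out["_ord"] = out["category"].map(_LABEL_ORDER)
    out = out.sort_values(["swine_class", "_ord"]).drop(columns="_ord")
    return out.reset_index(drop=True)


def dlr_by_month(records: pd.DataFrame, weather: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monthly dead-loss ratios across all classes, with temperature context.

    ``records`` needs ``week``, ``condemned``, ``total``; months are taken
    from the ISO week's Thursday.  When a plant-week weather table is given
    (columns ``plant_id, week, t_avg_week, t_min_week``) the monthly mean
    average temperature and observed range are appended.
    """
    rec = records.copy()
    rec["month"] = [iso_week_month(w)[1] for w in rec["week"]]
    out = (
        rec.groupby("month")
        .apply(
            lambda g: dead_loss_ratio(g["condemned"].sum(), g["total"].sum()),
            include_groups=False,
        )
        .rename("dlr")
        .reset_index()
    )
    if weather is not None:
        w = weather.copy()
        w["month"] = [iso_week_month(x)[1] for x in w["week"]]
        agg = w.groupby("month").agg(
            avg_temp=("t_avg_week", "mean"),
            temp_lo=("t_min_week", "min"),
            temp_hi=("t_avg_week", "max"),
        )
        out = out.merge(agg.reset_index(), on="month", how="left")
    return out


def iso_week_month(week: str):
    """(year, month) of an ISO week's majority month (its Thursday)."""
    import datetime as _dt

    y, w = week.split("-W")
    d = _dt.date.fromisocalendar(int(y), int(w), 4)
    return d.year, d.month
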