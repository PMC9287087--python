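"""Derived statistics on treatment-level series.

All metrics are unit-free ratios/proportions computed per census period
from the aggregated treatment series, with explicit validity flags rather
than silent drops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import CONTROL, EXCLOSURE, Month, TimePeriodScheme

ENERGY = "energy"
BIOMASS = "biomass"

_COLS = {
    ENERGY: {"total": "Etot", "kr": "KR", "sg": "SG", "cb": "CB"},
    BIOMASS: {"total": "Btot", "kr": "B_KR", "sg": "B_SG", "cb": "B_CB"},
}

REASON_ZERO_DENOM = "zero denominator"
REASON_MISSING_TREATMENT = "missing treatment"
REASON_EMPTY_WINDOW = "no valid values in window"


def _pivot(ts: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = ts.pivot_table(
        index=["period_id", "month_index"], columns="treatment", values=column
    )
    for t in (CONTROL, EXCLOSURE):
        if t not in wide.columns:
            wide[t] = np.nan
    return wide.reset_index()


def _series(
    period_id, month_index, value, valid, reason, metric_kind: str, basis: str
) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "period_id": np.asarray(period_id, dtype=int),
            "month_index": np.asarray(month_index, dtype=int),
            "value": np.asarray(value, dtype=float),
            "valid": np.asarray(valid, dtype=bool),
            "reason": reason,
        }
    )
    out.attrs["metric_kind"] = metric_kind
    out.attrs["basis"] = basis
    return out


def label_periods(series: pd.DataFrame, scheme: TimePeriodScheme) -> pd.DataFrame:
    """Attach the time-period label of each census month."""
    series = series.copy()
    series["period_label"] = [
        scheme.assign(Month.from_index(int(i))) for i in series["month_index"]
    ]
    return series


def compensation(ts: pd.DataFrame, basis: str = ENERGY) -> pd.DataFrame:
    """(SG_E - SG_C) / KR_C per census period.

    Periods where the control kangaroo-rat denominator is zero are flagged
    invalid (reason "zero denominator"), never dropped.
    """
    c = _COLS[basis]
    sg = _pivot(ts, c["sg"])
    kr = _pivot(ts, c["kr"])
    kr_c = kr[CONTROL].to_numpy()
    num = sg[EXCLOSURE].to_numpy() - sg[CONTROL].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        value = num / kr_c
    missing = np.isnan(kr_c) | np.isnan(num)
    zero = ~missing & (kr_c == 0)
    valid = ~missing & ~zero
    reason = np.where(missing, REASON_MISSING_TREATMENT, np.where(zero, REASON_ZERO_DENOM, ""))
    return _series(
        sg["period_id"], sg["month_index"], np.where(valid, value, np.nan), valid, reason,
        "compensation", basis,
    )


def total_ratio(ts: pd.DataFrame, basis: str = ENERGY) -> pd.DataFrame:
    """Exclosure total over control total per census period."""
    c = _COLS[basis]
    tot = _pivot(ts, c["total"])
    den = tot[CONTROL].to_numpy()
    num = tot[EXCLOSURE].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        value = num / den
    missing = np.isnan(den) | np.isnan(num)
    zero = ~missing & (den == 0)
    valid = ~missing & ~zero
    reason = np.where(missing, REASON_MISSING_TREATMENT, np.where(zero, REASON_ZERO_DENOM, ""))
    return _series(
        tot["period_id"], tot["month_index"], np.where(valid, value, np.nan), valid, reason,
        "total_ratio", basis,
    )


def proportion(
    ts: pd.DataFrame,
    numerator: str,
    denominator: str,
    treatment: str,
    basis: str = ENERGY,
) -> pd.DataFrame:
    """Within-treatment share ``numerator/denominator`` per census period.

    ``numerator``/``denominator`` are guild keys: one of total, kr, sg, cb.
    0/0 is flagged invalid; a numerator exceeding its denominator violates
    the guild partition and is a hard error.
    """
    c = _COLS[basis]
    sub = ts[ts["treatment"] == treatment]
    num = sub[c[numerator]].to_numpy(dtype=float)
    den = sub[c[denominator]].to_numpy(dtype=float)
    if np.any(num > den * (1 + 1e-12) + 1e-12):
        raise ValueError(
            f"proportion {numerator}/{denominator}: numerator exceeds denominator"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        value = num / den
    zero = den == 0
    valid = ~zero
    reason = np.where(zero, REASON_ZERO_DENOM, "")
    kind = f"proportion_{numerator.upper()}_{treatment}"
    return _series(
        sub["period_id"], sub["month_index"], np.where(valid, np.clip(value, None, 1.0), np.nan),
        valid, reason, kind, basis,
    )


def moving_average(series: pd.DataFrame, window_months: int = 6) -> pd.DataFrame:
    """Trailing mean of valid values over a calendar-month window.

    For each census month t the window is (t - window, t]; months whose
    window contains no valid value are flagged invalid. Intended for
    plotting only — inference always uses the raw series.
    """
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    t = series["month_index"].to_numpy()
    v = series["value"].to_numpy()
    ok = series["valid"].to_numpy()
    out_val = np.full(len(series), np.nan)
    out_ok = np.zeros(len(series), dtype=bool)
    for i in range(len(series)):
        in_win = (t > t[i] - window_months) & (t <= t[i]) & ok
        if in_win.any():
            out_val[i] = v[in_win].mean()
            out_ok[i] = True
    reason = np.where(out_ok, "", REASON_EMPTY_WINDOW)
    out = _series(
        series["period_id"], series["month_index"], out_val, out_ok, reason,
        f"{series.attrs.get('metric_kind', 'metric')}_ma{window_months}",
        series.attrs.get("basis", ENERGY),
    )
    return out


def write_metric_series(series: pd.DataFrame, path) -> None:
    df = series.copy()
    df["metric_kind"] = series.attrs.get("metric_kind", "")
    df["basis"] = series.attrs.get("basis", "")
    df.to_csv(path, index=False)


def read_metric_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    kind = df.pop("metric_kind").iloc[0] if "metric_kind" in df.columns else ""
    basis = df.pop("basis").iloc[0] if "basis" in df.columns else ENERGY
    df["reason"] = df["reason"].fillna("")
    df.attrs["metric_kind"] = kind
    df.attrs["basis"] = basis
    return df
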