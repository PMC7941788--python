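"""Within-community matched design: weekday-matched controls and excess counts.

Each spatial unit's count on an exposed day is contrasted with the median of
that unit's own counts on the same weekday one and two weeks before and after
(four control days for the default two-week window). Self-matching removes
any time-fixed unit-level confounding; the median contrast is robust to a
single aberrant control week. The excess may be negative or half-integer
(the median of four counts is the mean of the middle two).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "MissingDataError",
    "select_control_days",
    "excess_count",
    "excess_panel",
    "mean_excess_for_mapping",
    "aggregate_excess",
    "period_summary",
]


class MissingDataError(KeyError):
    """A required (unit, date) cell is absent and strict mode forbids imputation."""

    def __init__(self, cells):
        self.cells = list(cells)
        shown = ", ".join(f"({u}, {d})" for u, d in self.cells[:10])
        more = "" if len(self.cells) <= 10 else f" and {len(self.cells) - 10} more"
        super().__init__(f"missing count cells: {shown}{more}")


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d))


@dataclass
class StudyDesign:
    """Exposed dates plus the bidirectional weekday-matched control rule.

    ``window_weeks`` is the half-width of the control window: each exposed day
    gets ``2 * window_weeks`` controls at exact +-7k day offsets, so controls
    always share the exposed day's weekday regardless of calendar convention.
    """

    exposed_dates: list
    window_weeks: int = 2
    label: str = ""
    exclude_dates: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.exposed_dates = [_as_date(d) for d in self.exposed_dates]
        if not self.exposed_dates:
            raise ValueError("exposed_dates must be non-empty")
        if any(b <= a for a, b in zip(self.exposed_dates, self.exposed_dates[1:])):
            raise ValueError("exposed_dates must be strictly increasing")
        if self.window_weeks < 1:
            raise ValueError("window_weeks must be >= 1")
        self.exclude_dates = frozenset(_as_date(d) for d in self.exclude_dates)

    def control_days(self, exposed_date) -> list:
        days = select_control_days(exposed_date, self.window_weeks)
        return [d for d in days if d not in self.exclude_dates]


def select_control_days(exposed_date, window_weeks: int = 2) -> list:
    """Control days at exposed_date +- 7k, k = 1..window_weeks, sorted ascending."""
    if window_weeks < 1:
        raise ValueError("window_weeks must be >= 1")
    e = _as_date(exposed_date)
    return sorted(
        e + dt.timedelta(days=7 * k)
        for k in range(-window_weeks, window_weeks + 1)
        if k != 0
    )


def _panel_lookup(panel: pd.DataFrame) -> dict:
    cols = {"unit_id", "date", "count"}
    if not cols.issubset(panel.columns):
        raise ValueError(f"panel needs columns {sorted(cols)}")
    dates = [_as_date(d) for d in panel["date"]]
    return dict(zip(zip(panel["unit_id"], dates), panel["count"].astype(float)))


def _cell_counts(lookup, unit_id, dates, strict):
    missing = [(unit_id, d) for d in dates if (unit_id, d) not in lookup]
    if missing and strict:
        raise MissingDataError(missing)
    return np.array([lookup.get((unit_id, d), 0.0) for d in dates])


def excess_count(unit_id, exposed_date, panel: pd.DataFrame, design: StudyDesign,
                 strict: bool = False) -> float:
    """Exposed-day count minus the median of the matched control-day counts.

    With ``strict=False`` (default) absent (unit, date) rows count as zero —
    long-format aggregated count data routinely omits zero cells. With
    ``strict=True`` any absent cell raises :class:`MissingDataError`.
    """
    exposed_date = _as_date(exposed_date)
    lookup = _panel_lookup(panel)
    controls = design.control_days(exposed_date)
    y_exp = _cell_counts(lookup, unit_id, [exposed_date], strict)[0]
    y_ctl = _cell_counts(lookup, unit_id, controls, strict)
    return float(y_exp - np.median(y_ctl))


def excess_panel(panel: pd.DataFrame, design: StudyDesign, strict: bool = False) -> pd.DataFrame:
    """Median-contrast excess for every (unit, exposed day).

    Returns a long frame ``unit_id, date, excess`` with attrs ``total_count``
    (county admissions summed over exposed days) and ``label``.
    """
    lookup = _panel_lookup(panel)
    units = pd.unique(panel["unit_id"])
    rows = []
    missing_all = []
    total_count = 0.0
    for d in design.exposed_dates:
        controls = design.control_days(d)
        for u in units:
            need = [d] + controls
            absent = [(u, dd) for dd in need if (u, dd) not in lookup]
            if absent and strict:
                missing_all.extend(absent)
                continue
            y_exp = lookup.get((u, d), 0.0)
            y_ctl = np.array([lookup.get((u, dd), 0.0) for dd in controls])
            rows.append((u, d, float(y_exp - np.median(y_ctl))))
            total_count += y_exp
    if missing_all:
        raise MissingDataError(missing_all)
    out = pd.DataFrame(rows, columns=["unit_id", "date", "excess"])
    out.attrs["total_count"] = total_count
    out.attrs["label"] = design.label
    return out


def mean_excess_for_mapping(excess: pd.DataFrame) -> pd.Series:
    """Per-unit arithmetic mean of excess over the exposed days (for mapping)."""
    return excess.groupby("unit_id", sort=True)["excess"].mean()


def aggregate_excess(excess: pd.DataFrame) -> pd.Series:
    """Per-unit sum of excess over the exposed days (the hierarchical-model response)."""
    return excess.groupby("unit_id", sort=True)["excess"].sum()


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def period_summary(excess: pd.DataFrame, total_count: float | None = None) -> dict:
    """County-level summary row: per-day totals, total excess/count, percent.

    ``percent_excess = 100 * total_excess / total_count`` is returned both
    unrounded and rounded half-away-from-zero to the nearest integer for
    reporting. ``total_count`` defaults to the value recorded by
    :func:`excess_panel`.
    """
    per_day = excess.groupby("date", sort=True)["excess"].sum()
    total_excess = float(per_day.sum())
    if total_count is None:
        total_count = excess.attrs.get("total_count")
    if total_count is None:
        raise ValueError("total_count not supplied and not present in excess.attrs")
    if total_count == 0:
        raise ZeroDivisionError("total admissions count is zero; percent undefined")
    pct = 100.0 * total_excess / float(total_count)
    return {
        "label": excess.attrs.get("label", ""),
        "per_day_excess": {str(d): float(v) for d, v in per_day.items()},
        "total_excess": total_excess,
        "total_count": float(total_count),
        "percent_excess": pct,
        "percent_excess_reported": _round_half_away(pct),
    }
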