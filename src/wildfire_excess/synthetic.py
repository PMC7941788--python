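"""Synthetic count panels and Gaussian-process fields with known ground truth.

Real hospital-discharge panels are confidential, so every downstream stage is
exercised on simulated data built to have the structure the analysis assumes:

* per-unit Poisson baselines ``lambda_i`` drawn lognormal, calibrated so the
  county-wide daily mean per unit sits in the 0.3-0.5 admissions range;
* multiplicative day-of-week effects;
* on exposed days, a wind-driven anisotropic plume multiplies the rate by
  ``1 + e_i(d)`` where ``e_i(d)`` is a Gaussian kernel elongated downwind of
  the fire with a hard cutoff strictly upwind.

Counts are ``Y_{i,d} ~ Poisson(lambda_i * dow(d) * (1 + e_i(d)))`` and the
generator returns the expected excess ``lambda_i * dow(d) * e_i(d)`` as ground
truth for recovery checks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "gen_geometry",
    "plume_exposure",
    "gen_count_panel",
    "gen_gp_field",
    "default_scenario",
]

_SQ2 = float(np.sqrt(2.0))

#: Default Santa Ana (offshore, from the NE) transport vector, km.
DEFAULT_WIND = (-1.0 / _SQ2, -1.0 / _SQ2)


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d))


@dataclass
class ScenarioConfig:
    """Parameters of a simulated wildfire-smoke study period.

    Defaults emulate a fall season over ~100 spatial units with a five-day
    smoke event. ``wind_vectors`` gives one transport vector per exposed day;
    the default flips from offshore to onshore on the final exposed day,
    moving the plume footprint inland.

    Parameters
    ----------
    baseline_log_mean, baseline_log_sd
        Parameters of the lognormal draw of the per-unit Poisson rate
        ``lambda_i`` (daily admissions). The default mean is calibrated so
        ``E[lambda]`` is ~0.4 per unit per day.
    dow_effects
        Seven positive multipliers, Monday first.
    plume_amplitude
        Peak relative excess ``A``; the rate at the fire location on an
        exposed day is ``lambda_i * dow * (1 + A)``.
    plume_length, plume_width
        Downwind / crosswind kernel scales, km.
    """

    n_units: int = 108
    start: dt.date = dt.date(2007, 9, 1)
    end: dt.date = dt.date(2007, 11, 30)
    baseline_log_mean: float = float(np.log(0.47) - 0.25**2 / 2)
    baseline_log_sd: float = 0.25
    dow_effects: tuple = (1.05, 1.05, 1.0, 1.0, 0.95, 0.95, 1.05)
    fire_xy: tuple = (35.0, 35.0)
    wind_vectors: list = None
    hard_cutoffs: list = None
    plume_amplitude: float = 1.0
    plume_length: float = 300.0
    plume_width: float = 150.0
    exposed_dates: list = field(
        default_factory=lambda: [dt.date(2007, 10, 22) + dt.timedelta(days=k) for k in range(5)]
    )
    seed: int = 0

    def __post_init__(self):
        self.start = _as_date(self.start)
        self.end = _as_date(self.end)
        self.exposed_dates = [_as_date(d) for d in self.exposed_dates]
        if len(self.dow_effects) != 7 or any(e <= 0 for e in self.dow_effects):
            raise ValueError("dow_effects must be 7 positive multipliers")
        if self.plume_amplitude < 0:
            raise ValueError("plume_amplitude must be >= 0")
        for d in self.exposed_dates:
            if not (self.start <= d <= self.end):
                raise ValueError(f"exposed date {d} outside span {self.start}..{self.end}")
        n = len(self.exposed_dates)
        if self.wind_vectors is None:
            # offshore transport, reversing onshore on the last exposed day
            self.wind_vectors = [DEFAULT_WIND] * max(n - 1, 0) + (
                [(-DEFAULT_WIND[0], -DEFAULT_WIND[1])] if n else []
            )
            if self.hard_cutoffs is None:
                # the reversal day redistributes already-widespread smoke, so
                # it keeps the smooth kernel instead of the sharp upwind edge
                self.hard_cutoffs = [True] * max(n - 1, 0) + ([False] if n else [])
        if self.hard_cutoffs is None:
            self.hard_cutoffs = [True] * n
        if len(self.wind_vectors) != n or len(self.hard_cutoffs) != n:
            raise ValueError("need one wind vector and cutoff flag per exposed date")


def default_scenario(**overrides) -> ScenarioConfig:
    """The standard simulated study period; keyword overrides applied on top."""
    return ScenarioConfig(**overrides)


def gen_geometry(
    n_units: int = 108,
    bbox_km: tuple = (0.0, 0.0, 60.0, 80.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate unit centroids and populations inside a planar bounding box.

    Returns a DataFrame with columns ``unit_id, x_km, y_km, population``.
    Coordinates are uniform in the box; populations lognormal, rounded up.
    Populations act only as optional sampling weights, mirroring an analysis
    of raw counts without a population offset.
    """
    if n_units < 4:
        raise ValueError("n_units must be >= 4")
    x0, y0, x1, y1 = map(float, bbox_km)
    if not (x1 > x0 and y1 > y0):
        raise ValueError("bbox must have positive area")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x0, x1, n_units)
    y = rng.uniform(y0, y1, n_units)
    pop = np.ceil(rng.lognormal(mean=9.5, sigma=1.0, size=n_units)).astype(int)
    ids = [f"Z{i:03d}" for i in range(n_units)]
    return pd.DataFrame({"unit_id": ids, "x_km": x, "y_km": y, "population": pop})


def plume_exposure(
    unit_xy: np.ndarray,
    fire_xy,
    wind_vector,
    amplitude: float,
    length: float,
    width: float,
    hard_cutoff: bool = True,
) -> np.ndarray:
    """Relative excess ``e >= 0`` from an anisotropic downwind plume kernel.

    ``e = A * exp(-s^2/(2 L^2) - t^2/(2 W^2))`` for downwind distance ``s``
    along the wind unit vector and crosswind offset ``t``; by default ``e = 0``
    for units strictly upwind (``s < 0``), creating the sharp downwind/upwind
    contrast of wind-driven smoke transport. ``hard_cutoff=False`` keeps the
    smooth Gaussian on both sides.
    """
    if amplitude <= 0 or length <= 0 or width <= 0:
        raise ValueError("amplitude, length, width must be > 0")
    w = np.asarray(wind_vector, dtype=float)
    norm = np.hypot(w[0], w[1])
    if norm == 0:
        raise ValueError("wind_vector must be nonzero")
    u = w / norm
    xy = np.atleast_2d(np.asarray(unit_xy, dtype=float))
    d = xy - np.asarray(fire_xy, dtype=float)
    s = d @ u
    t = d @ np.array([-u[1], u[0]])
    e = amplitude * np.exp(-(s**2) / (2 * length**2) - (t**2) / (2 * width**2))
    if hard_cutoff:
        e = np.where(s < 0, 0.0, e)
    return e if np.asarray(unit_xy).ndim == 2 else float(e[0])


def _exposure_by_date(geometry: pd.DataFrame, scenario: ScenarioConfig) -> dict:
    xy = geometry[["x_km", "y_km"]].to_numpy()
    out = {}
    for d, w, hard in zip(scenario.exposed_dates, scenario.wind_vectors, scenario.hard_cutoffs):
        if scenario.plume_amplitude == 0:
            out[d] = np.zeros(len(geometry))
        else:
            out[d] = plume_exposure(
                xy, scenario.fire_xy, w, scenario.plume_amplitude,
                scenario.plume_length, scenario.plume_width, hard_cutoff=hard,
            )
    return out


def gen_count_panel(
    geometry: pd.DataFrame,
    scenario: ScenarioConfig,
    lambdas: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the daily count panel and its ground truth.

    Returns ``(panel, truth)``: a long panel with one row per (unit, date) and
    columns ``unit_id, date, count``; and a truth frame with the per-unit
    baseline rate ``lam`` and, for exposed dates, the expected excess count
    ``true_excess = lambda_i * dow(d) * e_i(d)`` (zero elsewhere).

    ``lambdas`` overrides the lognormal baseline draw (e.g. to zero a unit).
    """
    ids = geometry["unit_id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise ValueError("geometry unit_ids must be unique")
    n = len(ids)
    rng = np.random.default_rng(scenario.seed)
    if lambdas is None:
        lam = rng.lognormal(scenario.baseline_log_mean, scenario.baseline_log_sd, n)
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.shape != (n,) or (lam < 0).any():
            raise ValueError("lambdas must be n_units nonnegative rates")
    dates = pd.date_range(scenario.start, scenario.end, freq="D").date
    expo = _exposure_by_date(geometry, scenario)
    dow = np.asarray(scenario.dow_effects, dtype=float)

    rows_unit, rows_date, rows_count = [], [], []
    truth_rows = []
    for d in dates:
        rate = lam * dow[d.weekday()]
        e = expo.get(d)
        if e is not None:
            excess_rate = rate * e
            rate = rate * (1.0 + e)
            for i in range(n):
                truth_rows.append((ids[i], d, excess_rate[i]))
        counts = rng.poisson(rate)
        rows_unit.extend(ids)
        rows_date.extend([d] * n)
        rows_count.extend(counts.tolist())
    panel = pd.DataFrame({"unit_id": rows_unit, "date": rows_date, "count": rows_count})
    truth = pd.DataFrame(truth_rows, columns=["unit_id", "date", "true_excess"])
    truth.attrs["lambdas"] = pd.Series(lam, index=ids)
    return panel, truth


def gen_gp_field(
    geometry: pd.DataFrame,
    beta0: float,
    sigma2: float,
    tau2: float,
    phi: float,
    seed: int = 0,
    size: int = 1,
) -> np.ndarray:
    """Draw from the two-stage spatial model ``Y = beta0 + W + eps``.

    ``W ~ N(0, sigma2 * H(phi))`` with spherical correlation ``H`` over the
    unit centroids and ``eps ~ N(0, tau2 * I)``. Returns an ``(n,)`` vector,
    or ``(size, n)`` when ``size > 1`` (independent replicates for
    Monte-Carlo covariance checks).
    """
    from wildfire_excess.variogram import spherical_correlation

    if sigma2 <= 0 or tau2 <= 0:
        raise ValueError("sigma2 and tau2 must be > 0")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    xy = geometry[["x_km", "y_km"]].to_numpy()
    n = len(xy)
    h = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    H = spherical_correlation(h, phi)
    rng = np.random.default_rng(seed)
    # jitter keeps the Cholesky stable for near-duplicate points
    L = np.linalg.cholesky(sigma2 * H + 1e-12 * np.eye(n))
    W = rng.standard_normal((size, n)) @ L.T
    eps = rng.standard_normal((size, n)) * np.sqrt(tau2)
    out = beta0 + W + eps
    return out[0] if size == 1 else out
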