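"""Matched-design contracts: control-day arithmetic, median contrasts, summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildfire_excess import (
    MissingDataError,
    StudyDesign,
    excess_count,
    excess_panel,
    mean_excess_for_mapping,
    period_summary,
    select_control_days,
)
from wildfire_excess.matched import aggregate_excess

from conftest import tiny_panel


class TestControlDays:
    def test_main_event_first_day(self):
        # Monday Oct 22 -> matched Mondays of the two weeks before and after
        assert select_control_days(dt.date(2007, 10, 22), 2) == [
            dt.date(2007, 10, 8),
            dt.date(2007, 10, 15),
            dt.date(2007, 10, 29),
            dt.date(2007, 11, 5),
        ]

    def test_main_event_last_day_hits_window_edge(self):
        assert select_control_days(dt.date(2007, 10, 26), 2) == [
            dt.date(2007, 10, 12),
            dt.date(2007, 10, 19),
            dt.date(2007, 11, 2),
            dt.date(2007, 11, 9),
        ]

    def test_single_week_window(self):
        d = dt.date(2003, 10, 26)
        assert select_control_days(d, 1) == [d - dt.timedelta(days=7), d + dt.timedelta(days=7)]

    @settings(derandomize=True, max_examples=200)
    @given(
        day=st.dates(min_value=dt.date(1990, 1, 1), max_value=dt.date(2030, 12, 31)),
        weeks=st.integers(min_value=1, max_value=6),
    )
    def test_controls_preserve_weekday_and_offsets(self, day, weeks):
        ctl = select_control_days(day, weeks)
        assert len(ctl) == 2 * weeks
        assert day not in ctl
        assert ctl == sorted(ctl)
        for c in ctl:
            assert c.weekday() == day.weekday()
            assert abs((c - day).days) % 7 == 0

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            select_control_days(dt.date(2007, 10, 22), 0)


def _one_unit_panel(exposed_count, controls, exposed="2007-10-22"):
    days = select_control_days(dt.date.fromisoformat(exposed), 2)
    cells = {("z", exposed): exposed_count}
    cells.update({("z", d.isoformat()): c for d, c in zip(days, controls)})
    return tiny_panel(cells)


class TestExcessCount:
    @pytest.mark.parametrize(
        "exposed,controls,expected",
        [
            (5, [1, 2, 3, 4], 2.5),   # even-set median = mean of middle two
            (3, [3, 3, 3, 3], 0.0),
            (0, [0, 0, 1, 3], -0.5),  # negative excess is expected
        ],
    )
    def test_median_contrast(self, exposed, controls, expected):
        panel = _one_unit_panel(exposed, controls)
        design = StudyDesign([dt.date(2007, 10, 22)])
        assert excess_count("z", "2007-10-22", panel, design) == expected

    def test_matches_brute_force_median_on_random_sets(self):
        rng = np.random.default_rng(3)
        design = StudyDesign([dt.date(2007, 10, 22)])
        for _ in range(50):
            controls = rng.integers(0, 10, 4).tolist()
            exposed = int(rng.integers(0, 10))
            panel = _one_unit_panel(exposed, controls)
            s = sorted(controls)
            brute = exposed - (s[1] + s[2]) / 2
            assert excess_count("z", "2007-10-22", panel, design) == brute

    def test_strict_mode_names_missing_cells(self):
        panel = _one_unit_panel(5, [1, 2, 3, 4])
        panel = panel[panel["date"] != dt.date(2007, 10, 8)]
        design = StudyDesign([dt.date(2007, 10, 22)])
        with pytest.raises(MissingDataError) as err:
            excess_count("z", "2007-10-22", panel, design, strict=True)
        assert ("z", dt.date(2007, 10, 8)) in err.value.cells
        # default mode treats the absent cell as an implicit zero count:
        # controls become {0, 2, 3, 4} with median 2.5
        assert excess_count("z", "2007-10-22", panel, design) == 5 - 2.5


class TestExcessPanel:
    def test_constant_counts_give_zero_excess(self):
        dates = pd.date_range("2007-09-24", "2007-11-09").date
        panel = tiny_panel({(u, d.isoformat()): 2 for u in "ab" for d in dates})
        design = StudyDesign([dt.date(2007, 10, 22), dt.date(2007, 10, 23)])
        exc = excess_panel(panel, design)
        assert (exc["excess"] == 0).all()
        assert period_summary(exc)["percent_excess"] == 0.0

    def test_single_cell_arithmetic(self):
        panel = _one_unit_panel(5, [1, 2, 3, 4])
        exc = excess_panel(panel, StudyDesign([dt.date(2007, 10, 22)]))
        s = period_summary(exc)
        assert s["total_excess"] == 2.5
        assert s["total_count"] == 5
        assert s["percent_excess"] == 50.0

    def test_additivity_and_reorder_invariance(self, fire_run):
        _, _, _, exc = fire_run
        per_day = exc.groupby("date")["excess"].sum()
        assert per_day.sum() == pytest.approx(exc["excess"].sum())
        shuffled = exc.sample(frac=1, random_state=0)
        shuffled.attrs.update(exc.attrs)
        assert period_summary(shuffled)["total_excess"] == pytest.approx(
            period_summary(exc)["total_excess"]
        )
        # sum/mean exchange: n_units * mean-of-unit-means * n_days = total
        unit_means = mean_excess_for_mapping(exc)
        n_days = exc["date"].nunique()
        assert len(unit_means) * unit_means.mean() * n_days == pytest.approx(
            exc["excess"].sum()
        )

    def test_downwind_units_carry_the_signal(self, geometry108, fire_run):
        sc, _, truth, exc = fire_run
        unit_means = mean_excess_for_mapping(exc).reindex(geometry108["unit_id"])
        xy = geometry108[["x_km", "y_km"]].to_numpy()
        downwind = (xy[:, 0] - sc.fire_xy[0]) + (xy[:, 1] - sc.fire_xy[1]) < 0
        assert unit_means.mean() > 0
        assert unit_means[downwind].mean() > unit_means[~downwind].mean()
        # ground truth agrees on the ordering
        t = truth.groupby("unit_id")["true_excess"].mean().reindex(geometry108["unit_id"])
        assert t[downwind].mean() > t[~downwind].mean()

    def test_aggregate_is_five_day_sum(self, fire_run):
        _, _, _, exc = fire_run
        agg = aggregate_excess(exc)
        assert agg.sum() == pytest.approx(exc["excess"].sum())


class TestPeriodSummary:
    def test_rounding_half_away_from_zero(self):
        dates = [dt.date(2007, 10, 22)]
        exc = pd.DataFrame({"unit_id": ["a"], "date": dates, "excess": [29.5]})
        s = period_summary(exc, total_count=100)
        assert s["percent_excess"] == 29.5
        assert s["percent_excess_reported"] == 30

    def test_zero_total_count_is_an_error(self):
        exc = pd.DataFrame(
            {"unit_id": ["a"], "date": [dt.date(2007, 10, 22)], "excess": [1.0]}
        )
        with pytest.raises(ZeroDivisionError):
            period_summary(exc, total_count=0)

    def test_null_scenario_excess_matches_median_bias_oracle(self, geometry108):
        # with no plume the excess is NOT mean-zero: the median of four
        # low-count Poisson controls sits below the Poisson mean (skewness),
        # so E[excess] = lambda - E[median4(Poisson(lambda))] > 0. Check the
        # panel against a direct Monte-Carlo evaluation of that bias.
        from wildfire_excess import ScenarioConfig, gen_count_panel

        rng = np.random.default_rng(99)
        means, oracles = [], []
        for seed in range(10):
            sc = ScenarioConfig(seed=seed, plume_amplitude=0.0)
            panel, truth = gen_count_panel(geometry108, sc)
            exc = excess_panel(panel, StudyDesign(sc.exposed_dates))
            means.append(exc["excess"].mean())
            lam = truth.attrs["lambdas"].to_numpy()
            draws = rng.poisson(lam, size=(4000, 4, len(lam)))
            med4 = np.median(draws, axis=1)
            oracles.append(np.mean(lam[None, :] - med4))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(np.mean(oracles), abs=3 * se + 0.01)
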