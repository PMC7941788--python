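import numpy as np
import pandas as pd
import pytest

from wildfire_excess import ScenarioConfig, build_weights, gen_count_panel, gen_geometry


@pytest.fixture(scope="session")
def geometry108():
    return gen_geometry(108, seed=1)


@pytest.fixture(scope="session")
def weights8(geometry108):
    return build_weights(geometry108, k=8)


@pytest.fixture(scope="session")
def fire_run(geometry108):
    """One default-scenario simulation with its excess panel and ground truth."""
    from wildfire_excess import StudyDesign, excess_panel

    sc = ScenarioConfig(seed=7)
    panel, truth = gen_count_panel(geometry108, sc)
    exc = excess_panel(panel, StudyDesign(sc.exposed_dates, label="fire"))
    return sc, panel, truth, exc


def tiny_panel(counts_by_unit_date):
    """Build a long panel from {(unit, iso_date): count}."""
    import datetime as dt

    rows = [
        (u, dt.date.fromisoformat(d), c) for (u, d), c in counts_by_unit_date.items()
    ]
    return pd.DataFrame(rows, columns=["unit_id", "date", "count"])
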