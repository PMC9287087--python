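import numpy as np
import pandas as pd
import pytest

from enercomp.core_data import (
    CONTROL,
    EXCLOSURE,
    CaptureRecord,
    Month,
    PlotTable,
    SpeciesRegistry,
    TimePeriodScheme,
)


@pytest.fixture(scope="session")
def registry() -> SpeciesRegistry:
    return SpeciesRegistry.default()


@pytest.fixture(scope="session")
def plots8() -> PlotTable:
    return PlotTable(
        {**{i: CONTROL for i in range(1, 5)}, **{i: EXCLOSURE for i in range(5, 9)}}
    )


@pytest.fixture(scope="session")
def short_scheme() -> TimePeriodScheme:
    """Three 12-month periods for fast end-to-end runs."""
    return TimePeriodScheme(
        (
            ("P1", Month(1988, 2), Month(1989, 1)),
            ("P2", Month(1989, 2), Month(1990, 1)),
            ("P3", Month(1990, 2), Month(1991, 1)),
        )
    )


@pytest.fixture(scope="session")
def recovery_scheme() -> TimePeriodScheme:
    """Three 60-month periods for parameter-recovery experiments."""
    return TimePeriodScheme(
        (
            ("P1", Month(1988, 2), Month(1993, 1)),
            ("P2", Month(1993, 2), Month(1998, 1)),
            ("P3", Month(1998, 2), Month(2003, 1)),
        )
    )


def record(period, ym, plot, species, mass, **kw) -> CaptureRecord:
    return CaptureRecord(
        period_id=period,
        census_date=Month(*ym),
        plot_id=plot,
        species_code=species,
        mass_g=mass,
        **kw,
    )


@pytest.fixture
def toy_treatment_series() -> pd.DataFrame:
    """Hand-sized treatment series: one period, easy numbers."""
    return pd.DataFrame(
        [
            {
                "period_id": 1, "year": 1988, "month": 2, "month_index": Month(1988, 2).index,
                "treatment": CONTROL,
                "Etot": 100.0, "KR": 40.0, "SG": 10.0, "CB": 2.0,
                "Btot": 500.0, "B_KR": 300.0, "B_SG": 100.0, "B_CB": 20.0,
                "n_plots_censused": 4,
            },
            {
                "period_id": 1, "year": 1988, "month": 2, "month_index": Month(1988, 2).index,
                "treatment": EXCLOSURE,
                "Etot": 71.0, "KR": 0.0, "SG": 30.0, "CB": 15.0,
                "Btot": 350.0, "B_KR": 0.0, "B_SG": 200.0, "B_CB": 100.0,
                "n_plots_censused": 4,
            },
        ]
    )


def make_series(values, month_start=0, valid=None, kind="compensation"):
    """Build a MetricSeries frame from raw values for metric-level tests."""
    n = len(values)
    valid = [True] * n if valid is None else valid
    df = pd.DataFrame(
        {
            "period_id": np.arange(1, n + 1),
            "month_index": np.arange(month_start, month_start + n),
            "value": np.asarray(values, dtype=float),
            "valid": valid,
            "reason": ["" if v else "zero denominator" for v in valid],
        }
    )
    df.attrs["metric_kind"] = kind
    df.attrs["basis"] = "energy"
    return df
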