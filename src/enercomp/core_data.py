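"""Data model and ingestion for monthly capture records.

Dates are handled at month resolution: census bouts are monthly and the
analysis time periods are delimited by months. A day-of-month column is read
if present but never used for period assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: species-code sentinel marking a trapped plot that yielded no captures
NO_CAPTURE_CODE = "NONE"

CONTROL = "control"
EXCLOSURE = "exclosure"

DEFAULT_COLUMNS = {
    "period": "period",
    "year": "year",
    "month": "month",
    "plot": "plot",
    "species": "species",
    "mass": "wgt",
}


class Month(NamedTuple):
    """A calendar month. Ordered tuple comparison gives chronology."""

    year: int
    month: int

    @property
    def index(self) -> int:
        """Months since year 0 — differences give month gaps."""
        return self.year * 12 + self.month - 1

    @classmethod
    def from_index(cls, idx: int) -> "Month":
        return cls(idx // 12, idx % 12 + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.year:04d}-{self.month:02d}"


#: default study window
STUDY_START = Month(1988, 2)
STUDY_END = Month(2020, 1)


@dataclass(frozen=True)
class CaptureRecord:
    """One trapped individual (or a no-capture sentinel row)."""

    period_id: int
    census_date: Month
    plot_id: int
    species_code: str
    mass_g: float | None = None
    known_species: bool = True

    @property
    def is_sentinel(self) -> bool:
        return self.species_code == NO_CAPTURE_CODE


@dataclass(frozen=True)
class PlotTable:
    """Plot ids and their treatment assignment."""

    treatments: dict[int, str]

    def __post_init__(self) -> None:
        bad = set(self.treatments.values()) - {CONTROL, EXCLOSURE}
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")

    def plots(self, treatment: str) -> list[int]:
        return sorted(p for p, t in self.treatments.items() if t == treatment)

    @property
    def control_plots(self) -> list[int]:
        return self.plots(CONTROL)

    @property
    def exclosure_plots(self) -> list[int]:
        return self.plots(EXCLOSURE)

    def __len__(self) -> int:
        return len(self.treatments)

    @classmethod
    def from_csv(cls, path) -> "PlotTable":
        df = pd.read_csv(path)
        _require_columns(df, ["plot", "treatment"], str(path))
        return cls(dict(zip(df["plot"].astype(int), df["treatment"].str.strip())))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"plot": list(self.treatments), "treatment": list(self.treatments.values())}
        ).to_csv(path, index=False)


KANGAROO_RAT = "kangaroo_rat"
SMALL_GRANIVORE = "small_granivore"
OTHER = "other"
GUILDS = (KANGAROO_RAT, SMALL_GRANIVORE, OTHER)


@dataclass(frozen=True)
class SpeciesRegistry:
    """Species code -> guild and mean body mass (g).

    Guilds are disjoint: three kangaroo-rat species, twelve small
    granivores, and everything else in ``other``.
    """

    guilds: dict[str, str]
    mean_mass_g: dict[str, float]

    def __post_init__(self) -> None:
        bad = set(self.guilds.values()) - set(GUILDS)
        if bad:
            raise ValueError(f"unknown guilds: {sorted(bad)}")
        for code, m in self.mean_mass_g.items():
            if not m > 0:
                raise ValueError(f"nonpositive mean mass for {code!r}: {m}")

    def guild(self, species_code: str) -> str | None:
        return self.guilds.get(species_code)

    def known(self, species_code: str) -> bool:
        return species_code in self.guilds

    def codes(self, guild: str) -> list[str]:
        return sorted(c for c, g in self.guilds.items() if g == guild)

    @classmethod
    def from_csv(cls, path) -> "SpeciesRegistry":
        df = pd.read_csv(path)
        _require_columns(df, ["species", "guild", "mean_mass_g"], str(path))
        return cls(
            dict(zip(df["species"], df["guild"])),
            dict(zip(df["species"], df["mean_mass_g"].astype(float))),
        )

    @classmethod
    def default(cls) -> "SpeciesRegistry":
        from importlib.resources import files

        return cls.from_csv(files("enercomp").joinpath("fixtures/species.csv"))


def default_plot_table() -> PlotTable:
    from importlib.resources import files

    return PlotTable.from_csv(files("enercomp").joinpath("fixtures/plots.csv"))


@dataclass(frozen=True)
class TimePeriodScheme:
    """Ordered, contiguous, non-overlapping month ranges with labels."""

    periods: tuple[tuple[str, Month, Month], ...]

    def __post_init__(self) -> None:
        for label, start, end in self.periods:
            if start > end:
                raise ValueError(f"period {label!r}: start {start} after end {end}")
        for (_, _, e0), (l1, s1, _) in zip(self.periods, self.periods[1:]):
            if s1.index != e0.index + 1:
                raise ValueError(f"periods not contiguous at {l1!r}")

    @classmethod
    def default(cls) -> "TimePeriodScheme":
        return cls(
            (
                ("P1", Month(1988, 2), Month(1997, 6)),
                ("P2", Month(1997, 7), Month(2010, 1)),
                ("P3", Month(2010, 2), Month(2020, 1)),
            )
        )

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.periods]

    @property
    def start(self) -> Month:
        return self.periods[0][1]

    @property
    def end(self) -> Month:
        return self.periods[-1][2]

    def assign(self, census_date: Month) -> str:
        """Return the period label containing ``census_date``.

        Raises ``ValueError`` for dates outside the scheme's coverage.
        """
        for label, start, end in self.periods:
            if start <= census_date <= end:
                return label
        raise ValueError(f"date {census_date} outside period scheme coverage")


def assign_period(census_date: Month, scheme: TimePeriodScheme) -> str:
    """Functional alias for :meth:`TimePeriodScheme.assign`."""
    return scheme.assign(census_date)


def _require_columns(df: pd.DataFrame, needed: Sequence[str], source: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s): {', '.join(missing)}")


def read_captures(
    path,
    registry: SpeciesRegistry,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[CaptureRecord]:
    """Read a delimited capture table into :class:`CaptureRecord` rows.

    Parameters
    ----------
    path
        CSV (default) or TSV file with a header row.
    registry
        Used to flag unknown species codes; unknown rows are retained with
        ``known_species=False``.
    columns
        Overrides for the logical->physical column-name mapping
        (keys: period, year, month, plot, species, mass).
    sep
        Field delimiter; ``None`` sniffs comma vs tab from the header line.

    Rows with an unparseable date or plot are dropped; the number dropped is
    logged and raised as a ``ValueError`` summary if every row is malformed.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=[""])
    _require_columns(
        df, [cols[k] for k in ("period", "year", "month", "plot", "species")], str(path)
    )
    mass_col = cols["mass"] if cols["mass"] in df.columns else None

    records: list[CaptureRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = row._asdict()
        try:
            year = int(r[cols["year"]])
            month = int(r[cols["month"]])
            if not 1 <= month <= 12:
                raise ValueError(f"month out of range: {month}")
            period = int(r[cols["period"]])
            plot = int(r[cols["plot"]])
        except (ValueError, TypeError) as exc:
            bad_rows.append((i, str(exc)))
            continue
        code = str(r[cols["species"]]).strip()
        mass = None
        if mass_col is not None:
            raw = r[mass_col]
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                s = str(raw).strip()
                if s:
                    mass = float(s)
                    if mass <= 0:
                        bad_rows.append((i, f"nonpositive mass {mass}"))
                        continue
        records.append(
            CaptureRecord(
                period_id=period,
                census_date=Month(year, month),
                plot_id=plot,
                species_code=code,
                mass_g=mass,
                known_species=registry.known(code) or code == NO_CAPTURE_CODE,
            )
        )
    if bad_rows:
        logger.warning("read_captures: dropped %d malformed row(s)", len(bad_rows))
        if not records:
            raise ValueError(
                f"{path}: all {len(bad_rows)} rows malformed; first error: {bad_rows[0][1]}"
            )
    n_unknown = sum(not r.known_species for r in records)
    if n_unknown:
        logger.warning("read_captures: %d record(s) with unknown species code", n_unknown)
    return records


def write_captures(records: Iterable[CaptureRecord], path) -> None:
    """Write records in the dialect :func:`read_captures` accepts (round-trip)."""
    rows = [
        {
            "period": r.period_id,
            "year": r.census_date.year,
            "month": r.census_date.month,
            "plot": r.plot_id,
            "species": r.species_code,
            "wgt": "" if r.mass_g is None else r.mass_g,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["period", "year", "month", "plot", "species", "wgt"]).to_csv(
        path, index=False
    )


def filter_window(
    records: Sequence[CaptureRecord], start: Month = STUDY_START, end: Month = STUDY_END
) -> list[CaptureRecord]:
    """Keep records with start <= census_date <= end, preserving order."""
    if start > end:
        raise ValueError(f"window start {start} after end {end}")
    return [r for r in records if start <= r.census_date <= end]


def filter_plots(records: Sequence[CaptureRecord], plots: PlotTable) -> list[CaptureRecord]:
    """Keep records from the selected plots only."""
    keep = set(plots.treatments)
    return [r for r in records if r.plot_id in keep]


def select_plots(
    candidates: PlotTable,
    n_per_treatment: int = 4,
    seed: int = 1988,
    override: Sequence[int] | None = None,
) -> PlotTable:
    """Select a balanced plot set: ``n_per_treatment`` plots per treatment.

    Controls are taken as-is when exactly ``n_per_treatment`` are available;
    any surplus (in either treatment) is resolved by a uniform draw without
    replacement seeded by ``seed``. An explicit ``override`` list bypasses
    randomness entirely.
    """
    if override is not None:
        missing = [p for p in override if p not in candidates.treatments]
        if missing:
            raise ValueError(f"override plots not in candidate table: {missing}")
        return PlotTable({p: candidates.treatments[p] for p in override})
    rng = np.random.default_rng(seed)
    chosen: dict[int, str] = {}
    for treatment in (CONTROL, EXCLOSURE):
        pool = candidates.plots(treatment)
        if len(pool) < n_per_treatment:
            raise ValueError(
                f"need {n_per_treatment} {treatment} plots, only {len(pool)} available"
            )
        if len(pool) == n_per_treatment:
            picked = pool
        else:
            picked = sorted(rng.choice(pool, size=n_per_treatment, replace=False).tolist())
        for p in picked:
            chosen[p] = treatment
    return PlotTable(chosen)


def detect_establishment(
    records: Sequence[CaptureRecord],
    species_code: str,
    exclosure_plots: Sequence[int],
) -> int | None:
    """First period in which ``species_code`` occurs on every exclosure plot.

    Returns the smallest ``period_id`` with >=1 capture of the species on
    each plot in ``exclosure_plots``, or ``None`` ("never").
    """
    plots_needed = set(exclosure_plots)
    if not plots_needed:
        raise ValueError("empty exclosure plot set")
    seen: dict[int, set[int]] = {}
    for r in records:
        if r.species_code == species_code and r.plot_id in plots_needed:
            seen.setdefault(r.period_id, set()).add(r.plot_id)
    hits = sorted(p for p, plots in seen.items() if plots == plots_needed)
    return hits[0] if hits else None


def impute_missing_masses(
    records: Sequence[CaptureRecord], registry: SpeciesRegistry
) -> list[CaptureRecord]:
    """Fill missing masses with the species mean from the loaded data.

    Falls back to the registry mean mass for species with no measured mass
    at all. Sentinel rows are passed through. The imputation count is logged.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in records:
        if r.mass_g is not None:
            sums[r.species_code] = sums.get(r.species_code, 0.0) + r.mass_g
            counts[r.species_code] = counts.get(r.species_code, 0) + 1
    means = {c: sums[c] / counts[c] for c in sums}

    out: list[CaptureRecord] = []
    n_imputed = 0
    for r in records:
        if r.mass_g is None and not r.is_sentinel:
            mass = means.get(r.species_code, registry.mean_mass_g.get(r.species_code))
            if mass is None:
                out.append(r)  # unknown species with no mass: left as-is, excluded later
                continue
            out.append(replace(r, mass_g=mass))
            n_imputed += 1
        else:
            out.append(r)
    if n_imputed:
        logger.info("imputed %d missing body mass value(s) with species means", n_imputed)
    return out
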