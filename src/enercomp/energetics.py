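"""Metabolic scaling and aggregation to treatment-level guild totals."""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    CONTROL,
    EXCLOSURE,
    KANGAROO_RAT,
    OTHER,
    SMALL_GRANIVORE,
    CaptureRecord,
    PlotTable,
    SpeciesRegistry,
)

logger = logging.getLogger(__name__)

METABOLIC_COEF = 5.69
METABOLIC_EXP = 0.75

#: default species code for the focal colonizer
DEFAULT_FOCAL_SPECIES = "PB"

ENERGY_COLUMNS = ["Etot", "KR", "SG", "CB"]
BIOMASS_COLUMNS = ["Btot", "B_KR", "B_SG", "B_CB"]


def metabolic_rate(mass_g):
    """Individual metabolic rate from body mass: ``5.69 * m**0.75``.

    Accepts scalars or arrays; units are arbitrary metabolic units (only
    ratios of aggregates are ever interpreted).
    """
    m = np.asarray(mass_g, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass_g must be positive")
    out = METABOLIC_COEF * m**METABOLIC_EXP
    return float(out) if np.isscalar(mass_g) else out


def _record_frame(
    records: Sequence[CaptureRecord],
    registry: SpeciesRegistry,
    focal_species: str,
) -> pd.DataFrame:
    """Flatten records to a frame; non-contributing rows get guild ``_none``.

    Sentinel, unknown-species and massless rows contribute no value but
    still mark their plot as censused in that period.
    """
    rows = []
    n_skipped = 0
    for r in records:
        if r.is_sentinel or not registry.known(r.species_code) or r.mass_g is None:
            if not r.is_sentinel:
                n_skipped += 1
            rows.append((r.period_id, r.census_date.index, r.plot_id, "_none", 1.0, False))
            continue
        rows.append(
            (
                r.period_id,
                r.census_date.index,
                r.plot_id,
                registry.guild(r.species_code),
                float(r.mass_g),
                r.species_code == focal_species,
            )
        )
    if n_skipped:
        logger.info("aggregate: %d record(s) excluded from guild sums", n_skipped)
    return pd.DataFrame(
        rows, columns=["period_id", "month_index", "plot_id", "guild", "mass", "is_focal"]
    )


def _plot_guild_sums(df: pd.DataFrame, transform: Callable) -> pd.DataFrame:
    """Per (period, plot): guild sums of ``transform(mass)``.

    The kernel shared by the energy and biomass bases — they differ only in
    the per-individual transform (metabolic rate vs identity).
    """
    df = df.copy()
    contributing = df["guild"] != "_none"
    values = np.zeros(len(df))
    if contributing.any():
        values[contributing.to_numpy()] = transform(df.loc[contributing, "mass"].to_numpy())
    df["value"] = values
    key = ["period_id", "plot_id"]
    wide = df.pivot_table(
        index=key, columns="guild", values="value", aggfunc="sum", fill_value=0.0
    )
    for g in (KANGAROO_RAT, SMALL_GRANIVORE, OTHER):
        if g not in wide.columns:
            wide[g] = 0.0
    wide = wide[[KANGAROO_RAT, SMALL_GRANIVORE, OTHER]]
    wide["focal"] = (
        df[df["is_focal"]].groupby(key)["value"].sum().reindex(wide.index, fill_value=0.0)
    )
    wide["month_index"] = df.groupby(key)["month_index"].first()
    return wide.reset_index()


def aggregate(
    records: Sequence[CaptureRecord],
    plots: PlotTable,
    registry: SpeciesRegistry,
    focal_species: str = DEFAULT_FOCAL_SPECIES,
    granivores_only: bool = False,
) -> pd.DataFrame:
    """Aggregate captures to treatment-level means per census period.

    For each (period, treatment): sum individual metabolic rates (and body
    masses) by guild within each plot, then average the per-plot sums over
    the treatment's *censused* plots. A plot is censused in a period if it
    has at least one row there (a no-capture sentinel row counts); censused
    plots with no captures contribute zeros, untrapped plots are excluded
    from the mean's denominator.

    Returns a tidy frame with one row per (period_id, treatment) and columns
    ``year, month, month_index, Etot, KR, SG, CB, Btot, B_KR, B_SG, B_CB,
    n_plots_censused``. ``granivores_only=True`` restricts the totals to the
    kangaroo-rat + small-granivore guilds (excludes ``other``).
    """
    records = [r for r in records if r.plot_id in plots.treatments]
    if not records:
        raise ValueError("no records on the selected plots")
    frame = _record_frame(records, registry, focal_species)
    energy = _plot_guild_sums(frame, metabolic_rate)
    biomass = _plot_guild_sums(frame, lambda m: m)

    treatment_of = plots.treatments
    out_rows = []
    for (period_id, month_index), e_grp in energy.groupby(["period_id", "month_index"]):
        b_grp = biomass[biomass["period_id"] == period_id]
        for treatment in (CONTROL, EXCLOSURE):
            e_t = e_grp[e_grp["plot_id"].map(treatment_of) == treatment]
            b_t = b_grp[b_grp["plot_id"].map(treatment_of) == treatment]
            n = len(e_t)
            if n == 0:
                logger.warning(
                    "period %d: no censused %s plots; row omitted", period_id, treatment
                )
                continue

            def _means(grp):
                kr = grp[KANGAROO_RAT].sum() / n
                sg = grp[SMALL_GRANIVORE].sum() / n
                other = grp[OTHER].sum() / n
                focal = grp["focal"].sum() / n
                total = kr + sg if granivores_only else kr + sg + other
                return total, kr, sg, focal

            etot, kr, sg, cb = _means(e_t)
            btot, b_kr, b_sg, b_cb = _means(b_t)
            mo = int(month_index)
            out_rows.append(
                {
                    "period_id": period_id,
                    "year": mo // 12,
                    "month": mo % 12 + 1,
                    "month_index": mo,
                    "treatment": treatment,
                    "Etot": etot,
                    "KR": kr,
                    "SG": sg,
                    "CB": cb,
                    "Btot": btot,
                    "B_KR": b_kr,
                    "B_SG": b_sg,
                    "B_CB": b_cb,
                    "n_plots_censused": n,
                }
            )
    ts = pd.DataFrame(out_rows).sort_values(["period_id", "treatment"]).reset_index(drop=True)
    return ts


def read_treatment_series(path) -> pd.DataFrame:
    """Read a cached treatment series written by :func:`write_treatment_series`."""
    return pd.read_csv(path)


def write_treatment_series(ts: pd.DataFrame, path) -> None:
    ts.to_csv(path, index=False)
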