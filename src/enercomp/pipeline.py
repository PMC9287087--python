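"""End-to-end orchestration: ingest -> energetics -> metrics -> inference.

Every stage is importable on its own; this module wires them together,
writes tidy output tables plus a run manifest, and renders the four-panel
summary figure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, core_data, energetics, inference, metrics
from .core_data import (
    CONTROL,
    EXCLOSURE,
    Month,
    PlotTable,
    SpeciesRegistry,
    TimePeriodScheme,
)
from .synthetic_data import ScenarioConfig, simulate

logger = logging.getLogger(__name__)

#: published period estimates (percent) for the archived study dataset,
#: used only by the optional `reproduce` comparison
REFERENCE_ESTIMATES_PCT = {
    "compensation": {"P1": 18.0, "P2": 58.0, "P3": 28.0},
    "total_ratio": {"P1": 30.0, "P2": 71.0, "P3": 50.0},
    "kr_control_proportion": {"P1": 92.0, "P2": 70.0, "P3": 70.0},
    "cb_exclosure_proportion": {"P2": 72.0, "P3": 26.0},
    "cb_control_proportion": {"P2": 11.0, "P3": 0.0},
}


@dataclass
class RunConfig:
    """Everything needed to rerun an analysis end to end."""

    captures: str | None = None
    plots: str | None = None
    species: str | None = None
    scenario: str | None = None
    window_start: Month = core_data.STUDY_START
    window_end: Month = core_data.STUDY_END
    scheme: TimePeriodScheme = field(default_factory=TimePeriodScheme.default)
    granivores_only: bool = False
    basis: str = "energy"  # energy | biomass | both
    plot_seed: int = 1988
    plot_override: tuple[int, ...] | None = None
    n_plots_per_treatment: int = 4
    focal_species: str = energetics.DEFAULT_FOCAL_SPECIES
    gls_method: str = "REML"
    adjust: str = "tukey"
    outdir: str = "enercomp_output"

    def __post_init__(self) -> None:
        if (self.scenario is not None) == (self.captures is not None):
            raise ValueError("provide exactly one of scenario or captures input")
        if self.basis not in ("energy", "biomass", "both"):
            raise ValueError(f"basis must be energy|biomass|both, got {self.basis!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_start"] = list(self.window_start)
        d["window_end"] = list(self.window_end)
        d["scheme"] = [
            {"label": l, "start": list(s), "end": list(e)} for l, s, e in self.scheme.periods
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["window_start"] = Month(*d["window_start"])
        d["window_end"] = Month(*d["window_end"])
        d["scheme"] = TimePeriodScheme(
            tuple((p["label"], Month(*p["start"]), Month(*p["end"])) for p in d["scheme"])
        )
        if d.get("plot_override") is not None:
            d["plot_override"] = tuple(d["plot_override"])
        return cls(**d)


@dataclass
class MetricAnalysis:
    series: pd.DataFrame
    fit: inference.ModelFit
    summary: inference.MarginalSummary
    design: inference.DesignSpec | None = None


@dataclass
class AnalysisResult:
    """Per-basis bundle of metric series, fits and marginal summaries."""

    basis: str
    treatment_series: pd.DataFrame
    compensation: MetricAnalysis
    total_ratio: MetricAnalysis
    kr_control_proportion: MetricAnalysis
    cb_proportion: MetricAnalysis  # two-factor: period + treatment

    def estimates_pct(self) -> dict[str, dict[str, float]]:
        """Period-level estimates on the percent scale, keyed like the
        reference table."""
        out: dict[str, dict[str, float]] = {}
        for key, ma in (
            ("compensation", self.compensation),
            ("total_ratio", self.total_ratio),
            ("kr_control_proportion", self.kr_control_proportion),
        ):
            m = ma.summary.means
            m = m[m["factor"] == "period"]
            out[key] = {r["level"]: 100.0 * r["estimate"] for _, r in m.iterrows()}
        # colonizer: period x treatment cells from the additive model
        out.update(self._cb_cells_pct())
        return out

    def _cb_cells_pct(self) -> dict[str, dict[str, float]]:
        """Back-transformed period x treatment cell estimates for the
        colonizer model (additive on the logit scale)."""
        from scipy.special import expit

        ma = self.cb_proportion
        fit = ma.fit
        design_levels = ma.summary.means
        periods = design_levels.loc[design_levels["factor"] == "period", "level"].tolist()
        out = {"cb_exclosure_proportion": {}, "cb_control_proportion": {}}
        spec = ma.design
        names = spec.matrix()[1]
        for per in periods:
            for treatment, key in ((EXCLOSURE, "cb_exclosure_proportion"),
                                   (CONTROL, "cb_control_proportion")):
                row = np.zeros(len(names))
                row[0] = 1.0
                for f, lev in (("period", per), ("treatment", treatment)):
                    for cand in spec.levels[f][1:]:
                        j = names.index(f"{f}[{cand}]")
                        if cand == lev:
                            row[j] = 1.0
                out[key][per] = 100.0 * float(expit(row @ fit.coefficients))
        return out


def _analyze_metric(series, scheme, method, adjust) -> MetricAnalysis:
    design = inference.DesignSpec.from_metric(series, scheme)
    fit = inference.fit_gls_car1(design, method=method)
    summary = inference.marginal_means(fit, design, adjust=adjust)
    return MetricAnalysis(metrics.label_periods(series, scheme), fit, summary, design)


def _analyze_proportion(series, scheme, adjust) -> MetricAnalysis:
    design = inference.DesignSpec.from_metric(series, scheme)
    fit = inference.fit_proportion_glm(design)
    summary = inference.marginal_means(fit, design, adjust=adjust)
    return MetricAnalysis(metrics.label_periods(series, scheme), fit, summary, design)


def analyze(
    ts: pd.DataFrame,
    scheme: TimePeriodScheme,
    basis: str = "energy",
    gls_method: str = "REML",
    adjust: str = "tukey",
    cb_periods: tuple[str, ...] | None = None,
) -> AnalysisResult:
    """Fit the four standard models to an aggregated treatment series.

    ``cb_periods`` restricts the colonizer proportion model; the default is
    every period after the first (the colonizer is absent initially).
    """
    comp = _analyze_metric(metrics.compensation(ts, basis), scheme, gls_method, adjust)
    ratio = _analyze_metric(metrics.total_ratio(ts, basis), scheme, gls_method, adjust)
    kr = _analyze_proportion(metrics.proportion(ts, "kr", "total", CONTROL, basis), scheme, adjust)

    if cb_periods is None:
        cb_periods = tuple(scheme.labels[1:])
    cb_series = {
        EXCLOSURE: metrics.proportion(ts, "cb", "total", EXCLOSURE, basis),
        CONTROL: metrics.proportion(ts, "cb", "total", CONTROL, basis),
    }
    cb_design = inference.DesignSpec.from_metric_pair(cb_series, scheme, periods=cb_periods)
    cb_fit = inference.fit_proportion_glm(cb_design)
    cb_summary = inference.marginal_means(cb_fit, cb_design, adjust=adjust)
    cb = MetricAnalysis(
        metrics.label_periods(cb_series[EXCLOSURE], scheme), cb_fit, cb_summary, cb_design
    )

    return AnalysisResult(
        basis=basis,
        treatment_series=ts,
        compensation=comp,
        total_ratio=ratio,
        kr_control_proportion=kr,
        cb_proportion=cb,
    )


def load_records(config: RunConfig):
    """Load (or simulate) records plus plot table and registry."""
    if config.scenario is not None:
        scenario = ScenarioConfig.from_yaml(config.scenario)
        registry = (
            SpeciesRegistry.from_csv(config.species)
            if config.species
            else SpeciesRegistry.default()
        )
        records, _ = simulate(scenario, registry=registry)
        plot_ids = sorted({r.plot_id for r in records})
        n = len(plot_ids) // 2
        plots = PlotTable(
            {
                **{p: CONTROL for p in plot_ids[:n]},
                **{p: EXCLOSURE for p in plot_ids[n:]},
            }
        )
        return records, plots, registry
    registry = (
        SpeciesRegistry.from_csv(config.species)
        if config.species
        else SpeciesRegistry.default()
    )
    candidates = (
        PlotTable.from_csv(config.plots) if config.plots else core_data.default_plot_table()
    )
    plots = core_data.select_plots(
        candidates,
        n_per_treatment=config.n_plots_per_treatment,
        seed=config.plot_seed,
        override=config.plot_override,
    )
    records = core_data.read_captures(config.captures, registry)
    return records, plots, registry


def run(config: RunConfig) -> dict[str, AnalysisResult]:
    """Execute the full analysis and write the report bundle to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        records, plots, registry = load_records(config)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc

    records = core_data.filter_window(records, config.window_start, config.window_end)
    records = core_data.filter_plots(records, plots)
    records = core_data.impute_missing_masses(records, registry)

    try:
        ts = energetics.aggregate(
            records, plots, registry,
            focal_species=config.focal_species,
            granivores_only=config.granivores_only,
        )
    except Exception as exc:
        raise RuntimeError(f"[energetics] {exc}") from exc
    energetics.write_treatment_series(ts, outdir / "treatment_series.csv")

    bases = ["energy", "biomass"] if config.basis == "both" else [config.basis]
    results: dict[str, AnalysisResult] = {}
    for basis in bases:
        try:
            res = analyze(
                ts, config.scheme, basis=basis,
                gls_method=config.gls_method, adjust=config.adjust,
            )
        except Exception as exc:
            raise RuntimeError(f"[inference:{basis}] {exc}") from exc
        results[basis] = res
        _write_result(res, outdir, basis, config)

    _write_manifest(config, outdir)
    try:
        render_figure(results[bases[0]], config.scheme, outdir / "figure1.png")
    except Exception as exc:  # plotting must never sink the analysis
        logger.warning("[plot] figure rendering failed: %s", exc)
    return results


def _write_result(res: AnalysisResult, outdir: Path, basis: str, config: RunConfig) -> None:
    for name, ma in (
        ("compensation", res.compensation),
        ("total_ratio", res.total_ratio),
        ("kr_control_proportion", res.kr_control_proportion),
        ("cb_proportion", res.cb_proportion),
    ):
        stem = f"{name}_{basis}"
        metrics.write_metric_series(ma.series, outdir / f"{stem}_series.csv")
        ma.summary.means.to_csv(outdir / f"{stem}_means.csv", index=False)
        ma.summary.contrasts.to_csv(outdir / f"{stem}_contrasts.csv", index=False)
        fit = ma.fit
        pd.DataFrame(
            [
                {
                    "family": fit.family,
                    "method": fit.method,
                    "phi": fit.phi,
                    "sigma2": fit.sigma2,
                    "dispersion": fit.dispersion,
                    "loglik": fit.loglik,
                    "n": fit.n,
                    "df_residual": fit.df_residual,
                    "flags": ";".join(fit.flags),
                }
            ]
        ).to_csv(outdir / f"{stem}_fit.csv", index=False)


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    cfg = config.to_dict()
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def render_figure(res: AnalysisResult, scheme: TimePeriodScheme, path) -> None:
    """Four-panel summary figure: series lines plus period-mean bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(9, 12), sharex=True)
    boundaries = [s.index for _, s, _ in scheme.periods[1:]]

    def _months(series):
        return series["month_index"] / 12.0

    def _bands(ax, ma, factor="period"):
        m = ma.summary.means
        m = m[m["factor"] == factor]
        for _, row in m.iterrows():
            for label, start, end in scheme.periods:
                if label == row["level"]:
                    x = [start.index / 12.0, end.index / 12.0]
                    ax.fill_between(x, row["lower"], row["upper"], alpha=0.25)
                    ax.plot(x, [row["estimate"]] * 2, lw=2)

    ax = axes[0]
    s = res.total_ratio.series
    ax.plot(_months(s[s["valid"]]), s.loc[s["valid"], "value"], lw=0.8)
    _bands(ax, res.total_ratio)
    ax.set_ylabel("total ratio (E/C)")

    ax = axes[1]
    ma6 = metrics.moving_average(res.compensation.series, 6)
    ax.plot(_months(ma6[ma6["valid"]]), ma6.loc[ma6["valid"], "value"], lw=0.8)
    _bands(ax, res.compensation)
    ax.set_ylabel("compensation (6-mo MA)")

    ax = axes[2]
    s = res.kr_control_proportion.series
    ax.plot(_months(s[s["valid"]]), s.loc[s["valid"], "value"], lw=0.8)
    _bands(ax, res.kr_control_proportion)
    ax.set_ylabel("KR share, control")

    ax = axes[3]
    s = res.cb_proportion.series
    ax.plot(_months(s[s["valid"]]), s.loc[s["valid"], "value"], lw=0.8)
    ax.set_ylabel("colonizer share")
    ax.set_xlabel("year")

    for ax in axes:
        for b in boundaries:
            ax.axvline(b / 12.0, ls=":", color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def reproduce(data_dir, config: RunConfig | None = None) -> pd.DataFrame:
    """Run the pipeline on an archived-data directory and compare the
    period estimates with the published values (percent scale).

    Expects ``captures.csv`` (and optionally ``plots.csv``, ``species.csv``)
    inside ``data_dir``.
    """
    data_dir = Path(data_dir)
    captures = data_dir / "captures.csv"
    if not captures.exists():
        raise FileNotFoundError(
            f"expected {captures} (plus optional plots.csv, species.csv) in {data_dir}"
        )
    cfg = config or RunConfig(captures=str(captures), outdir=str(data_dir / "reproduction"))
    cfg = dataclasses.replace(
        cfg,
        captures=str(captures),
        scenario=None,
        plots=str(data_dir / "plots.csv") if (data_dir / "plots.csv").exists() else None,
        species=str(data_dir / "species.csv") if (data_dir / "species.csv").exists() else None,
    )
    results = run(cfg)
    est = results[cfg.basis if cfg.basis != "both" else "energy"].estimates_pct()
    rows = []
    for metric, ref_by_period in REFERENCE_ESTIMATES_PCT.items():
        for period, ref in ref_by_period.items():
            got = est.get(metric, {}).get(period)
            rows.append(
                {
                    "metric": metric,
                    "period": period,
                    "estimate_pct": got,
                    "reference_pct": ref,
                    "abs_diff": None if got is None else abs(got - ref),
                }
            )
    return pd.DataFrame(rows)
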