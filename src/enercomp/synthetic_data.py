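"""Scenario-driven capture-record generator with closed-form ground truth.

The generator targets the statistical structure the analysis assumes — not
rodent demography. Per census month and plot, guild-level energy targets
are drawn as period means perturbed by temporally autocorrelated lognormal
plot noise, then converted to individual captures by drawing body masses
from the guild's species pool until the accumulated metabolic rate best
matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .core_data import (
    CONTROL,
    EXCLOSURE,
    KANGAROO_RAT,
    NO_CAPTURE_CODE,
    SMALL_GRANIVORE,
    OTHER,
    CaptureRecord,
    Month,
    PlotTable,
    SpeciesRegistry,
    TimePeriodScheme,
)
from .energetics import DEFAULT_FOCAL_SPECIES, metabolic_rate

SCHEMA_VERSION = 1


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic removal-experiment community.

    Per-period parameters (one entry per period of ``scheme``):

    * ``kr_control_share`` (q): kangaroo-rat share of control-plot energy.
    * ``compensation`` (c): fraction of the removed kangaroo-rat energy
      taken up by small granivores on exclosures.
    * ``cb_exclosure_share`` / ``cb_control_share``: the focal colonizer's
      share of that treatment's *total* energy.

    All defaults are scenario inputs, not estimates.
    """

    n_plots_per_treatment: int = 4
    scheme: TimePeriodScheme = field(default_factory=TimePeriodScheme.default)
    kr_control_share: tuple[float, ...] = (0.92, 0.70, 0.70)
    compensation: tuple[float, ...] = (0.18, 0.58, 0.28)
    cb_exclosure_share: tuple[float, ...] = (0.0, 0.72, 0.26)
    cb_control_share: tuple[float, ...] = (0.0, 0.11, 0.005)
    other_share: float = 0.05
    total_control_energy: float = 2500.0
    noise_sd: float = 0.2
    noise_phi: float = 0.3
    mass_sd_log: float = 0.1
    missed_census_prob: float = 0.0
    colonizer_species: str = DEFAULT_FOCAL_SPECIES
    colonizer_event: Month | None = Month(1996, 7)
    quantization: str = "closest"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.scheme.periods)
        for name in (
            "kr_control_share",
            "compensation",
            "cb_exclosure_share",
            "cb_control_share",
        ):
            vals = getattr(self, name)
            if len(vals) != k:
                raise ValueError(f"{name} needs {k} entries, got {len(vals)}")
        for q in self.kr_control_share:
            if not 0 <= q <= 1:
                raise ValueError(f"kr_control_share out of [0,1]: {q}")
        if not 0 <= self.noise_phi < 1:
            raise ValueError("noise_phi must be in [0, 1)")
        for i, (q, cbc) in enumerate(zip(self.kr_control_share, self.cb_control_share)):
            sg_c = 1.0 - q - self.other_share
            if sg_c < -1e-12:
                raise ValueError(f"period {i}: shares sum beyond 1 (q + other > 1)")
            if cbc > sg_c + 1e-12:
                raise ValueError(f"period {i}: colonizer control share exceeds SG share")
        if self.quantization not in ("closest", "poisson"):
            raise ValueError(f"unknown quantization rule {self.quantization!r}")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["scheme"] = [
            {"label": lbl, "start": [s.year, s.month], "end": [e.year, e.month]}
            for lbl, s, e in self.scheme.periods
        ]
        if self.colonizer_event is not None:
            d["colonizer_event"] = [self.colonizer_event.year, self.colonizer_event.month]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        version = d.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported scenario schema version: {version}")
        d["scheme"] = TimePeriodScheme(
            tuple(
                (p["label"], Month(*p["start"]), Month(*p["end"]))
                for p in d["scheme"]
            )
        )
        if d.get("colonizer_event") is not None:
            d["colonizer_event"] = Month(*d["colonizer_event"])
        for name in (
            "kr_control_share",
            "compensation",
            "cb_exclosure_share",
            "cb_control_share",
        ):
            d[name] = tuple(d[name])
        return cls(**d)


def ground_truth(config: ScenarioConfig) -> "pd.DataFrame":
    """Closed-form per-period truths implied by a scenario.

    total ratio = 1 - q(1 - c); control composition and colonizer shares
    are direct inputs.
    """
    import pandas as pd

    rows = []
    for i, label in enumerate(config.scheme.labels):
        q = config.kr_control_share[i]
        c = config.compensation[i]
        rows.append(
            {
                "period_label": label,
                "compensation": c,
                "total_ratio": 1.0 - q * (1.0 - c),
                "kr_control_proportion": q,
                "cb_exclosure_proportion": config.cb_exclosure_share[i],
                "cb_control_proportion": config.cb_control_share[i],
            }
        )
    return pd.DataFrame(rows)


def _draw_individuals(target, codes, weights, means, sd_log, rng, rule):
    """Convert a guild energy target to (species, mass) individual draws.

    "closest": accumulate until adding one more individual would overshoot,
    keeping the last individual iff it brings the running total closer to
    the target. "poisson": expected count from mean individual energy, then
    a Poisson draw.
    """
    if target <= 0:
        return []
    mean_rates = metabolic_rate(means)
    mean_rate = float(np.dot(weights, mean_rates))

    def _batch(size):
        ks = rng.choice(len(codes), size=size, p=weights)
        ms = means[ks] * np.exp(sd_log * rng.standard_normal(size) - 0.5 * sd_log**2)
        return ks, ms

    if rule == "poisson":
        lam = target / mean_rate
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            return []
        ks, ms = _batch(n)
        return [(codes[k], m) for k, m in zip(ks, ms)]

    out: list[tuple[str, float]] = []
    total = 0.0
    while True:
        size = max(8, int((target - total) / mean_rate * 1.5) + 4)
        ks, ms = _batch(size)
        totals = total + np.cumsum(metabolic_rate(ms))
        over = np.flatnonzero(totals >= target)
        if len(over) == 0:
            out.extend(zip((codes[k] for k in ks), ms))
            total = float(totals[-1])
            continue
        i = int(over[0])
        out.extend(zip((codes[k] for k in ks[:i]), ms[:i]))
        prev = total if i == 0 else float(totals[i - 1])
        # include the overshooting individual iff it lands strictly closer
        if totals[i] - target < target - prev:
            out.append((codes[ks[i]], float(ms[i])))
        return out


def _guild_pool(registry: SpeciesRegistry, guild: str, exclude: tuple[str, ...] = ()):
    codes = [c for c in registry.codes(guild) if c not in exclude]
    means = np.array([registry.mean_mass_g[c] for c in codes])
    # weight toward smaller-bodied species: equal weights are fine too, but
    # inverse-mass weighting gives more individuals and finer quantization
    w = 1.0 / means
    return codes, w / w.sum(), means


def simulate(
    config: ScenarioConfig,
    registry: SpeciesRegistry | None = None,
    plots: PlotTable | None = None,
) -> tuple[list[CaptureRecord], "pd.DataFrame"]:
    """Generate capture records for a scenario; returns (records, truth).

    Deterministic for a given seed. Plot-level noise is AR(1) on the log
    scale, independent across plots and guild channels.
    """
    import pandas as pd

    registry = registry or SpeciesRegistry.default()
    if plots is None:
        n = config.n_plots_per_treatment
        plots = PlotTable(
            {**{i: CONTROL for i in range(1, n + 1)},
             **{i: EXCLOSURE for i in range(n + 1, 2 * n + 1)}}
        )
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    months = [Month.from_index(i) for i in range(scheme.start.index, scheme.end.index + 1)]

    kr_pool = _guild_pool(registry, KANGAROO_RAT)
    sg_pool = _guild_pool(registry, SMALL_GRANIVORE, exclude=(config.colonizer_species,))
    other_pool = _guild_pool(registry, OTHER)
    cb_mean = np.array([registry.mean_mass_g[config.colonizer_species]])
    cb_pool = ([config.colonizer_species], np.array([1.0]), cb_mean)

    E0 = config.total_control_energy
    o = config.other_share
    plot_ids = sorted(plots.treatments)
    # AR(1) state per (plot, channel); channels: kr, sg, cb, other
    state = {(p, ch): rng.normal(0.0, config.noise_sd) for p in plot_ids
             for ch in ("kr", "sg", "cb", "other")}

    def step_noise(p, ch):
        phi = config.noise_phi
        prev = state[(p, ch)]
        new = phi * prev + np.sqrt(1 - phi**2) * rng.normal(0.0, config.noise_sd)
        state[(p, ch)] = new
        return np.exp(new - 0.5 * config.noise_sd**2)

    records: list[CaptureRecord] = []
    period_id = 0
    for mo in months:
        period_id += 1
        if config.missed_census_prob > 0 and rng.random() < config.missed_census_prob:
            continue
        i = scheme.labels.index(scheme.assign(mo))
        q = config.kr_control_share[i]
        c = config.compensation[i]
        cb_e_share = config.cb_exclosure_share[i]
        cb_c_share = config.cb_control_share[i]
        if config.colonizer_event is None or mo < config.colonizer_event:
            cb_e_share = cb_c_share = 0.0
        sg_c = max(0.0, 1.0 - q - o)
        etot_e = 1.0 - q * (1.0 - c)  # exclosure total as fraction of E0
        targets_by_treatment = {
            CONTROL: {
                "kr": q * E0,
                "cb": cb_c_share * E0,
                "sg": max(0.0, sg_c - cb_c_share) * E0,
                "other": o * E0,
            },
            EXCLOSURE: {
                "kr": 0.0,
                "cb": cb_e_share * etot_e * E0,
                "sg": max(0.0, (sg_c + c * q) - cb_e_share * etot_e) * E0,
                "other": o * E0,
            },
        }
        for p in plot_ids:
            targets = targets_by_treatment[plots.treatments[p]]
            n_before = len(records)
            for ch, pool in (
                ("kr", kr_pool),
                ("sg", sg_pool),
                ("cb", cb_pool),
                ("other", other_pool),
            ):
                noise = step_noise(p, ch)  # advance AR state even at zero target
                target = targets[ch] * noise
                for code, mass in _draw_individuals(
                    target, *pool, config.mass_sd_log, rng, config.quantization
                ):
                    records.append(
                        CaptureRecord(
                            period_id=period_id,
                            census_date=mo,
                            plot_id=p,
                            species_code=code,
                            mass_g=float(mass),
                        )
                    )
            if len(records) == n_before:
                records.append(
                    CaptureRecord(
                        period_id=period_id,
                        census_date=mo,
                        plot_id=p,
                        species_code=NO_CAPTURE_CODE,
                        mass_g=None,
                    )
                )
    return records, ground_truth(config)
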