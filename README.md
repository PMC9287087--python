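# enercomp

Community-level energetics analysis for long-term rodent removal
experiments. Given monthly live-trapping capture records from paired
control and removal (exclosure) plots, the package estimates how much of
the energy freed by removing a dominant guild (kangaroo rats) is taken up
by the remaining small granivores, and how the total community energy flux
on removal plots compares with controls, across multi-year time periods.

Pipeline stages (one module each, all importable on their own):

- `enercomp.core_data` — capture-record data model, delimited-text reader,
  study-window filtering, balanced plot selection, guild registry, and the
  three-period time scheme (Feb 1988–Jun 1997 / Jul 1997–Jan 2010 /
  Feb 2010–Jan 2020 by default).
- `enercomp.energetics` — individual metabolic rate `b = 5.69 · m^0.75`
  (mass in grams) and aggregation to per-census-period, per-treatment guild
  totals (means over the treatment's censused plots), on both the energy
  and biomass bases via a shared kernel.
- `enercomp.metrics` — compensation `(SG_E − SG_C)/KR_C`, total energy
  ratio `Etot_E/Etot_C`, within-treatment proportional energy use, and a
  trailing 6-month moving average (plotting only).
- `enercomp.inference` — generalized least squares with continuous-time
  AR(1) errors (`corr = φ^Δt` within each time period, φ profiled by
  bounded scalar search, REML default), quasi-binomial logit GLMs for
  continuous proportions (IRLS with step-halving, Pearson dispersion),
  estimated marginal means with 95% t-intervals, and Tukey-adjusted
  pairwise contrasts. A minimal AIC comparison of independence vs CAR1 is
  included.
- `enercomp.synthetic_data` — scenario-driven capture-record generator
  with closed-form ground truth (per-period kangaroo-rat share q, true
  compensation c, colonizer shares; total ratio = 1 − q(1 − c)), lognormal
  body masses, AR(1) plot noise, and an energy-to-individuals quantization
  rule. Makes the entire pipeline testable offline.
- `enercomp.pipeline` / `enercomp.cli` — end-to-end orchestration, tidy
  CSV outputs, run manifest, four-panel summary figure.

## CLI

```sh
# generate a synthetic dataset (captures/plots/species/ground-truth CSVs)
enercomp simulate --seed 1 --out synthetic/

# full analysis: metric tables, model fits, marginal means, figure, manifest
enercomp run --captures synthetic/captures.csv --plots synthetic/plots.csv \
             --out analysis/

# or run directly from a scenario file
enercomp run --scenario synthetic/scenario.yml --out analysis/

# individual stages
enercomp metrics --captures synthetic/captures.csv --out metrics/
enercomp fit --series metrics/compensation.csv --family gls --out fit/
enercomp plot --captures synthetic/captures.csv --out figure1.png

# compare estimates on the archived field dataset with the published values
enercomp reproduce path/to/archived-data/
```

The `reproduce` subcommand expects a directory containing `captures.csv`
(columns `period,year,month,plot,species,wgt`; optional `plots.csv` and
`species.csv` overrides). The archived deposit is at
doi:10.5281/zenodo.5544361; export its capture table to that layout. This
path needs a one-time download and is entirely optional — everything else,
including the tests, runs offline.

## Conventions worth knowing

- Dates are month-resolution; period boundaries are inclusive months.
- A plot trapped in a period with no captures counts as a zero; an
  untrapped plot is excluded from that period's treatment mean. Input rows
  with the sentinel species code `NONE` mark trapped-but-empty plots.
- Missing body masses are imputed with the species mean from the loaded
  data (registry mean as fallback); imputations are logged.
- Total energy includes all rodent guilds by default; pass
  `granivores_only` (CLI `--granivores-only`) to restrict to granivores.
- The moving average is trailing, not centered.
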