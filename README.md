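# thermospectra

A temperature-dependent multi-species size-spectrum food-web model:
three interacting fish species over two background resource spectra,
with Arrhenius temperature scaling of physiological and resource rates,
Beverton-Holt recruitment, a calibration routine, and a warming/fishing
scenario pipeline.

Individuals are characterised by body weight on a shared logarithmic
grid.  Food-dependent growth and mortality emerge from log-normal
size-selective predation, a Holling type-II functional response, and an
allometric energy budget; the population dynamics follow a transport
equation in body weight solved with an implicit upwind scheme, coupled
to semi-chemostat resource dynamics.  Temperature enters through
exponential (Arrhenius) corrections of metabolism, maximum consumption,
search volume and background mortality (physiology pathway) and of the
resource regeneration rate and carrying capacity (resource pathway),
with scenario switches `none / physiology / resources / both` and
ensemble sampling of activation energies.

## Layout

| module | contents |
| --- | --- |
| `thermospectra.model_core` | domain types (`SpeciesParams`, `ResourceParams`, `WeightGrid`, `ModelState`, `InteractionMatrix`) and all per-step bioenergetic rate functions |
| `thermospectra.dynamics_engine` | implicit upwind fish step, semi-implicit resource step, `project`, `run_to_steady` |
| `thermospectra.thermal` | Arrhenius factors, scenario gating, activation-energy ensembles |
| `thermospectra.calibration` | maximum-recruitment fit to SSB targets (L-BFGS-B in log10 space), consumption tuning to growth targets, density-dependence diagnostics |
| `thermospectra.scenario_pipeline` | FMSY grid search, warming projections with no-warming baselines, constant temperature x fishing factorials, size/yield metrics |
| `thermospectra.synthetic_data` | archetype community and synthetic forcing/target generators (illustrative parameters, not any real stock's values) |
| `thermospectra.config` / `thermospectra.cli` | YAML schema and the `thermospectra` command-line interface |

## CLI

```sh
# synthetic forcing tables (temperature + fishing histories)
thermospectra simulate-data --seed 1 --out data/

# write a config for the default archetype community, then calibrate
python -c "
from thermospectra.config import dump_config
from thermospectra.synthetic_data import default_model
from thermospectra.thermal import ThermalConfig
from thermospectra.dynamics_engine import SolverConfig
dump_config(default_model(), ThermalConfig(), SolverConfig(), 'model.yaml')"
thermospectra calibrate --config model.yaml --targets targets.csv --out fit/

# FMSY per species, warming projection, constant T x F grid
thermospectra fmsy --config model.yaml --f-others 0.45,0.35,0.9 --out fmsy/
thermospectra project --config model.yaml --temperature data/temperature.csv \
    --fishing data/fishing.csv --n-draws 20 --out proj/
thermospectra grid --config model.yaml --fmsy-csv fmsy/fmsy.csv --out grid/
```

Each command writes CSV outputs plus a `run_log.json` with the seed,
config hash and convergence flags.

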