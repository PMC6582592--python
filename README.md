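# vegdyn

State-and-transition simulation of vegetation dynamics on large rasters.

Vegetation is discretized into a fine-grained set of states along three
axes — composition (bare / single-species dominance / mixtures of up to
four species), structure (dominant canopy height in 4 m bins), and
functioning (three leaf-area-index classes). A two-headed classifier
predicts, per 1 ha cell, (a) *when* the cell will leave its current state
within a 10-year horizon (11-way categorical: censored + years 1–10) and
(b) *which* state it will enter, from predictors covering the current
state, residence time, soil, a 10-year monthly climate window, species
shares in two neighbourhood tiers (8-neighbour and 300 m radius, as a
seed-input proxy), and distance to the landscape edge. Ecosystem
attributes (live carbon, Hill-number tree diversity) are linked
nonparametrically to (state × residence-time) classes and sampled during
simulation. The simulator advances annually: scheduled cells draw a
target state and reset residence time, all others age by one year.

Because real training data from a process-based simulator is large and
external, the package includes a **synthetic succession generator** with a
known semi-Markov ground-truth kernel (logistic residence-time hazards
with a temperature term; neighbourhood- and temperature-structured target
states). Every experiment — network training, parameter recovery,
stationary occupancy, gradient zonation — can therefore be checked
against closed-form oracles.

## Layout

| module | contents |
|---|---|
| `vegdyn.states` | state space: classifiers, `StateTable`, enumeration, CSV I/O |
| `vegdyn.synthetic` | truth kernels, trajectory simulation, example extraction, analytic stationary distribution |
| `vegdyn.transition` | feature schema, `ExampleSet`, NumPy MLP (`fit_dnn`), tabulated/kernel oracles, metrics |
| `vegdyn.attributes` | Hill diversity, (S × R) attribute database |
| `vegdyn.engine` | annual raster simulation, neighbourhood tiers, landscape summaries |
| `vegdyn.climate`, `vegdyn.rasters`, `vegdyn.config`, `vegdyn.cli`, `vegdyn.pipeline` | monthly climate driver, ESRI ASCII grids, YAML config, CLI, end-to-end demo |

## CLI

```bash
vegdyn --seed 1 demo                       # self-contained end-to-end run
vegdyn --config project.yaml synth         # landscape + climate + trajectories
vegdyn --config project.yaml extract       # training examples
vegdyn --config project.yaml --seed 1 train
vegdyn --config project.yaml simulate      # annual simulation with the model
vegdyn --config project.yaml evaluate
vegdyn --config project.yaml summarize     # S x R attribute statistics
```

A minimal `project.yaml`:

```yaml
kernel: {preset: eight_state}
synth: {rows: 40, cols: 40, years: 120, n_regions: 3, temperature_range: 2.0}
model: {hidden: [128, 128], epochs: 10, climate_encoding: decadal_means}
run: {years: 100, seed: 1}
```

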