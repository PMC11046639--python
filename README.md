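# flockinf

Collective motion from surprise-minimizing agents.

Each agent carries a small generative model of the average distance to
its neighbors within four visual sectors (60° each, covering −120°…+120°
relative to its heading; the rear is blind). States are represented in
generalized coordinates of motion (three belief orders, two observation
orders). Agents simultaneously

- **infer** the sector distances by generalized filtering (free-energy
  gradient descent on beliefs, including the order-shift flow),
- **act** by steering along the free-energy gradient with respect to
  their heading — precision-weighted first-order prediction errors times
  per-sector direction vectors, which is exactly an emergent
  attraction/repulsion social force with the switch at the preferred
  distance η, and
- optionally **learn** the sensory smoothness λz online by a slower
  free-energy descent ("plasticity").

Groups of such agents reproduce polarized, milling, and disordered
regimes, informed-subgroup target navigation, and perturbation-response
experiments with and without plasticity.

## Layout

| module | contents |
| --- | --- |
| `flockinf.generative_model` | `ModelParams`, `GeneralizedBelief`, drift, order-shift, temporal/amplitude precision construction |
| `flockinf.world` | true dynamics: sector geometry, hidden states, noisy observation, Euler–Maruyama stepping, trajectory records (CSV/JSON) |
| `flockinf.inference` | prediction errors, Laplace free energy, belief updates, λz plasticity |
| `flockinf.control` | sector vectors, heading derivative, heading update |
| `flockinf.metrics` | polarization, angular momentum, milling probability, fragmentation, turning response |
| `flockinf.experiments` | free-schooling sweeps, target navigation, perturbation protocol, stimulus construction |
| `flockinf.cli_io` | YAML config validation, deterministic fixtures, seed tree |
| `flockinf._fast` | numba kernel mirroring the reference numpy step (pinned by an exactness test) |

## CLI

Every subcommand takes `--config <yaml> --seed <int> --out <dir>`:

```sh
flockinf simulate --config examples/free_schooling.yaml --seed 1 --out runs/demo
flockinf sweep    --config examples/sweep.yaml    --seed 1 --out runs/sweep
flockinf navigate --config examples/navigate.yaml --seed 1 --out runs/nav
flockinf perturb  --config examples/perturb.yaml  --seed 1 --out runs/pert
```

Outputs: `trajectory.csv` (time, agent_id, x, y, vx, vy, …),
`summary.json` / `*_report.json` (order parameters, per-condition
statistics, config hash and seeds), `config_used.yaml`.

A minimal config:

```yaml
experiment: {protocol: simulate}
n_agents: 50
duration_s: 15.0
master_seed: 1
model:
  eta: 1.0        # preferred spacing
  lambda_z: 1.0   # believed sensory smoothness
```

Unknown keys are rejected; all omitted parameters take the documented
defaults in `ModelParams`.

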