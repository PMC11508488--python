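# habflow

Multi-objective timber-harvest scheduling for working forests that must
balance wildlife habitat against revenue. `habflow` is aimed at forest
planners and quantitative ecologists who need to ask: *given projected
stand growth under a menu of silvicultural regimes, which assignment of
regimes to stands keeps pulpwood yield, and habitat area for several
species with conflicting canopy preferences, inside per-period target
bands — and what do the resulting habitat patches look like on the map?*

## The model

The decision variable is a **schedule**: one management regime per forest
stand. Each objective is a **flow component** — a table of projected
output per (stand, regime, period), e.g. harvested pulpwood tons or
habitat acres. Habitat flows come from **habitat suitability indices
(HSI)**: a user equation over projected stand attributes (here basal area
BA in m²/ha, a canopy-openness proxy), optionally squashed through the
logistic function so HSI ∈ (0, 1); a stand counts its full acreage as
habitat in a period when HSI > threshold (default 0.7), else zero.

Targets are set with a model string (`"10,1000; 20,1000; 30,1000"`),
linearly interpolated across the horizon, with an allowable negative
deviation *thlo* and positive deviation *thhi* forming a per-period band
[target − thlo, target + thhi]. A schedule's badness is

E(S) = Σ_flows w · Σ_t ( max(0, lo_t − y_t, y_t − hi_t) / max(target_t, 1) )²

where y_t is the flow's period-t output under S. The search is
**Metropolis–Hastings**: pick a stand uniformly, reassign it to a
different admissible regime uniformly, accept with probability
min(1, exp(−ΔE/T)); the best-so-far schedule is returned. Sweeping target
levels over a grid (by default 5 HSI levels × 20 pulpwood steps = 100
runs) yields alternative solutions; per objective, the run maximizing the
mean per-period output is selected, and a deviation table reports each
solution's percent shortfall from the per-flow maximum. A spatial module
then aggregates each solution's habitat stands into patches — by shared
boundary ("terrestrial") or within a travel distance ("avian") — with
per-period patch summaries and geometric metrics.

Because real stand inventories are rarely shareable, a synthetic
generator supplies a Voronoi stand map and logistic growth-with-events
projections shaped like forest-growth-simulator output (default template:
505 stands, 17,774 acres, 10 regimes, 35 three-year periods).

## Worked example

Fifty synthetic stands, four flows, a 3 × 3 target grid, 2,000 sampler
iterations per run:

```python
import numpy as np
import habflow as hf
from habflow.experiment import SweepSpec, run_sweep, select_solutions
from habflow.objectives import FlowComponent
from habflow.scheduler import MHConfig

side = float(np.sqrt(50 * 35.2 * hf.ACRE_M2))
geoms, info = hf.generate_landscape(hf.LandscapeSpec(50, (0, 0, side, side), seed=1))
growth = hf.project_growth(info, hf.default_regimes(35), 35, seed=1)
for eq in hf.builtin_equations():
    growth = hf.hsi_calc(growth, eq)
flows = {n: hf.habitat_flow(growth, info, n, 0.7)
         for n in ("hsi_closed", "hsi_intermediate", "hsi_open")}
flows["pulp"] = hf.area_scaled_flow(growth, info, "pulp")
spec = SweepSpec(
    hsi_levels=[(1000.0 * k, 1000.0 * k) for k in (1, 3, 5)],
    pulp_steps=[(1000.0 * k, 5000.0 * k) for k in (1, 10, 20)],
    hsi_flow_names=("hsi_closed", "hsi_intermediate", "hsi_open"),
    pulp_flow_name="pulp",
    mh=MHConfig(iterations=2000, seed=1),
)
comps = [FlowComponent(n, flows[n], "10,1000; 20,1000; 30,1000", 1000, 1000)
         for n in flows]
traces = run_sweep(comps, growth, spec)
sol = select_solutions(traces, comps)
print(sol.mean_outputs.round(0)); print(sol.deviations)
```

prints

```
                    hsi_closed  hsi_intermediate  hsi_open    pulp
solution_1 (run 1)      1179.0             277.0     320.0  1446.0
solution_2 (run 3)       942.0             480.0     376.0  3595.0
solution_3 (run 7)      1086.0             298.0     402.0  1470.0
solution_4 (run 2)      1099.0             476.0     223.0  4215.0

                    hsi_closed  hsi_intermediate  hsi_open  pulp
solution_1 (run 1)         0.0             -42.3     -20.4 -65.7
solution_2 (run 3)       -20.1               0.0      -6.4 -14.7
solution_3 (run 7)        -7.9             -37.8       0.0 -65.1
solution_4 (run 2)        -6.7              -0.8     -44.5   0.0
```

Each row is the solution that maximizes one objective (mean acres per
period for the three habitat flows, tons for pulpwood); the second table
shows the cost each solution imposes on the other objectives — e.g.
maximizing closed-canopy habitat (solution 1) forfeits 65.7% of the
attainable pulpwood yield, the classic habitat/revenue trade-off.

The same workflow runs from the shell: `habflow simulate`, `convert`,
`hsi`, `schedule`, `sweep` (full pipeline from a YAML config), `select`,
`spatial`, and `plot`. See `docs/methods.md` for model details and
assumptions.

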