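# Methods

## Problem formulation

A landscape is a set of stands, each with an area in acres and a polygon
footprint in planar meter coordinates. A growth projection supplies, for
every stand × regime × period triple, the stand's attributes (basal area,
pulpwood yield per acre, anything else a growth model emits). A schedule
assigns exactly one regime to every stand; the planner's problem is to
find schedules whose per-period flow outputs stay inside target bands for
several simultaneous objectives.

Periods are 1-based integers 1..nperiods; the package is agnostic to
calendar length (the case-study template uses 35 three-year periods, 105
years). Units are carried as labels only — no conversion is performed
except the documented acre/square-meter constant (1 acre = 4046.8564224
m²) inside the synthetic generator, and the explicit per-acre → per-stand
scaling of yield flows (`area_scaled_flow`).

## Habitat suitability and habitat-area flows

An HSI equation maps attribute vectors to a raw score; with the logistic
option (the default) the final score is 1/(1+exp(−raw)) ∈ (0, 1).
Non-logistic outputs pass through unmodified and are range-checked only
when converted to a habitat flow. Three illustrative shapes are built in,
all functions of basal area alone:

| name | raw score | species archetype |
|---|---|---|
| closed | 0.25·(BA − 14) | closed-canopy associate, suitability rises with BA |
| intermediate | 2 − 0.08·(BA − 14)² | mid-canopy associate, peak at BA = 14 |
| open | −0.25·(BA − 14) | open-canopy associate, suitability falls with BA |

The coefficients were chosen once so the logistic HSI spans roughly
(0.05, 0.95) over BA ∈ [0, 28] m²/ha — the dynamic range the synthetic
growth model produces — and are fully overridable; the package contract
is the user-supplied-equation mechanism, not these constants. Real HSIs
would distinguish cover types, stand structure and more; a single
basal-area indicator cannot, and is meant for methodological work.

A stand × regime × period combination is habitat when HSI **strictly
exceeds** the threshold (default 0.7); it then contributes the stand's
entire acreage to the habitat-area flow, else zero. There is no partial
credit, so habitat flows take exactly two values per stand and are
pointwise anti-monotone in the threshold.

## Targets, bands and the deviation penalty

Model strings (`"period,target; period,target; …"`) give targets at
anchor periods; the full series is piecewise-linear between anchors and
constant outside them. (Whether the original scheduler interpolates
linearly or stepwise is not documented; linear was chosen so the band is
defined over every period.) The band at period t is
[target_t − thlo, target_t + thhi].

The energy of a schedule S is

E(S) = Σ_c w_c · Σ_t v_{c,t}²,  v_{c,t} = max(0, lo_t − y_t, y_t − hi_t) / max(target_t, 1)

Squaring gives smooth pressure toward the band; dividing by the target
makes flows measured in acres and flows measured in tons commensurable,
with a floor of 1 guarding zero targets. E = 0 iff every period of every
component is inside its band, and E is non-increasing in thlo and thhi.
Weights default to 1 (objectives unweighted) and are exposed.

## The Metropolis–Hastings sampler

Proposal: stand chosen uniformly among stands with ≥ 2 admissible
regimes, new regime uniform among the alternatives — symmetric, so the
Hastings ratio is 1 and acceptance is min(1, exp(−ΔE/T)). Defaults are
T₀ = 1 and no cooling (pure Metropolis); geometric cooling
(T_k = T₀·c^k) and a greedy flag (accept only ΔE ≤ 0, the T → 0⁺ limit)
are available. The run returns the **best schedule seen**, not the final
chain state, because solutions are judged by realized output rather than
by stationary sampling; with continued sampling the chain would emit an
open-ended stream of candidate schedules.

ΔE is computed incrementally from cached per-period flow sums (only the
reassigned stand's value vectors change); the test suite pins the
incremental path to full recomputation. All randomness flows from a
single integer seed through `numpy.random.default_rng`, so runs are
bit-reproducible. Initialization is a seeded uniform regime draw per
stand unless a schedule is supplied.

No optimality is claimed: the sampler finds schedules that meet targets
within thresholds, not certified optima. On instances small enough to
enumerate (≤ 4 stands × ≤ 3 regimes) it recovers the exhaustive minimum
within 10,000 iterations essentially always (measured 100/100).

## Target sweeps and solution selection

A sweep is the outer product of HSI levels (applied identically to all
HSI flows) and pulpwood steps, thlo fixed throughout. The template grid
mirrors the motivating design: 20 pulpwood steps (+1,000 tons target,
+5,000 tons thhi per step) × 5 HSI levels (+1,000 acres target and thhi
per level, starting at 1,000/1,000), targets anchored at periods 10, 20,
30, thlo = 1,000, 10,000 iterations per run. Run k uses seed base+k, so
sweeps are reproducible run-by-run with no cross-run state.

Per flow component, the run with maximal mean per-period output wins
(ties to the lowest run index); for yield flows total and mean are
argmax-equivalent (total = 35 × mean). The deviation table reports
100·(value − max)/max per flow across the selected solutions, rounded
half-away-from-zero to one decimal, giving an exactly-zero diagonal.

## Patch aggregation and metrics

Habitat stands of a period (positive flow value under the assigned
regime) are aggregated into patches as connected components of an
adjacency graph:

* **terrestrial** — edge iff the shared boundary has positive length.
  Corner contact is excluded: a point is not traversable, and linework
  barriers (roads, rivers) encoded in the polygon boundaries naturally
  split patches.
* **avian** — edge iff minimum boundary-to-boundary Euclidean distance ≤
  dist (inclusive), for species that can cross gaps up to a travel
  distance. Since touching polygons have distance 0, terrestrial patches
  refine avian patches for any dist ≥ 0.

Patches are recomputed independently per period; no temporal patch
identity is tracked. Patch areas sum the member stands' flow values
(i.e., their acreages from the stand-info table), so per-period patch
totals conserve the flow accounting exactly (measured relative gap ~1e-15
on the 505-stand template); polygon geometry is used for adjacency and
for the geometric metrics. Member sums and dissolves run in sorted
stand-ID order so results are identical across processes.

Geometric metrics (meters): patch level — area, perimeter,
perimeter/area ratio of the dissolved patch polygon; class level —
patch count, total and mean patch area, and largest-patch index (largest
patch area / total landscape area, in (0, 1]); landscape level is the
class level over all habitat, habitat being a single class here. This is
a defined subset, not parity with any landscape-metrics catalogue.

## Synthetic data generator

The generator emulates the *shape* of a managed-forest dataset, not any
real forest. Geometry: seeded uniform points in a rectangular extent,
Voronoi-tessellated (points mirrored across the extent edges so every
cell closes, then clipped), giving polygons that partition the extent to
within 0.1%. Stand areas are geometric areas in acres. Growth: per
period, BA ← BA + r·BA·(1 − BA/K)·(1 + ε) with ε ~ N(0, 0.15²)
truncated to ±0.9 per stand-period — multiplicative on the increment, so
undisturbed trajectories are monotone non-decreasing below the asymptote
K. Stands receive a seeded initial-condition multiplier in [0.7, 1.3]
shared across regimes. A thin retains a fraction of post-growth BA; a
clearcut removes all of it and replants at the regime's BA₀. Pulpwood
(tons/acre) is 1.5 × BA removed at the event, zero otherwise; the yield
coefficient was sized so per-period targets of 1,000–20,000 tons are
attainable but binding at template scale. Ten default regimes span
no-management, light/heavy periodic thinning, one- and two-cut rotations,
a frequent-thin open-woodland regime, and a slow-growing conversion
regime, guaranteeing genuinely distinct BA trajectories (the scheduler
has real choices).

What the generator does *not* emulate: species composition, size-class
structure, mortality/regeneration stochasticity, spatial autocorrelation
of site quality, and real regime prescriptions. Tests passing on
synthetic data therefore demonstrate correctness of the accounting,
search and spatial logic — not ecological validity of any schedule.

## Numerical and design choices

* Flow files are long-format text (`stand regime period value`) with a
  `#` header; values are written with `repr` and growth CSVs with
  `%.17g` + round-trip parsing, so write→read is bit-exact.
* The project-file XML schema is self-defined (element names mirror the
  flow-form parameter names); byte compatibility with any external
  program's project files is not claimed.
* The run-configuration string grammar (`n_flows`, per-flow sub-component
  flag pairs, three trailing component flags) is parsed strictly;
  nonzero flags for the unsupported clearcut/block/biological/spatial
  sub-components are rejected loudly rather than ignored.
* Percent deviations round half-away-from-zero (0.05% → 0.1%), matching
  the convention under which the published summary arithmetic reproduces.
* Degenerate inputs: a one-stand/one-regime problem is legal for a full
  run (constant trace) but a single proposal step on it is an error; an
  empty habitat period yields a patch set with zero patches and NaN area
  statistics in summaries.
* The feasibility-recovery experiment constructs instances backward from
  a randomly drawn schedule: targets anchor every period at that
  schedule's outputs and thlo = thhi = 25% of each flow's peak output.
  The band width is part of the construction: much tighter and the
  exactly-feasible set becomes too thin for constant-temperature sampling
  to certify in 10⁴ steps, while the case-study design itself uses far
  looser bands (thresholds of 1–5× the target).
* Problem sizes in the checked experiments (100 enumerable instances,
  20-stand feasibility instances, 200 30-stand patch landscapes, the
  full 505-stand conservation check, and a 100-stand copy of the 100-run
  sweep at 2,000 iterations) were chosen to exercise every code path at
  desk scale while keeping the whole suite fast.

## Known limitations

* Habitat quality is binary per stand (threshold rule): no area-weighted
  partial suitability.
* The sampler is single-chain; no parallel tempering or restarts, and no
  optimality certificates.
* Avian connectivity is a pure distance rule in the projected plane — no
  movement ecology, matrix resistance or barrier permeability.
* Patch identity is not tracked through time, so patch longevity and
  turnover require post-processing.
* Shapefile input is not supported; convert geometries to GeoJSON.
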