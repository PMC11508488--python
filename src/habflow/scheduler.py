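"""Metropolis-Hastings search over stand-to-regime assignments.

The decision variable is a schedule: one management regime per stand. A
proposal picks one stand uniformly at random and reassigns it to a different
regime chosen uniformly among its alternatives; since the proposal is
symmetric the Hastings correction is 1 and the move is accepted with
probability min(1, exp(-dE/T)), where E is the total weighted deviation
penalty summed over flow components. The sampler tracks and returns the
best schedule seen, not the final chain state, because solutions are judged
by realized output rather than stationary-distribution samples.

Energy updates are incremental: per-period flow sums are cached and a
proposal only touches the per-period value vectors of the one stand being
reassigned. Correctness of the incremental path is pinned to full
recomputation by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GrowthTable, Schedule
from .objectives import FlowComponent, flow_output, penalty

__all__ = ["MHConfig", "RunTrace", "Problem", "total_energy", "mh_step", "run_mh"]


@dataclass(frozen=True)
class MHConfig:
    """Sampler settings.

    iterations : number of proposal steps.
    temperature : initial Metropolis temperature T0 (> 0).
    cooling : per-iteration geometric factor in (0, 1]; 1.0 keeps T constant.
    seed : RNG seed; identical inputs and seed give identical traces.
    init : "random" for a seeded uniform initial assignment, or a Schedule.
    greedy : accept only non-increasing moves (the T -> 0+ hill-climb limit).
    """

    iterations: int
    temperature: float = 1.0
    cooling: float = 1.0
    seed: int = 0
    init: str | Schedule = "random"
    greedy: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError(f"iterations must be > 0, got {self.iterations}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not 0 < self.cooling <= 1:
            raise ValueError(f"cooling must be in (0, 1], got {self.cooling}")


@dataclass
class RunTrace:
    """Record of one sampler run."""

    energies: np.ndarray  # energy after each iteration
    accepted: np.ndarray  # bool per iteration
    best_schedule: Schedule
    best_energy: float
    outputs: dict[str, np.ndarray]  # flow name -> per-period output of best
    initial_energy: float = 0.0

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if len(self.accepted) else 0.0


class Problem:
    """Precompiled flow arrays for fast sampling.

    Enumerates (stand, regime) pairs; for every flow a dense array of shape
    ``(n_pairs, nperiods)`` holds the per-period values (0 where the flow has
    no key). Build once and reuse across sweep runs that share flows.
    """

    def __init__(
        self,
        stands: list[str],
        regimes: list[list[str]],
        flow_arrays: dict[str, np.ndarray],
        nperiods: int,
    ):
        self.stands = stands
        self.regimes = regimes
        self.nperiods = nperiods
        self.flow_arrays = flow_arrays
        # pair layout: stand i owns pair indices offsets[i] .. offsets[i+1]-1
        counts = np.array([len(r) for r in regimes])
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.n_pairs = int(self.offsets[-1])
        self.movable = np.flatnonzero(counts >= 2)

    @classmethod
    def from_growth(
        cls, growth: GrowthTable, components: Sequence[FlowComponent]
    ) -> "Problem":
        by_stand = growth.regimes_by_stand()
        stands = list(by_stand)
        regimes = [by_stand[s] for s in stands]
        return cls._build(stands, regimes, components, growth.nperiods)

    @classmethod
    def from_components(
        cls, components: Sequence[FlowComponent], nperiods: int
    ) -> "Problem":
        """Infer stand/regime availability from the union of flow keys."""
        by_stand: dict[str, list[str]] = {}
        for c in components:
            for (sid, rid, _p) in c.flow.values:
                lst = by_stand.setdefault(sid, [])
                if rid not in lst:
                    lst.append(rid)
        stands = list(by_stand)
        return cls._build(stands, [by_stand[s] for s in stands], components, nperiods)

    @classmethod
    def _build(
        cls,
        stands: list[str],
        regimes: list[list[str]],
        components: Sequence[FlowComponent],
        nperiods: int,
    ) -> "Problem":
        pair_index = {}
        k = 0
        for s, regs in zip(stands, regimes):
            for r in regs:
                pair_index[(s, r)] = k
                k += 1
        flow_arrays: dict[str, np.ndarray] = {}
        for c in components:
            if c.flow.name in flow_arrays:
                continue
            arr = np.zeros((k, nperiods), dtype=float)
            for (sid, rid, per), v in c.flow.values.items():
                idx = pair_index.get((sid, rid))
                if idx is None:
                    raise ValueError(
                        f"flow {c.flow.name!r} has key ({sid!r}, {rid!r}) "
                        "absent from the stand/regime universe"
                    )
                arr[idx, per - 1] = v
            flow_arrays[c.flow.name] = arr
        return cls(stands, regimes, flow_arrays, nperiods)

    def pair_of(self, schedule: Schedule) -> np.ndarray:
        """Current pair index per stand for a schedule."""
        out = np.empty(len(self.stands), dtype=np.intp)
        for i, (s, regs) in enumerate(zip(self.stands, self.regimes)):
            rid = schedule.assignment.get(s)
            if rid is None:
                raise ValueError(f"schedule misses stand {s!r}")
            try:
                out[i] = self.offsets[i] + regs.index(rid)
            except ValueError:
                raise ValueError(
                    f"stand {s!r}: regime {rid!r} not available (has {regs})"
                ) from None
        return out

    def schedule_of(self, pairs: np.ndarray) -> Schedule:
        assignment = {
            s: self.regimes[i][int(pairs[i] - self.offsets[i])]
            for i, s in enumerate(self.stands)
        }
        return Schedule(assignment)

    def random_schedule(self, rng: np.random.Generator) -> np.ndarray:
        pairs = np.empty(len(self.stands), dtype=np.intp)
        for i in range(len(self.stands)):
            lo, hi = self.offsets[i], self.offsets[i + 1]
            pairs[i] = rng.integers(lo, hi)
        return pairs


class _EnergyModel:
    """Stacked per-component band arrays for vectorized penalty evaluation."""

    def __init__(self, problem: Problem, components: Sequence[FlowComponent]):
        self.problem = problem
        self.names = [c.name for c in components]
        T = problem.nperiods
        self.values = np.stack(
            [problem.flow_arrays[c.flow.name] for c in components]
        )  # (C, n_pairs, T)
        lo, hi, denom, w = [], [], [], []
        for c in components:
            ts = c.target_series(T)
            lo.append(ts.lower_bound)
            hi.append(ts.upper_bound)
            denom.append(np.maximum(ts.targets, 1.0))
            w.append(c.weight)
        self.lower = np.stack(lo)
        self.upper = np.stack(hi)
        self.denom = np.stack(denom)
        self.weights = np.array(w)

    def sums_for(self, pairs: np.ndarray) -> np.ndarray:
        return self.values[:, pairs, :].sum(axis=1)  # (C, T)

    def energy(self, sums: np.ndarray) -> float:
        viol = np.maximum(0.0, np.maximum(self.lower - sums, sums - self.upper))
        v = viol / self.denom
        return float(self.weights @ (v * v).sum(axis=1))


def total_energy(
    schedule: Schedule, components: Sequence[FlowComponent], nperiods: int
) -> float:
    """Sum of per-component deviation penalties for a schedule."""
    return sum(
        penalty(flow_output(schedule, c.flow, nperiods), c.target_series(nperiods), c.weight)
        for c in components
    )


def mh_step(
    schedule: Schedule,
    components: Sequence[FlowComponent],
    nperiods: int,
    temperature: float,
    rng: np.random.Generator,
    greedy: bool = False,
) -> tuple[Schedule, float, bool]:
    """One Metropolis proposal from ``schedule``.

    Returns ``(new_schedule, new_energy, accepted)``; on rejection the
    original schedule (and its energy) comes back unchanged.
    """
    problem = Problem.from_components(components, nperiods)
    if len(problem.movable) == 0:
        raise ValueError("no stand has an alternative regime to propose")
    model = _EnergyModel(problem, components)
    pairs = problem.pair_of(schedule)
    sums = model.sums_for(pairs)
    energy = model.energy(sums)
    new_pairs, new_sums, new_energy, accepted = _propose(
        model, problem, pairs, sums, energy, temperature, rng, greedy
    )
    if accepted:
        return problem.schedule_of(new_pairs), new_energy, True
    return schedule, energy, False


def _propose(model, problem, pairs, sums, energy, temperature, rng, greedy):
    i = int(problem.movable[rng.integers(len(problem.movable))])
    lo, hi = int(problem.offsets[i]), int(problem.offsets[i + 1])
    cur = int(pairs[i])
    # uniform among the stand's other regimes
    j = int(rng.integers(lo, hi - 1))
    if j >= cur:
        j += 1
    delta = model.values[:, j, :] - model.values[:, cur, :]
    cand = sums + delta
    cand_energy = model.energy(cand)
    d_e = cand_energy - energy
    if d_e <= 0:
        accept = True
    elif greedy:
        accept = False
    else:
        accept = rng.random() < np.exp(-d_e / temperature)
    if accept:
        pairs = pairs.copy()
        pairs[i] = j
        return pairs, cand, cand_energy, True
    return pairs, sums, energy, False


def run_mh(
    components: Sequence[FlowComponent],
    growth: GrowthTable,
    cfg: MHConfig,
    problem: Problem | None = None,
) -> RunTrace:
    """Run the sampler for ``cfg.iterations`` steps and return the trace.

    The temperature schedule is geometric, ``T_k = T0 * cooling**k``. The
    returned trace holds the best-so-far schedule, its energy, and its
    per-flow per-period outputs. Deterministic given the seed.
    """
    if problem is None:
        problem = Problem.from_growth(growth, components)
    model = _EnergyModel(problem, components)
    rng = np.random.default_rng(cfg.seed)

    if isinstance(cfg.init, Schedule):
        pairs = problem.pair_of(cfg.init)
    elif cfg.init == "random":
        pairs = problem.random_schedule(rng)
    else:
        raise ValueError(f"init must be 'random' or a Schedule, got {cfg.init!r}")

    sums = model.sums_for(pairs)
    energy = model.energy(sums)
    best_pairs, best_energy = pairs.copy(), energy
    initial_energy = energy

    energies = np.empty(cfg.iterations)
    accepted = np.zeros(cfg.iterations, dtype=bool)
    temperature = cfg.temperature
    can_move = len(problem.movable) > 0

    for k in range(cfg.iterations):
        if can_move:
            pairs, sums, energy, acc = _propose(
                model, problem, pairs, sums, energy, temperature, rng, cfg.greedy
            )
            accepted[k] = acc
            if acc and energy < best_energy:
                best_energy = energy
                best_pairs = pairs.copy()
        energies[k] = energy
        temperature *= cfg.cooling

    best_schedule = problem.schedule_of(best_pairs)
    best_sums = model.sums_for(best_pairs)
    outputs = {name: best_sums[c] for c, name in enumerate(model.names)}
    return RunTrace(
        energies=energies,
        accepted=accepted,
        best_schedule=best_schedule,
        best_energy=float(best_energy),
        outputs=outputs,
        initial_energy=float(initial_energy),
    )
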