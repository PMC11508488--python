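import itertools

import numpy as np
import pandas as pd
import pytest

import habflow as hf
from habflow.core import GrowthTable, Schedule
from habflow.objectives import FlowComponent
from habflow.scheduler import MHConfig, mh_step, run_mh, total_energy


def _instance(seed: int, n_stands=3, n_regimes=3, nperiods=4):
    """A small random one-flow instance whose targets track a random schedule."""
    rng = np.random.default_rng(seed)
    rows = [
        (f"s{s}", f"R{r}", p, float(rng.uniform(0, 10)))
        for s in range(n_stands)
        for r in range(n_regimes)
        for p in range(1, nperiods + 1)
    ]
    df = pd.DataFrame(rows, columns=["stand_id", "regime_id", "period", "pulp"])
    growth = GrowthTable(df, nperiods)
    flow = growth.flow("pulp")
    ref = Schedule({f"s{s}": f"R{rng.integers(n_regimes)}" for s in range(n_stands)})
    out = hf.flow_output(ref, flow, nperiods)
    # anchor every period at the reference outputs: ref is inside the band
    model = "; ".join(f"{p},{out[p - 1]:.3f}" for p in range(1, nperiods + 1))
    comp = FlowComponent(
        "pulp", flow, model, thlo=float(rng.uniform(0.5, 2)), thhi=float(rng.uniform(0.5, 2))
    )
    return growth, [comp]


def _enumerate_minimum(growth, components):
    by = growth.regimes_by_stand()
    return min(
        total_energy(Schedule(dict(zip(by, combo))), components, growth.nperiods)
        for combo in itertools.product(*by.values())
    )


class TestTotalEnergy:
    def test_feasible_schedule_scores_zero(self):
        growth, comps = _instance(0)
        # the reference schedule used to set the targets is inside the band
        by = growth.regimes_by_stand()
        feasible = [
            Schedule(dict(zip(by, combo)))
            for combo in itertools.product(*by.values())
            if total_energy(Schedule(dict(zip(by, combo))), comps, 4) == 0.0
        ]
        assert feasible  # at least the generating schedule

    def test_single_component_equals_penalty(self, small_problem):
        from tests.conftest import random_schedule

        _, _, growth, flows = small_problem
        comp = FlowComponent("pulp", flows["pulp"], "5,1000", 500, 500)
        sched = random_schedule(growth, 1)
        out = hf.flow_output(sched, flows["pulp"], 10)
        assert total_energy(sched, [comp], 10) == pytest.approx(
            hf.penalty(out, comp.target_series(10), 1.0)
        )

    def test_four_components_sum(self, small_problem):
        from tests.conftest import random_schedule

        _, _, growth, flows = small_problem
        comps = [
            FlowComponent(n, f, "3,500; 8,500", 200, 200, weight=w)
            for (n, f), w in zip(flows.items(), (1.0, 2.0, 0.5, 1.0))
        ]
        sched = random_schedule(growth, 2)
        expected = sum(  # per-component recomputation oracle
            hf.penalty(hf.flow_output(sched, c.flow, 10), c.target_series(10), c.weight)
            for c in comps
        )
        assert total_energy(sched, comps, 10) == pytest.approx(expected)


class TestMhStep:
    def test_downhill_always_accepted(self):
        growth, comps = _instance(1)
        by = growth.regimes_by_stand()
        # start from the worst schedule so most proposals go downhill
        worst = max(
            (Schedule(dict(zip(by, c))) for c in itertools.product(*by.values())),
            key=lambda s: total_energy(s, comps, 4),
        )
        rng = np.random.default_rng(0)
        seen_downhill = False
        sched = worst
        for _ in range(50):
            new, e, acc = mh_step(sched, comps, 4, temperature=1e-9, rng=rng, greedy=True)
            if acc and new.assignment != sched.assignment:
                assert e <= total_energy(sched, comps, 4) + 1e-12
                seen_downhill = True
            sched = new
        assert seen_downhill

    def test_zero_delta_accepted(self):
        # two identical regimes: every proposal has dE = 0 and must be accepted
        df = pd.DataFrame(
            {
                "stand_id": ["s1"] * 4,
                "regime_id": ["A", "A", "B", "B"],
                "period": [1, 2, 1, 2],
                "v": [5.0, 5.0, 5.0, 5.0],
            }
        )
        growth = GrowthTable(df, 2)
        comp = FlowComponent("v", growth.flow("v"), "1,5; 2,5", 1, 1)
        _, _, accepted = mh_step(
            Schedule({"s1": "A"}), [comp], 2, temperature=1.0, rng=np.random.default_rng(0)
        )
        assert accepted

    def test_incremental_energy_matches_recompute(self):
        for seed in range(5):
            growth, comps = _instance(seed, n_stands=4)
            rng = np.random.default_rng(seed)
            by = growth.regimes_by_stand()
            sched = Schedule({s: rs[0] for s, rs in by.items()})
            for _ in range(30):
                sched, energy, _ = mh_step(sched, comps, 4, 1.0, rng)
                assert energy == pytest.approx(
                    total_energy(sched, comps, 4), rel=1e-12, abs=1e-12
                )

    def test_no_alternative_regime_errors(self):
        df = pd.DataFrame(
            {"stand_id": ["s1"], "regime_id": ["A"], "period": [1], "v": [1.0]}
        )
        growth = GrowthTable(df, 1)
        comp = FlowComponent("v", growth.flow("v"), "1,1", 1, 1)
        with pytest.raises(ValueError, match="alternative"):
            mh_step(Schedule({"s1": "A"}), [comp], 1, 1.0, np.random.default_rng(0))


class TestRunMh:
    def test_single_schedule_problem(self):
        df = pd.DataFrame(
            {"stand_id": ["s1"], "regime_id": ["A"], "period": [1], "v": [1.0]}
        )
        growth = GrowthTable(df, 1)
        comp = FlowComponent("v", growth.flow("v"), "1,5", 1, 1)
        trace = run_mh([comp], growth, MHConfig(iterations=1, seed=0))
        assert trace.best_schedule.assignment == {"s1": "A"}
        assert np.all(trace.energies == trace.best_energy)

    def test_determinism(self):
        growth, comps = _instance(7)
        t1 = run_mh(comps, growth, MHConfig(iterations=500, seed=42))
        t2 = run_mh(comps, growth, MHConfig(iterations=500, seed=42))
        assert np.array_equal(t1.energies, t2.energies)
        assert np.array_equal(t1.accepted, t2.accepted)
        assert t1.best_schedule.assignment == t2.best_schedule.assignment

    def test_more_iterations_only_improve(self):
        growth, comps = _instance(8)
        short = run_mh(comps, growth, MHConfig(iterations=200, seed=5))
        long = run_mh(comps, growth, MHConfig(iterations=2000, seed=5))
        assert long.best_energy <= short.best_energy

    def test_greedy_never_climbs(self):
        growth, comps = _instance(9, n_stands=4)
        trace = run_mh(comps, growth, MHConfig(iterations=500, seed=3, greedy=True))
        diffs = np.diff(np.concatenate([[trace.initial_energy], trace.energies]))
        assert (diffs <= 1e-12).all()

    def test_one_stand_three_regimes_recovers_enumeration(self):
        growth, comps = _instance(10, n_stands=1, n_regimes=3)
        best = _enumerate_minimum(growth, comps)
        trace = run_mh(comps, growth, MHConfig(iterations=100, seed=1))
        assert trace.best_energy == pytest.approx(best, abs=1e-12)

    def test_feasible_five_stand_instance_reaches_zero(self):
        growth, comps = _instance(11, n_stands=5, n_regimes=3, nperiods=4)
        # instance built backward from a feasible schedule: minimum is 0
        assert _enumerate_minimum(growth, comps) == 0.0
        trace = run_mh(comps, growth, MHConfig(iterations=10_000, seed=2))
        assert trace.best_energy == 0.0

    def test_outputs_equal_flow_output_of_best(self):
        growth, comps = _instance(12, n_stands=4)
        trace = run_mh(comps, growth, MHConfig(iterations=300, seed=6))
        recomputed = hf.flow_output(trace.best_schedule, comps[0].flow, 4)
        assert np.allclose(trace.outputs["pulp"], recomputed)

    def test_schedule_init_respected(self):
        growth, comps = _instance(13)
        by = growth.regimes_by_stand()
        init = Schedule({s: rs[0] for s, rs in by.items()})
        trace = run_mh(comps, growth, MHConfig(iterations=1, seed=0, init=init))
        assert trace.initial_energy == pytest.approx(total_energy(init, comps, 4))

    @pytest.mark.parametrize(
        "kwargs", [dict(iterations=0), dict(iterations=1, temperature=0.0), dict(iterations=1, cooling=0.0)]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MHConfig(**kwargs)
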