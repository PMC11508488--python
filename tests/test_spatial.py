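import itertools

import numpy as np
import pytest
from shapely.geometry import Polygon, box

import habflow as hf
from habflow.core import FlowTable, Schedule, StandInfo
from habflow.spatial import (
    PatchSet,
    SpatialParams,
    StandGeometry,
    adjacency_graph,
    patch_metrics,
    patch_summary,
    patches_per_period,
)

TERRESTRIAL = SpatialParams(mode="terrestrial")


def _squares(*origins, size=1.0):
    return [
        StandGeometry(f"s{i}", box(x, y, x + size, y + size))
        for i, (x, y) in enumerate(origins)
    ]


def _bruteforce_components(geoms, params):
    """O(n^2) pairwise union-find oracle, independent of the graph library."""
    parent = {g.stand_id: g.stand_id for g in geoms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(geoms, 2):
        if params.mode == "terrestrial":
            linked = a.polygon.intersection(b.polygon).length > 1e-9
        else:
            linked = a.polygon.distance(b.polygon) <= params.dist
        if linked:
            parent[find(a.stand_id)] = find(b.stand_id)
    comps = {}
    for g in geoms:
        comps.setdefault(find(g.stand_id), set()).add(g.stand_id)
    return {frozenset(c) for c in comps.values()}


class TestAdjacencyGraph:
    def test_shared_edge_connects(self):
        g = adjacency_graph(_squares((0, 0), (1, 0)), TERRESTRIAL)
        assert g.number_of_edges() == 1

    def test_corner_touch_does_not_connect(self):
        g = adjacency_graph(_squares((0, 0), (1, 1)), TERRESTRIAL)
        assert g.number_of_edges() == 0

    def test_avian_distance_rule(self):
        geoms = _squares((0, 0), (0, 0), size=100.0)
        geoms = [
            StandGeometry("a", box(0, 0, 100, 100)),
            StandGeometry("b", box(200, 0, 300, 100)),  # 100 m gap
        ]
        near = adjacency_graph(geoms, SpatialParams(mode="avian", dist=500.0))
        far = adjacency_graph(geoms, SpatialParams(mode="avian", dist=50.0))
        assert near.has_edge("a", "b")
        assert not far.has_edge("a", "b")

    def test_avian_distance_inclusive(self):
        geoms = [
            StandGeometry("a", box(0, 0, 1, 1)),
            StandGeometry("b", box(2, 0, 3, 1)),  # exactly 1 apart
        ]
        g = adjacency_graph(geoms, SpatialParams(mode="avian", dist=1.0))
        assert g.has_edge("a", "b")

    def test_invalid_geometry_names_stand(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="s9"):
            StandGeometry("s9", bowtie)

    @pytest.mark.parametrize(
        "params",
        [TERRESTRIAL, SpatialParams(mode="avian", dist=30.0), SpatialParams(mode="avian", dist=120.0)],
    )
    def test_components_match_bruteforce_on_random_landscapes(self, params):
        for seed in range(10):
            geoms, _ = hf.generate_landscape(
                hf.LandscapeSpec(30, (0, 0, 900, 900), seed=seed)
            )
            g = adjacency_graph(geoms, params)
            import networkx as nx

            got = {frozenset(c) for c in nx.connected_components(g)}
            assert got == _bruteforce_components(geoms, params)

    def test_spatial_params_validation(self):
        with pytest.raises(ValueError):
            SpatialParams(mode="avian")  # dist required
        with pytest.raises(ValueError):
            SpatialParams(mode="terrestrial", dist=5.0)
        with pytest.raises(ValueError):
            SpatialParams(mode="swimming")


class TestPatchesPerPeriod:
    def _flow(self, habitat: dict[int, dict[str, float]], regime="A") -> FlowTable:
        values = {}
        for per, stands in habitat.items():
            for sid, v in stands.items():
                values[(sid, regime, per)] = v
        return FlowTable("h", values, "acres")

    def test_empty_period_convention(self):
        geoms = _squares((0, 0), (1, 0))
        flow = self._flow({1: {"s0": 0.0, "s1": 0.0}})
        sched = Schedule({"s0": "A", "s1": "A"})
        (ps,) = patches_per_period(sched, flow, geoms, TERRESTRIAL, 1)
        assert ps.n_patches == 0 and ps.total_area == 0.0

    def test_infinite_avian_distance_single_patch(self):
        geoms = _squares((0, 0), (5, 0), (0, 5), (9, 9))
        flow = self._flow({1: {g.stand_id: 1.0 for g in geoms}})
        sched = Schedule({g.stand_id: "A" for g in geoms})
        (ps,) = patches_per_period(
            sched, flow, geoms, SpatialParams(mode="avian", dist=1e9), 1
        )
        assert ps.n_patches == 1
        assert ps.members() == {g.stand_id for g in geoms}

    def test_only_assigned_regime_counts(self):
        geoms = _squares((0, 0))
        flow = FlowTable("h", {("s0", "A", 1): 1.0, ("s0", "B", 1): 0.0})
        (ps,) = patches_per_period(
            Schedule({"s0": "B"}), flow, geoms, TERRESTRIAL, 1
        )
        assert ps.n_patches == 0

    def test_missing_geometry_rejected(self):
        flow = self._flow({1: {"ghost": 1.0}})
        with pytest.raises(ValueError, match="ghost"):
            patches_per_period(Schedule({"ghost": "A"}), flow, _squares((0, 0)), TERRESTRIAL, 1)

    def test_partition_and_area_conservation(self, small_problem):
        from tests.conftest import random_schedule

        geoms, _, growth, flows = small_problem
        sched = random_schedule(growth, 21)
        flow = flows["hsi_intermediate"]
        patchsets = patches_per_period(sched, flow, geoms, TERRESTRIAL, 10)
        out = hf.flow_output(sched, flow, 10)
        for ps in patchsets:
            # member sets partition the habitat stands; areas sum to the flow
            members = [m for _, m, _ in ps.patches]
            assert sum(len(m) for m in members) == len(ps.members())
            assert ps.total_area == pytest.approx(out[ps.period - 1])

    def test_avian_monotone_in_dist(self, small_problem):
        from tests.conftest import random_schedule

        geoms, _, growth, flows = small_problem
        sched = random_schedule(growth, 22)
        flow = flows["hsi_closed"]
        prev_n, prev_max = None, None
        for dist in (0.0, 50.0, 200.0, 1000.0):
            patchsets = patches_per_period(
                sched, flow, geoms, SpatialParams(mode="avian", dist=dist), 10
            )
            n = sum(ps.n_patches for ps in patchsets)
            mx = max((ps.areas.max() for ps in patchsets if ps.n_patches), default=0)
            if prev_n is not None:
                assert n <= prev_n
                # merged patches re-sum member areas: allow float noise
                assert mx >= prev_max - 1e-9 * max(1.0, prev_max)
            prev_n, prev_max = n, mx

    def test_terrestrial_refines_avian(self, small_problem):
        from tests.conftest import random_schedule

        geoms, _, growth, flows = small_problem
        sched = random_schedule(growth, 23)
        flow = flows["hsi_open"]
        terr = patches_per_period(sched, flow, geoms, TERRESTRIAL, 10)
        avian = patches_per_period(
            sched, flow, geoms, SpatialParams(mode="avian", dist=100.0), 10
        )
        for pt, pa in zip(terr, avian):
            avian_sets = [m for _, m, _ in pa.patches]
            for _, members, _ in pt.patches:
                assert any(members <= a for a in avian_sets)


class TestPatchSummary:
    def test_two_patch_statistics(self):
        ps = PatchSet(1, ((1, frozenset({"a"}), 10.0), (2, frozenset({"b"}), 30.0)))
        df = patch_summary([ps])
        row = df.iloc[0]
        assert (row.n_patches, row.min_area, row.max_area, row.mean_area, row.total_area) == (
            2, 10.0, 30.0, 20.0, 40.0,
        )

    def test_single_patch_collapses_stats(self):
        ps = PatchSet(1, ((1, frozenset({"a"}), 12.5),))
        row = patch_summary([ps]).iloc[0]
        assert row.min_area == row.max_area == row.mean_area == row.total_area == 12.5

    def test_aggregate_rows_present(self):
        ps = [PatchSet(t, ((1, frozenset({"a"}), float(t)),)) for t in (1, 2)]
        df = patch_summary(ps)
        assert list(df["period"].tail(2)) == ["mean", "range"]
        assert df.iloc[2]["total_area"] == 1.5


class TestPatchMetrics:
    def test_square_patch_geometry(self):
        geoms = [StandGeometry("a", box(0, 0, 100, 100))]
        ps = [PatchSet(1, ((1, frozenset({"a"}), 2.47),))]
        df = patch_metrics(ps, geoms, level="patch")
        assert df.iloc[0]["area"] == pytest.approx(10_000.0)
        assert df.iloc[0]["perimeter"] == pytest.approx(400.0)
        assert df.iloc[0]["para"] == pytest.approx(0.04)

    def test_largest_patch_index_bound(self):
        geoms = _squares((0, 0), (1, 0))
        ps = [PatchSet(1, ((1, frozenset({"s0", "s1"}), 2.0),))]
        df = patch_metrics(ps, geoms, level="landscape")
        assert df.iloc[0]["lpi"] == pytest.approx(1.0)

    def test_class_counts_match_summary(self, small_problem):
        from tests.conftest import random_schedule

        geoms, _, growth, flows = small_problem
        sched = random_schedule(growth, 24)
        patchsets = patches_per_period(sched, flows["hsi_open"], geoms, TERRESTRIAL, 10)
        cls = patch_metrics(patchsets, geoms, level="class")
        summ = patch_summary(patchsets).iloc[:10]
        assert np.array_equal(cls["n_patches"].to_numpy(), summ["n_patches"].to_numpy())

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            patch_metrics([], [], level="region")


class TestGeoJson:
    def test_round_trip(self, tmp_path, small_problem):
        geoms, info, _, _ = small_problem
        path = tmp_path / "stands.geojson"
        hf.write_geojson(geoms, path, info)
        back = hf.read_geojson(path)
        assert [g.stand_id for g in back] == [g.stand_id for g in geoms]
        for a, b in zip(back, geoms):
            assert a.polygon.equals_exact(b.polygon, 1e-9)
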