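"""Synthetic stand landscapes and growth projections.

Real stand inventories and growth-model output are rarely shareable, so this
module fabricates both: a Voronoi tessellation of a rectangular extent
stands in for the stand map, and a discrete logistic basal-area model with
scripted silvicultural events (thinning, clearcut-and-replant) stands in
for a forest growth simulator. The output has the exact shape the rest of
the package consumes — a stand-info table, stand polygons, and a growth
table of basal area (m2/ha) and harvested pulpwood (tons/acre) per stand x
regime x period — at the scale of the motivating case study: 505 stands on
17,774 acres, 10 regimes, 35 three-year periods.

Growth dynamics per period: BA increases by r*BA*(1 - BA/K) modulated by
small seeded stand-level noise, then any scheduled event fires. A thin
retains a fraction of the post-growth basal area; a clearcut removes it all
and restarts from the regime's replant basal area. Pulpwood is produced
only at event periods, proportional to the basal area removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .core import GrowthTable, StandInfo
from .spatial import StandGeometry

__all__ = [
    "LandscapeSpec",
    "RegimeEvent",
    "RegimeSpec",
    "generate_landscape",
    "project_growth",
    "default_regimes",
    "case_study_template",
    "ACRE_M2",
    "YIELD_TONS_PER_ACRE_PER_BA",
]

#: Square meters per acre.
ACRE_M2 = 4046.8564224

#: Pulpwood yield coefficient: tons/acre produced per m2/ha of basal area
#: removed in a harvest event. Sized so that on the case-study-scale
#: landscape, per-period pulpwood targets of 1,000-20,000 tons are
#: attainable but binding.
YIELD_TONS_PER_ACRE_PER_BA = 1.5

#: Smallest Voronoi cell worth calling a stand.
_MIN_CELL_AREA_M2 = 25.0

#: Planning horizon used by the case-study template (three-year periods).
TEMPLATE_NPERIODS = 35


@dataclass(frozen=True)
class LandscapeSpec:
    """A rectangular extent to tessellate into ``n_stands`` polygons."""

    n_stands: int
    extent: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if self.n_stands < 1:
            raise ValueError(f"n_stands must be >= 1, got {self.n_stands}")
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"degenerate extent {self.extent}")
        if (x1 - x0) * (y1 - y0) < self.n_stands * _MIN_CELL_AREA_M2:
            raise ValueError(
                f"extent cannot host {self.n_stands} stands at minimum "
                f"cell size {_MIN_CELL_AREA_M2} m2"
            )

    @property
    def area_m2(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class RegimeEvent:
    """A scheduled silvicultural action in one period."""

    period: int
    action: str  # "thin" | "clearcut_replant"
    retention: float | None = None  # thin only: fraction of BA kept

    def __post_init__(self) -> None:
        if self.action not in ("thin", "clearcut_replant"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "thin":
            if self.retention is None or not 0 < self.retention < 1:
                raise ValueError(f"thin retention must be in (0, 1), got {self.retention}")
        elif self.retention is not None:
            raise ValueError("retention only applies to thinning")


@dataclass(frozen=True)
class RegimeSpec:
    """A management regime: scripted events plus stand growth parameters.

    growth = (r, K, BA0): per-period logistic rate, basal-area asymptote
    (m2/ha) and replant/initial basal area.
    """

    regime_id: str
    events: tuple[RegimeEvent, ...] = ()
    r: float = 0.35
    K: float = 30.0
    ba0: float = 12.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.K <= 0 or self.ba0 < 0:
            raise ValueError(f"regime {self.regime_id!r}: need r > 0, K > 0, ba0 >= 0")


def generate_landscape(
    spec: LandscapeSpec,
) -> tuple[list[StandGeometry], StandInfo]:
    """Tessellate the extent into stand polygons (Voronoi of seeded points).

    Seed points are drawn uniformly; mirroring them across the four extent
    edges closes every interior cell, which is then clipped to the extent.
    The cells partition the extent (no gaps or overlaps beyond floating
    point), and stand areas are the geometric areas converted to acres.
    Deterministic given ``spec.seed``.
    """
    x0, y0, x1, y1 = spec.extent
    extent_poly = box(x0, y0, x1, y1)
    n = spec.n_stands
    ids = [f"s{i + 1:04d}" for i in range(n)]
    if n == 1:
        geoms = [StandGeometry(ids[0], extent_poly)]
    else:
        rng = np.random.default_rng(spec.seed)
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
        )
        mirrored = np.vstack(
            [
                pts,
                np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]]),
                np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]]),
                np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]]),
                np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]]),
            ]
        )
        vor = Voronoi(mirrored)
        geoms = []
        for i, sid in enumerate(ids):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:  # cannot happen with mirroring
                raise RuntimeError(f"open Voronoi cell for stand {sid}")
            cell = Polygon(vor.vertices[region]).intersection(extent_poly)
            if not cell.is_valid:
                cell = cell.buffer(0)
            geoms.append(StandGeometry(sid, cell))
    info = StandInfo({g.stand_id: g.polygon.area / ACRE_M2 for g in geoms})
    return geoms, info


def project_growth(
    info: StandInfo,
    regimes: Sequence[RegimeSpec],
    nperiods: int,
    seed: int = 0,
    noise_sd: float = 0.15,
) -> GrowthTable:
    """Simulate basal area and harvested pulpwood per stand x regime x period.

    Each stand gets a seeded initial-condition multiplier (lognormal-ish,
    clipped to [0.7, 1.3]) applied to every regime's starting basal area, so
    stands differ but a stand's regimes share initial conditions. The
    growth increment is perturbed multiplicatively by stand-period noise
    (sd ``noise_sd``, truncated at +-0.9), keeping no-event trajectories
    monotone non-decreasing below the asymptote. Basal area is recorded
    after any event; pulpwood (tons/acre) is ``YIELD_TONS_PER_ACRE_PER_BA``
    times the basal area removed, zero outside event periods.
    """
    for reg in regimes:
        for ev in reg.events:
            if not 1 <= ev.period <= nperiods:
                raise ValueError(
                    f"regime {reg.regime_id!r}: event period {ev.period} "
                    f"outside [1, {nperiods}]"
                )
    stands = list(info.areas)
    ns = len(stands)
    rng = np.random.default_rng(seed)
    init_factor = np.clip(rng.normal(1.0, 0.12, size=ns), 0.7, 1.3)

    frames = []
    for reg in regimes:
        events = {ev.period: ev for ev in reg.events}
        eps = np.clip(rng.normal(0.0, noise_sd, size=(ns, nperiods)), -0.9, 0.9)
        ba = reg.ba0 * init_factor
        ba_out = np.empty((ns, nperiods))
        pulp_out = np.zeros((ns, nperiods))
        for t in range(1, nperiods + 1):
            growth = reg.r * ba * (1.0 - ba / reg.K) * (1.0 + eps[:, t - 1])
            ba = np.maximum(ba + growth, 0.0)
            ev = events.get(t)
            if ev is not None:
                if ev.action == "thin":
                    removed = ba * (1.0 - ev.retention)
                    ba = ba * ev.retention
                else:  # clearcut_replant
                    removed = ba
                    ba = reg.ba0 * init_factor
                pulp_out[:, t - 1] = YIELD_TONS_PER_ACRE_PER_BA * removed
            ba_out[:, t - 1] = ba
        frames.append(
            pd.DataFrame(
                {
                    "stand_id": np.repeat(stands, nperiods),
                    "regime_id": reg.regime_id,
                    "period": np.tile(np.arange(1, nperiods + 1), ns),
                    "BA": ba_out.ravel(),
                    "pulp": pulp_out.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return GrowthTable(df, nperiods)


def default_regimes(nperiods: int = TEMPLATE_NPERIODS) -> list[RegimeSpec]:
    """Ten contrasting regimes spanning closed, intermediate and open stands.

    Analogues of a working-forest regime set — no management, periodic
    thinning at several intensities, clearcut rotations, and a
    slow-growing conversion regime — not replicas of any particular
    prescription catalogue.
    """
    thin = lambda p, keep: RegimeEvent(p, "thin", keep)
    cc = lambda p: RegimeEvent(p, "clearcut_replant")
    every = lambda start, step: range(start, nperiods + 1, step)
    regimes = [
        RegimeSpec("R01_nomgmt"),
        RegimeSpec("R02_thin_light", tuple(thin(p, 0.7) for p in (10, 20, 30))),
        RegimeSpec("R03_thin_heavy", tuple(thin(p, 0.5) for p in (8, 16, 24, 32))),
        RegimeSpec("R04_cc30", (cc(30),)),
        RegimeSpec("R05_cc20", (cc(20),), ba0=10.0),
        RegimeSpec("R06_cc10_25", (cc(10), cc(25)), ba0=8.0),
        RegimeSpec("R07_open", tuple(thin(p, 0.35) for p in every(5, 5)), ba0=8.0),
        RegimeSpec("R08_convert", (cc(5),), r=0.18, K=26.0, ba0=2.0),
        RegimeSpec(
            "R09_intermediate", tuple(thin(p, 0.6) for p in every(6, 6)), ba0=13.0
        ),
        RegimeSpec("R10_cc15_30", (cc(15), cc(30)), ba0=9.0),
    ]
    # shorter horizons keep the same regime identities, minus late events
    return [
        RegimeSpec(
            reg.regime_id,
            tuple(ev for ev in reg.events if ev.period <= nperiods),
            reg.r,
            reg.K,
            reg.ba0,
        )
        for reg in regimes
    ]


def case_study_template():
    """Specs sized to the motivating case study.

    505 stands on a square extent of 17,774 acres (so the mean stand area
    is 35.2 acres by construction), 10 regimes over 35 three-year periods,
    and the 5 x 20 target sweep: HSI flow targets of 1,000-5,000 acres
    (thhi equal to the target), pulpwood targets of 1,000-20,000 tons with
    thhi of 5,000-100,000 tons, thlo fixed at 1,000 throughout, targets
    anchored at periods 10, 20 and 30, 10,000 sampler iterations per run.

    Returns ``(LandscapeSpec, list[RegimeSpec], SweepSpec)``.
    """
    from .scheduler import MHConfig
    from .experiment import SweepSpec

    side = math.sqrt(17_774 * ACRE_M2)
    landscape = LandscapeSpec(n_stands=505, extent=(0.0, 0.0, side, side), seed=505)
    regimes = default_regimes(TEMPLATE_NPERIODS)
    sweep = SweepSpec(
        hsi_levels=[(1000.0 * k, 1000.0 * k) for k in range(1, 6)],
        pulp_steps=[(1000.0 * k, 5000.0 * k) for k in range(1, 21)],
        hsi_flow_names=("hsi_closed", "hsi_intermediate", "hsi_open"),
        pulp_flow_name="pulp",
        thlo=1000.0,
        anchor_periods=(10, 20, 30),
        mh=MHConfig(iterations=10_000),
    )
    return landscape, regimes, sweep
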