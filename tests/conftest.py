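import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import habflow as hf
from habflow.core import GrowthTable, Schedule, StandInfo

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_growth() -> GrowthTable:
    """2 stands x 2 regimes x 3 periods with BA and pulp attributes."""
    rows = []
    for s, base in (("s1", 10.0), ("s2", 14.0)):
        for r, bump in (("A", 0.0), ("B", 4.0)):
            for p in (1, 2, 3):
                rows.append((s, r, p, base + bump + 2.0 * p, 1.0 * p))
    df = pd.DataFrame(rows, columns=["stand_id", "regime_id", "period", "BA", "pulp"])
    return GrowthTable(df, nperiods=3)


@pytest.fixture
def tiny_info() -> StandInfo:
    return StandInfo({"s1": 10.0, "s2": 35.2})


@pytest.fixture
def small_problem():
    """20-stand synthetic landscape with growth, HSI columns and four flows."""
    geoms, info = hf.generate_landscape(
        hf.LandscapeSpec(n_stands=20, extent=(0, 0, 1100, 1100), seed=11)
    )
    growth = hf.project_growth(info, hf.default_regimes(10), 10, seed=11)
    for eq in hf.builtin_equations():
        growth = hf.hsi_calc(growth, eq)
    flows = {
        n: hf.habitat_flow(growth, info, n, 0.7)
        for n in ("hsi_closed", "hsi_intermediate", "hsi_open")
    }
    flows["pulp"] = hf.area_scaled_flow(growth, info, "pulp")
    return geoms, info, growth, flows


def random_schedule(growth: GrowthTable, seed: int) -> Schedule:
    rng = np.random.default_rng(seed)
    by = growth.regimes_by_stand()
    return Schedule({s: rs[rng.integers(len(rs))] for s, rs in by.items()})
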