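"""Habitat-suitability indices (HSI) and habitat-area flow components.

An HSI maps projected stand attributes (here, basal area in m2/ha as a
canopy-openness proxy) to a habitat-quality score. With the logistic option
on, the raw equation value is squashed through 1/(1+exp(-x)) so the final
score lies strictly in (0, 1). A stand x regime x period combination counts
as habitat when its HSI strictly exceeds a user threshold, and then
contributes its full acreage to the habitat-area flow; otherwise it
contributes zero — there is no partial credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import FlowTable, GrowthTable, StandInfo

__all__ = [
    "HSIEquation",
    "HabitatThreshold",
    "hsi_calc",
    "builtin_equations",
    "habitat_flow",
]


@dataclass(frozen=True)
class HSIEquation:
    """A habitat-suitability equation over growth-table attributes.

    ``raw_fn`` receives a mapping of attribute name -> pandas Series (the
    full table, vectorized) and returns the raw score; when ``logistic`` is
    true the raw score is passed through the standard logistic function,
    bounding the final HSI in (0, 1).
    """

    name: str
    raw_fn: Callable[[Mapping[str, pd.Series]], pd.Series]
    logistic: bool = True


@dataclass(frozen=True)
class HabitatThreshold:
    """HSI cutoff above which (strictly) a stand counts as habitat."""

    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


class _AttrView(dict):
    """Attribute-map view over a growth frame that fails with a clear name."""

    def __missing__(self, key: str):
        raise KeyError(f"HSI equation references unknown attribute {key!r}")


def hsi_calc(table: GrowthTable, eq: HSIEquation) -> GrowthTable:
    """Append an HSI column (named after ``eq``) to a growth table.

    Evaluates ``eq.raw_fn`` on every stand x regime x period record and, if
    ``eq.logistic``, maps raw values through 1/(1+exp(-raw)).
    """
    attrs = _AttrView({a: table.df[a] for a in table.attribute_names})
    raw = np.asarray(eq.raw_fn(attrs), dtype=float)
    if raw.shape != (len(table.df),):
        raw = np.broadcast_to(raw, (len(table.df),)).astype(float)
    if not np.isfinite(raw).all():
        raise ValueError(f"HSI equation {eq.name!r} produced non-finite raw values")
    if eq.logistic:
        with np.errstate(over="ignore"):
            values = 1.0 / (1.0 + np.exp(-raw))
    else:
        values = raw
    return table.with_column(eq.name, values)


def builtin_equations(
    a: float = 0.25, c: float = 14.0, m: float = 14.0, b: float = 2.0, q: float = 0.08
) -> tuple[HSIEquation, HSIEquation, HSIEquation]:
    """Three example HSI shapes keyed to basal area (column ``BA``).

    * ``closed`` — increasing in basal area (closed-canopy-associated
      species): raw = a*(BA - c).
    * ``intermediate`` — peaked at an intermediate basal area: raw =
      b - q*(BA - m)^2.
    * ``open`` — decreasing in basal area (open-canopy-associated species):
      raw = -a*(BA - c).

    Defaults span roughly (0.05, 0.95) after the logistic transform over
    basal areas of 0-28 m2/ha; they are illustrative, not species-specific,
    and fully overridable (or replace the equation wholesale via
    :class:`HSIEquation`).
    """
    closed = HSIEquation("hsi_closed", lambda d: a * (d["BA"] - c))
    intermediate = HSIEquation("hsi_intermediate", lambda d: b - q * (d["BA"] - m) ** 2)
    open_ = HSIEquation("hsi_open", lambda d: -a * (d["BA"] - c))
    return closed, intermediate, open_


def habitat_flow(
    table_with_hsi: GrowthTable,
    info: StandInfo,
    hsi_name: str,
    thr: HabitatThreshold | float,
) -> FlowTable:
    """Convert an HSI column into a habitat-area flow (acres).

    A record whose HSI strictly exceeds the threshold contributes the full
    stand area; any other record contributes 0. Every (stand, regime,
    period) triple of the input is present in the output.
    """
    if not isinstance(thr, HabitatThreshold):
        thr = HabitatThreshold(thr)
    if hsi_name not in table_with_hsi.attribute_names:
        raise KeyError(f"no HSI column named {hsi_name!r}")
    df = table_with_hsi.df
    hsi = df[hsi_name].to_numpy(dtype=float)
    if ((hsi < 0) | (hsi > 1)).any():
        raise ValueError(f"HSI column {hsi_name!r} has values outside [0, 1]")
    info.validate_against(table_with_hsi)
    area = df["stand_id"].map(info.areas).to_numpy(dtype=float)
    vals = np.where(hsi > thr.threshold, area, 0.0)
    values = dict(
        zip(zip(df["stand_id"], df["regime_id"], df["period"]), vals.tolist())
    )
    return FlowTable(name=hsi_name, values=values, units="acres")
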