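"""Flow components: target strings, per-period bands, and the deviation penalty.

A flow component couples a flow table with a *model string* of
``period,target`` pairs ("10,1000; 20,1000; 30,1000"), an allowable negative
deviation ``thlo`` and positive deviation ``thhi``. Targets given at a few
anchor periods are linearly interpolated to every period of the horizon
(constant-extended outside the anchors), forming a feasibility band
``[target - thlo, target + thhi]`` per period. The scheduler minimizes the
sum over components of a squared, target-normalized band violation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .core import FlowTable, Schedule

__all__ = [
    "FlowComponent",
    "TargetSeries",
    "parse_model_string",
    "interpolate_targets",
    "flow_output",
    "penalty",
]


def parse_model_string(s: str) -> list[tuple[int, float]]:
    """Parse a model string into ordered ``(period, target)`` pairs.

    Grammar: ``period,target`` pairs separated by semicolons, e.g.
    ``"1, 1000; 2, 2000"``. Whitespace-tolerant. Periods must be strictly
    increasing positive integers; targets non-negative reals.
    """
    if not s or not s.strip():
        raise ValueError("empty model string")
    pairs: list[tuple[int, float]] = []
    for token in s.split(";"):
        token = token.strip()
        if not token:
            raise ValueError(f"model string {s!r}: empty pair")
        m = re.fullmatch(r"(\d+)\s*,\s*([0-9.eE+-]+)", token)
        if m is None:
            raise ValueError(
                f"model string {s!r}: malformed pair {token!r} "
                "(expected 'period,target')"
            )
        period = int(m.group(1))
        try:
            target = float(m.group(2))
        except ValueError:
            raise ValueError(
                f"model string {s!r}: non-numeric target in {token!r}"
            ) from None
        if target < 0:
            raise ValueError(f"model string {s!r}: negative target {target}")
        if pairs and period <= pairs[-1][0]:
            raise ValueError(
                f"model string {s!r}: periods must be strictly increasing"
            )
        pairs.append((period, target))
    return pairs


def format_model_string(pairs: list[tuple[int, float]]) -> str:
    return "; ".join(f"{p},{t:g}" for p, t in pairs)


@dataclass(frozen=True)
class TargetSeries:
    """Per-period targets with a feasibility band derived from thlo/thhi."""

    targets: np.ndarray  # length nperiods
    thlo: float
    thhi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float))
        if self.thlo < 0 or self.thhi < 0:
            raise ValueError("thlo and thhi must be >= 0")

    @property
    def nperiods(self) -> int:
        return len(self.targets)

    @property
    def lower_bound(self) -> np.ndarray:
        return self.targets - self.thlo

    @property
    def upper_bound(self) -> np.ndarray:
        return self.targets + self.thhi


def interpolate_targets(
    pairs: list[tuple[int, float]], nperiods: int, thlo: float, thhi: float
) -> TargetSeries:
    """Expand anchor ``(period, target)`` pairs to a full target series.

    Piecewise-linear between consecutive anchors; constant extension before
    the first and after the last anchor.
    """
    if not pairs:
        raise ValueError("no (period, target) pairs")
    last = pairs[-1][0]
    if last > nperiods:
        raise ValueError(f"pair period {last} exceeds horizon nperiods={nperiods}")
    xp = np.array([p for p, _ in pairs], dtype=float)
    fp = np.array([t for _, t in pairs], dtype=float)
    periods = np.arange(1, nperiods + 1, dtype=float)
    targets = np.interp(periods, xp, fp)  # np.interp constant-extends
    return TargetSeries(targets=targets, thlo=thlo, thhi=thhi)


@dataclass(frozen=True)
class FlowComponent:
    """One scheduling objective: a flow plus its targets, band and weight."""

    name: str
    flow: FlowTable
    model: str
    thlo: float
    thhi: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.thlo < 0 or self.thhi < 0:
            raise ValueError(f"flow {self.name!r}: thlo/thhi must be >= 0")
        if self.weight < 0:
            raise ValueError(f"flow {self.name!r}: weight must be >= 0")
        parse_model_string(self.model)  # validate eagerly

    @cached_property
    def pairs(self) -> list[tuple[int, float]]:
        return parse_model_string(self.model)

    def target_series(self, nperiods: int) -> TargetSeries:
        return interpolate_targets(self.pairs, nperiods, self.thlo, self.thhi)


def flow_output(schedule: Schedule, flow: FlowTable, nperiods: int) -> np.ndarray:
    """Per-period totals of a flow under a schedule.

    ``output[t-1]`` sums the flow values of every stand under its assigned
    regime at period ``t``; a (stand, regime, period) key absent from the
    flow contributes 0. Assigning a stand a regime the flow has no keys for,
    while the flow does carry other regimes of that stand, is a
    schedule/flow mismatch and raises.
    """
    out = np.zeros(nperiods, dtype=float)
    regimes_seen: dict[str, set[str]] = {}
    for (sid, rid, per), v in flow.values.items():
        regimes_seen.setdefault(sid, set()).add(rid)
        if schedule.assignment.get(sid) == rid:
            out[per - 1] += v
    for sid, regs in regimes_seen.items():
        rid = schedule.assignment.get(sid)
        if rid is None:
            raise ValueError(f"schedule misses stand {sid!r} present in flow")
        if rid not in regs:
            raise ValueError(
                f"stand {sid!r}: assigned regime {rid!r} absent from flow "
                f"{flow.name!r} (flow has {sorted(regs)})"
            )
    return out


def penalty(outputs: np.ndarray, ts: TargetSeries, weight: float = 1.0) -> float:
    """Squared target-normalized band-violation penalty.

    For each period, the violation is the distance from the output to the
    band ``[target - thlo, target + thhi]``, divided by ``max(target, 1)``
    to make flows in acres and tons comparable; the penalty is ``weight``
    times the sum of squared normalized violations. Zero iff every period
    lies inside its band.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (ts.nperiods,):
        raise ValueError(
            f"outputs length {outputs.shape} != nperiods {ts.nperiods}"
        )
    below = ts.lower_bound - outputs
    above = outputs - ts.upper_bound
    viol = np.maximum(0.0, np.maximum(below, above))
    denom = np.maximum(ts.targets, 1.0)
    v = viol / denom
    return float(weight * np.dot(v, v))
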