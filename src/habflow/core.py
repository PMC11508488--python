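"""Domain types and file I/O for the harvest-scheduling data layer.

The data substrate is a *growth table*: one record per stand x management
regime x planning period holding projected outputs of a forest growth model
(basal area, harvested pulpwood tons per acre, or any other named attribute).
Flow files slice a single attribute out of that table; a project file bundles
the run configuration (number of stands, objective/flow parameters, iteration
budget) into XML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GrowthTable",
    "StandInfo",
    "FlowTable",
    "Schedule",
    "FlowSpec",
    "ProjectSpec",
    "read_growth_table",
    "read_stand_info",
    "write_stand_info",
    "write_growth_table",
    "read_flow_file",
    "write_flow_file",
    "write_project_file",
    "read_project_file",
    "parse_config_string",
    "format_config_string",
    "MAX_FLOW_COMPONENTS",
]

#: Upper bound on flow components a project file may carry.
MAX_FLOW_COMPONENTS = 10

_KEY_COLUMNS = ["stand_id", "regime_id", "period"]


class GrowthTableError(ValueError):
    """Raised when a growth table violates its structural invariants."""


@dataclass(frozen=True)
class GrowthTable:
    """Projected outputs for every stand x regime x period combination.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``stand_id`` (str), ``regime_id`` (str), ``period`` (int,
        1-based) plus one numeric column per projected attribute.
    nperiods : int
        Length of the planning horizon in periods; all ``period`` values
        must fall in ``[1, nperiods]``.
    """

    df: pd.DataFrame
    nperiods: int

    def __post_init__(self) -> None:
        _validate_growth_frame(self.df, self.nperiods)

    @property
    def attribute_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in _KEY_COLUMNS]

    @property
    def stand_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["stand_id"]))

    def regimes_for(self, stand_id: str) -> list[str]:
        sub = self.df.loc[self.df["stand_id"] == stand_id, "regime_id"]
        return list(dict.fromkeys(sub))

    def regimes_by_stand(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, rid in zip(self.df["stand_id"], self.df["regime_id"]):
            lst = out.setdefault(sid, [])
            if rid not in lst:
                lst.append(rid)
        return out

    def with_column(self, name: str, values: np.ndarray) -> "GrowthTable":
        """Return a copy with an extra attribute column (row-aligned)."""
        if len(values) != len(self.df):
            raise GrowthTableError(
                f"column {name!r} has {len(values)} values for {len(self.df)} rows"
            )
        df = self.df.copy()
        df[name] = np.asarray(values, dtype=float)
        return GrowthTable(df, self.nperiods)

    def flow(self, attribute: str, units: str = "") -> "FlowTable":
        """Extract one attribute as a flow component table."""
        if attribute not in self.attribute_names:
            raise KeyError(f"unknown attribute {attribute!r}")
        values = dict(
            zip(
                zip(self.df["stand_id"], self.df["regime_id"], self.df["period"]),
                self.df[attribute].astype(float),
            )
        )
        return FlowTable(name=attribute, values=values, units=units)

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "GrowthTable") -> bool:
        if self.nperiods != other.nperiods:
            return False
        a = self.df.sort_values(_KEY_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(_KEY_COLUMNS).reset_index(drop=True)
        return a.equals(b[a.columns]) if set(a.columns) == set(b.columns) else False


def _validate_growth_frame(df: pd.DataFrame, nperiods: int) -> None:
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise GrowthTableError(f"growth table missing required columns: {missing}")
    attrs = [c for c in df.columns if c not in _KEY_COLUMNS]
    if not attrs:
        raise GrowthTableError("growth table needs at least one attribute column")
    if nperiods < 1:
        raise GrowthTableError(f"nperiods must be >= 1, got {nperiods}")
    periods = df["period"].to_numpy()
    if not np.issubdtype(periods.dtype, np.integer):
        raise GrowthTableError("period column must be integer")
    if len(df) and (periods.min() < 1 or periods.max() > nperiods):
        bad = df.loc[(df["period"] < 1) | (df["period"] > nperiods)].index[0]
        raise GrowthTableError(
            f"row {bad}: period outside [1, {nperiods}]"
        )
    dup = df.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        row = df.loc[dup, _KEY_COLUMNS].iloc[0]
        raise GrowthTableError(
            f"duplicate (stand_id, regime_id, period) triple: "
            f"({row.stand_id}, {row.regime_id}, {row.period})"
        )
    for a in attrs:
        col = df[a]
        if not np.issubdtype(col.dtype, np.number):
            raise GrowthTableError(f"attribute column {a!r} is not numeric")
        if not np.isfinite(col.to_numpy(dtype=float)).all():
            raise GrowthTableError(f"attribute column {a!r} contains non-finite values")
    # every (stand, regime) must cover the same period set within its stand
    cov = df.groupby(["stand_id", "regime_id"])["period"].agg(frozenset)
    per_stand = cov.groupby(level=0).nunique()
    bad_stands = per_stand[per_stand > 1]
    if len(bad_stands):
        raise GrowthTableError(
            f"stand {bad_stands.index[0]!r}: regimes cover different period sets"
        )


@dataclass(frozen=True)
class StandInfo:
    """Stand areas keyed by stand ID, in acres."""

    areas: Mapping[str, float]

    def __post_init__(self) -> None:
        for sid, area in self.areas.items():
            if not (area > 0):
                raise ValueError(f"stand {sid!r}: area must be > 0, got {area}")

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def mean_area(self) -> float:
        return self.total_area / len(self.areas)

    def __len__(self) -> int:
        return len(self.areas)

    def __getitem__(self, stand_id: str) -> float:
        return self.areas[stand_id]

    def validate_against(self, table: GrowthTable) -> None:
        missing = set(table.stand_ids) - set(self.areas)
        if missing:
            raise ValueError(f"stands missing from stand info: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class FlowTable:
    """One objective's projected output per (stand, regime, period)."""

    name: str
    values: Mapping[tuple[str, str, int], float]
    units: str = ""

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"flow {self.name!r}: non-finite value at {key}")

    def __len__(self) -> int:
        return len(self.values)

    def periods(self) -> set[int]:
        return {p for (_, _, p) in self.values}

    def stand_ids(self) -> set[str]:
        return {s for (s, _, _) in self.values}


@dataclass(frozen=True)
class Schedule:
    """Assignment of exactly one management regime to every stand."""

    assignment: Mapping[str, str]

    def validate_against(self, table: GrowthTable) -> None:
        by_stand = table.regimes_by_stand()
        missing = set(by_stand) - set(self.assignment)
        if missing:
            raise ValueError(f"schedule misses stands: {sorted(missing)[:5]}")
        for sid, rid in self.assignment.items():
            if sid not in by_stand:
                raise ValueError(f"schedule stand {sid!r} not in growth table")
            if rid not in by_stand[sid]:
                raise ValueError(
                    f"stand {sid!r}: regime {rid!r} not available "
                    f"(has {by_stand[sid]})"
                )

    def __getitem__(self, stand_id: str) -> str:
        return self.assignment[stand_id]

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class FlowSpec:
    """Flow-form parameters for one component inside a project file."""

    name: str
    file: str
    model: str
    thlo: float
    thhi: float
    weight: float = 1.0


@dataclass(frozen=True)
class ProjectSpec:
    """Run information bundled into a project file.

    ``config`` follows the scheduler's configuration grammar: the flow count,
    then one pair of clearcut/block sub-component flags per flow, then three
    trailing flags for the unsupported Biol1/Biol2/spatial-model components.
    """

    npoly: int
    config: str
    iterations: int
    workdir: str
    flow_specs: tuple[FlowSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError(f"iterations must be > 0, got {self.iterations}")
        if not 1 <= len(self.flow_specs) <= MAX_FLOW_COMPONENTS:
            raise ValueError(
                f"number of flow components must be in "
                f"[1, {MAX_FLOW_COMPONENTS}], got {len(self.flow_specs)}"
            )
        n_flows, *_ = parse_config_string(self.config)
        if n_flows != len(self.flow_specs):
            raise ValueError(
                f"config declares {n_flows} flows but {len(self.flow_specs)} "
                "flow components given"
            )


def area_scaled_flow(
    table: GrowthTable, info: StandInfo, attribute: str, units: str = "tons"
) -> FlowTable:
    """Scale a per-acre attribute by stand area into a per-stand total flow.

    Yield attributes are projected per acre; multiplying by the stand's
    acreage gives the stand-level quantity the scheduler's targets are set
    in (e.g. pulpwood tons/acre -> tons).
    """
    if attribute not in table.attribute_names:
        raise KeyError(f"unknown attribute {attribute!r}")
    info.validate_against(table)
    df = table.df
    area = df["stand_id"].map(info.areas).to_numpy(dtype=float)
    vals = df[attribute].to_numpy(dtype=float) * area
    values = dict(
        zip(zip(df["stand_id"], df["regime_id"], df["period"]), vals.tolist())
    )
    return FlowTable(name=attribute, values=values, units=units)


# ---------------------------------------------------------------------------
# configuration-string grammar


def parse_config_string(s: str) -> tuple[int, list[tuple[int, int]], int, int, int]:
    """Parse a run-configuration string.

    The grammar is ``n_flows, <2 x n_flows pair flags>, biol1, biol2, spatial``
    — comma-separated integers, token count ``1 + 2*n_flows + 3``. The pair
    flags toggle clearcut and block-size sub-components per flow; this
    implementation supports none of the sub-components and rejects any
    nonzero flag.

    Returns ``(n_flows, pairs, biol1, biol2, spatial)``.
    """
    try:
        tokens = [int(t.strip()) for t in s.split(",")]
    except ValueError as e:
        raise ValueError(f"config string {s!r}: non-integer token ({e})") from None
    if not tokens:
        raise ValueError("empty config string")
    n_flows = tokens[0]
    if n_flows < 1:
        raise ValueError(f"config string {s!r}: flow count must be >= 1")
    expected = 1 + 2 * n_flows + 3
    if len(tokens) != expected:
        raise ValueError(
            f"config string {s!r}: expected {expected} tokens "
            f"(1 + 2*{n_flows} + 3), got {len(tokens)}"
        )
    flags = tokens[1:]
    if any(f != 0 for f in flags):
        raise ValueError(
            f"config string {s!r}: nonzero sub-component flag — clearcut, "
            "block, Biol1, Biol2 and spatial-model components are unsupported"
        )
    pairs = [(flags[2 * i], flags[2 * i + 1]) for i in range(n_flows)]
    return n_flows, pairs, flags[-3], flags[-2], flags[-1]


def format_config_string(n_flows: int) -> str:
    """Build the all-zero configuration string for ``n_flows`` components."""
    if not 1 <= n_flows <= MAX_FLOW_COMPONENTS:
        raise ValueError(f"n_flows must be in [1, {MAX_FLOW_COMPONENTS}]")
    return ",".join([str(n_flows)] + ["0"] * (2 * n_flows + 3))


# ---------------------------------------------------------------------------
# CSV I/O


def read_growth_table(path: str | Path, nperiods: int) -> GrowthTable:
    """Read a stand growth projection CSV.

    Required columns: ``stand_id``, ``regime_id``, ``period``; every further
    column is treated as a numeric projected attribute.
    """
    df = pd.read_csv(
        path, dtype={"stand_id": str, "regime_id": str}, float_precision="round_trip"
    )
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise GrowthTableError(f"{path}: missing required columns {missing}")
    try:
        df["period"] = df["period"].astype(int)
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df["period"], errors="coerce").isna()][0]
        raise GrowthTableError(f"{path}: row {bad + 2}: non-integer period") from None
    for col in df.columns:
        if col in _KEY_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.index[coerced.isna()][0]
            raise GrowthTableError(
                f"{path}: row {bad + 2}: non-numeric value in column {col!r}"
            )
        df[col] = coerced.astype(float)
    return GrowthTable(df, nperiods)


def write_growth_table(table: GrowthTable, path: str | Path) -> None:
    # %.17g guarantees binary round-trip of float64 attributes
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_stand_info(path: str | Path) -> StandInfo:
    """Read a stand-info CSV with columns ``stand_id`` and ``area`` (acres)."""
    df = pd.read_csv(path, dtype={"stand_id": str}, float_precision="round_trip")
    for col in ("stand_id", "area"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["stand_id"].duplicated().any():
        dup = df.loc[df["stand_id"].duplicated(), "stand_id"].iloc[0]
        raise ValueError(f"{path}: duplicate stand_id {dup!r}")
    areas = dict(zip(df["stand_id"], df["area"].astype(float)))
    return StandInfo(areas)


def write_stand_info(info: StandInfo, path: str | Path) -> None:
    pd.DataFrame(
        {"stand_id": list(info.areas), "area": list(info.areas.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flow files: long-format text, one row per (stand, regime, period, value)


def write_flow_file(flow: FlowTable, path: str | Path) -> None:
    """Write a flow component to a long-format text file.

    Layout: an optional ``#`` comment header carrying name/units, then one
    ``stand_id regime_id period value`` row per entry.
    """
    with open(path, "w") as fh:
        fh.write(f"# flow: {flow.name}\n")
        fh.write(f"# units: {flow.units}\n")
        for (sid, rid, per), v in flow.values.items():
            fh.write(f"{sid} {rid} {per} {v!r}\n")


def read_flow_file(path: str | Path, name: str | None = None) -> FlowTable:
    """Read a long-format flow file written by :func:`write_flow_file`."""
    values: dict[tuple[str, str, int], float] = {}
    file_name, units = Path(path).stem, ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("flow:"):
                    file_name = body[5:].strip()
                elif body.startswith("units:"):
                    units = body[6:].strip()
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields "
                    f"'stand regime period value', got {len(parts)}"
                )
            sid, rid, per_s, val_s = parts
            try:
                per, val = int(per_s), float(val_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric period or value"
                ) from None
            values[(sid, rid, per)] = val
    return FlowTable(name=name or file_name, values=values, units=units)


# ---------------------------------------------------------------------------
# project file (XML)


def write_project_file(spec: ProjectSpec, path: str | Path) -> None:
    """Serialize a :class:`ProjectSpec` to a self-describing XML project file."""
    root = ET.Element("project")
    ET.SubElement(root, "npoly").text = str(spec.npoly)
    ET.SubElement(root, "config").text = spec.config
    ET.SubElement(root, "iterations").text = str(spec.iterations)
    ET.SubElement(root, "workdir").text = spec.workdir
    flows = ET.SubElement(root, "flows")
    for fs in spec.flow_specs:
        el = ET.SubElement(flows, "flow", name=fs.name)
        ET.SubElement(el, "file").text = fs.file
        ET.SubElement(el, "model").text = fs.model
        ET.SubElement(el, "thlo").text = repr(fs.thlo)
        ET.SubElement(el, "thhi").text = repr(fs.thhi)
        ET.SubElement(el, "weight").text = repr(fs.weight)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_project_file(path: str | Path) -> ProjectSpec:
    root = ET.parse(path).getroot()

    def text(el: ET.Element | None, what: str) -> str:
        if el is None or el.text is None:
            raise ValueError(f"{path}: missing element {what!r}")
        return el.text

    flow_specs = tuple(
        FlowSpec(
            name=el.get("name", ""),
            file=text(el.find("file"), "file"),
            model=text(el.find("model"), "model"),
            thlo=float(text(el.find("thlo"), "thlo")),
            thhi=float(text(el.find("thhi"), "thhi")),
            weight=float(text(el.find("weight"), "weight")),
        )
        for el in root.findall("./flows/flow")
    )
    return ProjectSpec(
        npoly=int(text(root.find("npoly"), "npoly")),
        config=text(root.find("config"), "config"),
        iterations=int(text(root.find("iterations"), "iterations")),
        workdir=text(root.find("workdir"), "workdir"),
        flow_specs=flow_specs,
    )
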