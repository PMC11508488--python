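"""End-to-end orchestration: data -> flows -> sweep -> selection -> maps.

The pipeline mirrors the four-step planning workflow: (1) collate (or
synthesize) stand data, (2) build flow files from HSI columns and the
pulpwood yield, (3) run the target sweep with the Metropolis-Hastings
sampler, (4) select per-objective solutions and analyze their habitat
patches. Every artifact lands under the working directory and is listed
with a content hash in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, hsi as hsi_mod, spatial as spatial_mod, synthgen
from .core import FlowSpec, ProjectSpec, format_config_string
from .experiment import SweepSpec, mean_output, run_sweep, select_solutions
from .objectives import FlowComponent
from .scheduler import MHConfig

__all__ = ["RunConfig", "run_pipeline", "template_config", "load_config"]

HSI_FLOW_NAMES = ("hsi_closed", "hsi_intermediate", "hsi_open")
PULP_FLOW_NAME = "pulp"


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``n_stands`` (synthetic landscape + growth) or ``inputs`` (paths
    to growth CSV, stand-info CSV and GeoJSON geometry) must be given.
    """

    workdir: str | Path
    seed: int = 1
    nperiods: int = synthgen.TEMPLATE_NPERIODS
    # synthetic inputs
    n_stands: int | None = None
    extent_acres: float = 17_774.0
    # or external inputs
    inputs: dict | None = None  # keys: growth, stand_info, geometry
    hsi_threshold: float = 0.7
    hsi_levels: list = field(default_factory=lambda: [[1000.0, 1000.0]])
    pulp_steps: list = field(default_factory=lambda: [[1000.0, 5000.0]])
    thlo: float = 1000.0
    anchor_periods: tuple = (10, 20, 30)
    iterations: int = 10_000
    temperature: float = 1.0
    cooling: float = 1.0
    avian_dist: float = 500.0  # closed-canopy species travel distance (m)
    plots: bool = True

    def sweep_spec(self) -> SweepSpec:
        return SweepSpec(
            hsi_levels=[tuple(x) for x in self.hsi_levels],
            pulp_steps=[tuple(x) for x in self.pulp_steps],
            hsi_flow_names=HSI_FLOW_NAMES,
            pulp_flow_name=PULP_FLOW_NAME,
            thlo=self.thlo,
            anchor_periods=tuple(self.anchor_periods),
            mh=MHConfig(
                iterations=self.iterations,
                temperature=self.temperature,
                cooling=self.cooling,
                seed=self.seed,
            ),
        )

    #: per-flow patch aggregation modes: the closed-canopy species is
    #: treated as avian (within-distance connectivity), the other two as
    #: terrestrial (shared-boundary adjacency).
    def spatial_params(self) -> dict[str, spatial_mod.SpatialParams]:
        return {
            "hsi_closed": spatial_mod.SpatialParams(mode="avian", dist=self.avian_dist),
            "hsi_intermediate": spatial_mod.SpatialParams(mode="terrestrial"),
            "hsi_open": spatial_mod.SpatialParams(mode="terrestrial"),
        }


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def template_config(
    workdir: str | Path,
    n_stands: int = 100,
    n_hsi_levels: int = 5,
    n_pulp_steps: int = 20,
    iterations: int = 2_000,
    seed: int = 1,
    plots: bool = True,
) -> RunConfig:
    """A scaled-down copy of the case-study configuration.

    Same 5 x 20 sweep grammar (HSI targets 1,000-5,000 acres with thhi =
    target; pulpwood targets 1,000 tons and thhi 5,000 tons per step; thlo
    1,000) but on a synthetic landscape of ``n_stands`` stands whose extent
    keeps the case study's 35.2-acre mean stand area.
    """
    return RunConfig(
        workdir=workdir,
        seed=seed,
        n_stands=n_stands,
        extent_acres=n_stands * 35.2,
        hsi_levels=[[1000.0 * k, 1000.0 * k] for k in range(1, n_hsi_levels + 1)],
        pulp_steps=[[1000.0 * k, 5000.0 * k] for k in range(1, n_pulp_steps + 1)],
        iterations=iterations,
        plots=plots,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _collate(config: RunConfig, wd: Path, manifest: list[Path]):
    """Step 1: obtain stand geometry, areas and growth projections."""
    if config.inputs is not None:
        growth = core.read_growth_table(config.inputs["growth"], config.nperiods)
        info = core.read_stand_info(config.inputs["stand_info"])
        geoms = spatial_mod.read_geojson(config.inputs["geometry"])
        info.validate_against(growth)
        return growth, info, geoms
    if config.n_stands is None:
        raise ValueError("config needs either n_stands (synthetic) or inputs")
    side = float(np.sqrt(config.extent_acres * synthgen.ACRE_M2))
    lspec = synthgen.LandscapeSpec(
        n_stands=config.n_stands, extent=(0.0, 0.0, side, side), seed=config.seed
    )
    geoms, info = synthgen.generate_landscape(lspec)
    growth = synthgen.project_growth(
        info, synthgen.default_regimes(config.nperiods), config.nperiods, seed=config.seed
    )
    core.write_growth_table(growth, wd / "growth.csv")
    core.write_stand_info(info, wd / "stands.csv")
    spatial_mod.write_geojson(geoms, wd / "stands.geojson", info)
    manifest += [wd / "growth.csv", wd / "stands.csv", wd / "stands.geojson"]
    return growth, info, geoms


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk)."""
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    try:
        growth, info, geoms = _collate(config, wd, manifest)
    except Exception as e:
        raise RuntimeError(f"step 1 (collate stand data) failed: {e}") from e

    # --- step 2: HSI columns and flow files -------------------------------
    try:
        for eq in hsi_mod.builtin_equations():
            growth = hsi_mod.hsi_calc(growth, eq)
        core.write_growth_table(growth, wd / "growth_with_hsi.csv")
        manifest.append(wd / "growth_with_hsi.csv")
        flows = {
            name: hsi_mod.habitat_flow(growth, info, name, config.hsi_threshold)
            for name in HSI_FLOW_NAMES
        }
        flows[PULP_FLOW_NAME] = core.area_scaled_flow(growth, info, PULP_FLOW_NAME)
        for name, flow in flows.items():
            core.write_flow_file(flow, wd / f"{name}.flow")
            manifest.append(wd / f"{name}.flow")
    except Exception as e:
        raise RuntimeError(f"step 2 (flow files) failed: {e}") from e

    # --- step 3: project file and the target sweep ------------------------
    try:
        spec = config.sweep_spec()
        components = [
            FlowComponent(
                name=name,
                flow=flows[name],
                model="; ".join(f"{p},{spec.hsi_levels[0][0]:g}" for p in spec.anchor_periods)
                if name != PULP_FLOW_NAME
                else "; ".join(f"{p},{spec.pulp_steps[0][0]:g}" for p in spec.anchor_periods),
                thlo=spec.thlo,
                thhi=spec.hsi_levels[0][1] if name != PULP_FLOW_NAME else spec.pulp_steps[0][1],
            )
            for name in (*HSI_FLOW_NAMES, PULP_FLOW_NAME)
        ]
        project = ProjectSpec(
            npoly=len(info),
            config=format_config_string(len(components)),
            iterations=spec.mh.iterations,
            workdir=str(wd),
            flow_specs=tuple(
                FlowSpec(c.name, f"{c.name}.flow", c.model, c.thlo, c.thhi, c.weight)
                for c in components
            ),
        )
        core.write_project_file(project, wd / "project.xml")
        manifest.append(wd / "project.xml")

        traces = run_sweep(components, growth, spec)
        summary_rows = []
        for k, tr in enumerate(traces, start=1):
            out_df = pd.DataFrame(
                {"period": np.arange(1, growth.nperiods + 1)}
                | {name: tr.outputs[name] for name in tr.outputs}
            )
            out_df.to_csv(wd / f"outputs_{k:03d}.csv", index=False)
            manifest.append(wd / f"outputs_{k:03d}.csv")
            summary_rows.append(
                {
                    "run": k,
                    "best_energy": tr.best_energy,
                    "acceptance_rate": tr.acceptance_rate,
                    **{f"mean_{n}": mean_output(tr, n) for n in tr.outputs},
                }
            )
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(wd / "sweep_summary.csv", index=False)
        manifest.append(wd / "sweep_summary.csv")
    except Exception as e:
        raise RuntimeError(f"step 3 (target sweep) failed: {e}") from e

    # --- step 4: solution selection and spatial analysis ------------------
    try:
        solset = select_solutions(traces, components)
        solset.mean_outputs.to_csv(wd / "solutions.csv")
        solset.deviations.to_csv(wd / "deviations.csv")
        manifest += [wd / "solutions.csv", wd / "deviations.csv"]
        spatial_params = config.spatial_params()
        for name in HSI_FLOW_NAMES:
            sched = solset.schedules[name]
            pd.DataFrame(
                sorted(sched.assignment.items()), columns=["stand_id", "regime_id"]
            ).to_csv(wd / f"schedule_{name}.csv", index=False)
            manifest.append(wd / f"schedule_{name}.csv")
            patchsets = spatial_mod.patches_per_period(
                sched, flows[name], geoms, spatial_params[name], growth.nperiods
            )
            spatial_mod.patch_summary(patchsets).to_csv(
                wd / f"patch_summary_{name}.csv", index=False
            )
            manifest.append(wd / f"patch_summary_{name}.csv")
            spatial_mod.write_patches_geojson(
                patchsets, geoms, wd / f"patches_{name}.geojson"
            )
            manifest.append(wd / f"patches_{name}.geojson")
        if config.plots:
            _plot_trajectories(traces, components, solset, growth.nperiods, wd)
            manifest.append(wd / "flow_trajectories.png")
    except Exception as e:
        raise RuntimeError(f"step 4 (solution selection) failed: {e}") from e

    manifest_data = {
        "workdir": str(wd),
        "seed": config.seed,
        "n_runs": len(traces),
        "files": {p.name: _sha256(p) for p in manifest},
    }
    (wd / "manifest.json").write_text(json.dumps(manifest_data, indent=2))
    return manifest_data


def _plot_trajectories(traces, components, solset, nperiods, wd: Path) -> None:
    """Per-flow output trajectories: grey = all runs, colored = solutions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [c.name for c in components]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    periods = np.arange(1, nperiods + 1)
    colors = ["tab:blue", "tab:orange", "tab:green", "tab:red"]
    for ax, name in zip(axes.ravel(), names):
        for tr in traces:
            ax.plot(periods, tr.outputs[name], color="0.8", lw=0.5, zorder=1)
        for i, win_name in enumerate(names):
            tr = traces[solset.winners[win_name]]
            ax.plot(
                periods,
                tr.outputs[name],
                color=colors[i % len(colors)],
                lw=1.5,
                zorder=2,
                label=f"solution {i + 1} ({win_name})",
            )
        ax.set_title(name)
        ax.set_xlabel("period")
        ax.set_ylabel("output")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(wd / "flow_trajectories.png", dpi=120)
    plt.close(fig)
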