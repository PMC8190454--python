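"""Scenario specifications, built-in experiment designs, and result I/O.

A :class:`ScenarioSpec` captures everything needed to reproduce one
experiment — parameters, initial-condition recipe, grids, variant knobs,
simulation settings, and the RNG seed — and serializes to a flat YAML file.
The built-in scenarios encode the standard experimental designs of the
analysis: the two stability phase diagrams, the two basin-of-attraction
panels, the migration (local-adaptation) experiment, and the multispecies
acquisition sweep.

``run_scenario`` dispatches a spec to the appropriate module and writes a
tidy CSV plus a JSON metadata sidecar (parameters, tolerances, seed, code
version, wall-clock time).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import SimulationSettings, basin_map
from .equilibria import phase_sweep
from .model import ModelParameters
from .multispecies import MultiSpeciesParameters, acquisition_sweep
from .variants import migration_outcome_map

__all__ = ["ScenarioSpec", "builtin_scenarios", "run_scenario",
           "SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

#: Version of the output CSV/JSON schema.
SCHEMA_VERSION = 1

_KINDS = ("phase_sweep", "basin", "migration", "multispecies")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully reproducible experiment specification.

    ``kind`` selects the dispatch target; ``options`` carries the
    kind-specific design (axes, grids, panel, totals, rate lists).  All
    randomness flows from ``seed``.
    """

    name: str
    kind: str
    params: ModelParameters = field(default_factory=ModelParameters)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    options: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "params": self.params.to_dict(),
            "settings": asdict(self.settings),
            "options": self.options,
            "seed": self.seed,
            "schema_version": SCHEMA_VERSION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(name=d["name"], kind=d["kind"],
                   params=ModelParameters.from_dict(d.get("params", {})),
                   settings=SimulationSettings(**d.get("settings", {})),
                   options=dict(d.get("options", {})),
                   seed=d.get("seed"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """Ready-made specs for the standard experiments.

    All use the main illustrative parameter set (λ=1, γ=1, s=0.005,
    cP=0.075, β=0.2, A=1, cR=0.05) as the base.
    """
    base = ModelParameters()
    specs = [
        ScenarioSpec(
            name="phase-A-cR", kind="phase_sweep",
            params=base,
            options={"axis1": {"name": "A", "start": 0.0, "stop": 2.0,
                               "num": 61},
                     "axis2": {"name": "cR", "start": 0.0, "stop": 0.5,
                               "num": 61}}),
        ScenarioSpec(
            name="phase-beta-cP", kind="phase_sweep",
            params=base,
            options={"axis1": {"name": "beta", "start": 0.0, "stop": 0.25,
                               "num": 61},
                     "axis2": {"name": "cP", "start": 0.0, "stop": 0.5,
                               "num": 61}}),
        ScenarioSpec(
            name="basin-panel-A", kind="basin", params=base,
            options={"panel": "A", "grid": 41,
                     "sensitive_total": 1.0, "resistant_total": 1.0}),
        ScenarioSpec(
            name="basin-panel-B", kind="basin", params=base,
            options={"panel": "B", "grid": 41,
                     "sensitive_total": 1.0, "resistant_total": 1.0}),
        ScenarioSpec(
            name="migration", kind="migration", params=base,
            options={"mu_values": [1e-1, 1e-2], "grid": 41}),
        ScenarioSpec(
            name="multispecies", kind="multispecies",
            options={"n_values": [2, 5, 10, 20],
                     "ratios": [0.1, 1.0, 10.0, 100.0],
                     "m": 1e-6, "c": 1e-5, "t_freq": 0.1,
                     "n_realizations": 1000},
            seed=1),
    ]
    return {s.name: s for s in specs}


def _axis(opt: dict) -> tuple[str, np.ndarray]:
    return opt["name"], np.linspace(opt["start"], opt["stop"], int(opt["num"]))


def _dispatch(spec: ScenarioSpec, grid: int | None) -> pd.DataFrame:
    opts = spec.options
    if spec.kind == "phase_sweep":
        ax1, ax2 = dict(opts["axis1"]), dict(opts["axis2"])
        if grid is not None:
            ax1["num"] = ax2["num"] = grid
        return phase_sweep(spec.params, _axis(ax1), _axis(ax2))
    if spec.kind == "basin":
        g = grid or int(opts.get("grid", 41))
        totals = (float(opts.get("sensitive_total", 1.0)),
                  float(opts.get("resistant_total", 1.0)))
        return basin_map(opts["panel"], spec.params, grid=g, totals=totals,
                         settings=spec.settings)
    if spec.kind == "migration":
        g = grid or int(opts.get("grid", 41))
        frames = [migration_outcome_map(spec.params, mu=float(mu), grid=g,
                                        settings=spec.settings)
                  for mu in opts["mu_values"]]
        return pd.concat(frames, ignore_index=True)
    if spec.kind == "multispecies":
        base = MultiSpeciesParameters(
            n=int(opts.get("n_values", [10])[0]),
            m=float(opts.get("m", 1e-6)), c=float(opts.get("c", 1e-5)),
            p=float(opts.get("c", 1e-5)) * 10.0,
            t_freq=float(opts.get("t_freq", 0.1)))
        return acquisition_sweep(
            [int(n) for n in opts["n_values"]],
            [float(r) for r in opts["ratios"]],
            base=base,
            n_realizations=int(opts.get("n_realizations", 1000)),
            seed=spec.seed)
    raise ValueError(f"unknown scenario kind {spec.kind!r}")


def run_scenario(spec: ScenarioSpec | str, outdir: str | Path | None = None,
                 grid: int | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Run a scenario (by spec or built-in name) and optionally write results.

    Writes ``<name>.csv`` (tidy results) and ``<name>.meta.json`` (full spec,
    code version, schema version, wall-clock seconds) into ``outdir`` when
    given.  ``grid`` overrides the spec's grid resolution, which is how tests
    and quick looks scale the built-in designs down.

    Returns the results DataFrame and the metadata dict.
    """
    if isinstance(spec, str):
        try:
            spec = builtin_scenarios()[spec]
        except KeyError:
            raise KeyError(
                f"unknown scenario {spec!r}; built-ins: "
                f"{sorted(builtin_scenarios())}") from None

    logger.info("running scenario %s (kind=%s)", spec.name, spec.kind)
    t0 = time.perf_counter()
    df = _dispatch(spec, grid)
    elapsed = time.perf_counter() - t0
    logger.info("scenario %s finished in %.2f s (%d rows)",
                spec.name, elapsed, len(df))

    meta = {
        "spec": spec.to_dict(),
        "grid_override": grid,
        "code_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "n_rows": int(len(df)),
        "wall_clock_seconds": elapsed,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / f"{spec.name}.csv", index=False)
        (outdir / f"{spec.name}.meta.json").write_text(
            json.dumps(meta, indent=2))
    return df, meta
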