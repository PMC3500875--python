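"""Readers, writers, run configuration and manifests (the shell layer).

File conventions: comma-separated CSV with mandatory header, "." decimal,
UTF-8, times as decimal floating point; JSON for models, graphs and
manifests; YAML or JSON for scenarios.  All JSON/YAML schemas carry a
"schema" field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dpa import CountingProcessData
from .errors import ValidationError
from .increments import PanelData
from .ligraph import LocalIndependenceGraph
from .sdeflow import LinearSDEModel
from .synthgen import MediationScenario, PanelScenario

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_counting_process_csv",
    "write_counting_process_csv",
    "read_panel_csv",
    "write_panel_csv",
    "read_model_json",
    "write_model_json",
    "read_graph_json",
    "write_graph_json",
    "read_scenario",
    "write_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration shared by CLI subcommands."""

    output_dir: Path
    seed: int = 0
    tolerances: Mapping[str, float] = field(default_factory=dict)
    verbosity: int = logging.WARNING

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValidationError("seed must be a nonnegative integer")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    def ensure_output_dir(self) -> Path:
        self.output_dir.mkdir(parents=True, exist_ok=True)
        return self.output_dir


def _require_file(path) -> Path:
    path = Path(path)
    if not path.is_file():
        raise ValidationError(f"input file not found: {path}")
    return path


# ---------------------------------------------------------------------------
# counting-process data
# ---------------------------------------------------------------------------


def read_counting_process_csv(path) -> CountingProcessData:
    """Read long-format counting-process data (id,start,stop,event,covariates)."""
    path = _require_file(path)
    table = pd.read_csv(path)
    try:
        return CountingProcessData(table)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_counting_process_csv(data: CountingProcessData, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panel data
# ---------------------------------------------------------------------------


def read_panel_csv(path, layout: str = "wide") -> PanelData:
    """Read panel data; ``layout`` is 'wide' (id,time,var columns) or 'long'
    (id,time,variable,value).  Both produce the same canonical object."""
    path = _require_file(path)
    table = pd.read_csv(path)
    if layout == "long":
        for c in ("id", "time", "variable", "value"):
            if c not in table.columns:
                raise ValidationError(f"{path}: long layout needs column {c!r}")
        if table.duplicated(["id", "time", "variable"]).any():
            raise ValidationError(f"{path}: duplicate (id, time, variable) entries")
        wide = table.pivot_table(
            index=["id", "time"], columns="variable", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        # keep first-appearance variable order from the long file
        var_order = list(pd.unique(table["variable"]))
        wide = wide[["id", "time"] + var_order]
    elif layout == "wide":
        wide = table
    else:
        raise ValidationError(f"layout must be 'wide' or 'long', got {layout!r}")
    try:
        return PanelData.from_frame(wide)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_panel_csv(panel: PanelData, path, layout: str = "wide") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    panel.to_frame(layout).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# models, graphs, scenarios
# ---------------------------------------------------------------------------


def read_model_json(path) -> LinearSDEModel:
    path = _require_file(path)
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        return LinearSDEModel.from_json_dict(obj)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_model_json(model: LinearSDEModel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_json_dict(), fh, indent=2)
        fh.write("\n")


def read_graph_json(path) -> LocalIndependenceGraph:
    path = _require_file(path)
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        return LocalIndependenceGraph.from_json_dict(obj)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_graph_json(graph: LocalIndependenceGraph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph.to_json_dict(), fh, indent=2)
        fh.write("\n")


def read_scenario(path) -> MediationScenario | PanelScenario:
    """Read a simulator scenario from YAML or JSON (dispatch on "kind")."""
    path = _require_file(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            obj = yaml.safe_load(fh)
        else:
            obj = json.load(fh)
    if not isinstance(obj, Mapping):
        raise ValidationError(f"{path}: scenario file must contain a mapping")
    kind = obj.get("kind")
    try:
        if kind == "mediation_survival":
            return MediationScenario.from_dict(obj)
        if kind == "coupled_panel":
            return PanelScenario.from_dict(obj)
    except (TypeError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    raise ValidationError(
        f"{path}: unknown scenario kind {kind!r} "
        "(expected 'mediation_survival' or 'coupled_panel')"
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(
    output_dir,
    command: str,
    inputs: Mapping,
    seed: int | None = None,
    outputs: Sequence[str] = (),
    skipped_times: Mapping[str, Sequence[float]] | None = None,
) -> Path:
    """Machine-readable record sufficient to re-run a CLI invocation."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema": "dynpath-manifest/1",
        "version": __version__,
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "outputs": [str(o) for o in outputs],
        "skipped_times": {k: list(map(float, v)) for k, v in (skipped_times or {}).items()},
    }
    path = output_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
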