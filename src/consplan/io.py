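"""Readers and writers for landscape layers, tables, and configs.

Grids round-trip losslessly at double precision through both backends:
single-band float64 TIFF (100 m pixel resolution tags; a placeholder
georeference, adequate for a synthetic landscape) and plain delimited
text. Planning-unit tables are CSV (see aggregation module); configs are
YAML or JSON mappings of LandscapeConfig / ScenarioGrid fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .errors import ConfigError
from .landscape import FineLandscape, LandscapeConfig


def write_grid_tiff(path, grid: np.ndarray) -> None:
    """Single-band float64 TIFF, 100 m (1-ha) pixels."""
    tifffile.imwrite(
        path, np.asarray(grid, dtype=np.float64),
        resolution=(1 / 100, 1 / 100), resolutionunit="CENTIMETER",
    )


def read_grid_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_grid_text(path, grid: np.ndarray) -> None:
    """Whitespace-delimited text grid, full double precision."""
    np.savetxt(path, np.asarray(grid, dtype=np.float64), fmt="%.17g")


def read_grid_text(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.float64, ndmin=2)


_GRID_IO = {
    "tiff": (write_grid_tiff, read_grid_tiff, ".tif"),
    "text": (write_grid_text, read_grid_text, ".txt"),
}


def write_landscape(directory, landscape: FineLandscape,
                    fmt: str = "tiff") -> list[Path]:
    """Write the cost layer and every occupancy layer to ``directory``.

    Returns the written paths (cost first, then species in table order).
    """
    if fmt not in _GRID_IO:
        raise ConfigError(f"unknown grid format {fmt!r}")
    writer, _, ext = _GRID_IO[fmt]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / f"cost{ext}"]
    writer(paths[0], landscape.cost_fine)
    for sid, layer in zip(landscape.species_ids, landscape.occupancy_fine):
        p = directory / f"occupancy_{sid}{ext}"
        writer(p, layer)
        paths.append(p)
    return paths


# --- configuration files ------------------------------------------------

def landscape_config_to_dict(config: LandscapeConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["species_cv_range"] = list(d["species_cv_range"])
    return d


def landscape_config_from_dict(data: dict[str, Any]) -> LandscapeConfig:
    fields = {f.name for f in dataclasses.fields(LandscapeConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown landscape config keys: {sorted(unknown)}")
    if "species_cv_range" in data:
        data = dict(data)
        data["species_cv_range"] = tuple(data["species_cv_range"])
    return LandscapeConfig(**data)


def load_config_file(path) -> dict[str, Any]:
    """Load a YAML or JSON mapping; .json parses as JSON, else YAML."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def load_landscape_config(path, **overrides) -> LandscapeConfig:
    """LandscapeConfig from a YAML/JSON file, with keyword overrides
    (CLI flags) taking precedence; None overrides are ignored."""
    data = load_config_file(path)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return landscape_config_from_dict(data)
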