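"""Grid configuration: classifier families and parameter grids.

The default grid ships as ``data/default_grid.yaml``; users can supply
their own YAML with the same shape.  :func:`expand_grid` turns a config
into the explicit list of :class:`~seqqc.modeling.ModelSpec`
combinations (feature-selection setting × algorithm × parameter set).
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_grid", "expand_grid", "DEFAULT_GRID_RESOURCE"]

DEFAULT_GRID_RESOURCE = "default_grid.yaml"


def load_grid(path: str | Path | None = None) -> dict:
    """Load a grid config; the shipped default when ``path`` is None."""
    if path is None:
        text = resources.files("seqqc.data").joinpath(DEFAULT_GRID_RESOURCE).read_text()
    else:
        text = Path(path).read_text()
    grid = yaml.safe_load(text)
    if not grid.get("algorithms"):
        raise ValueError("grid config must list at least one algorithm")
    grid.setdefault("feature_selection", [{"method": "none", "k": 1.0}])
    return grid


def expand_grid(grid: dict) -> list["ModelSpec"]:
    """Expand a grid config into all (selection × algorithm × params) specs."""
    from seqqc.modeling import ModelSpec  # circular-import guard

    specs: list[ModelSpec] = []
    for fs in grid["feature_selection"]:
        for algo, param_grid in grid["algorithms"].items():
            param_grid = param_grid or {}
            names = sorted(param_grid)
            for combo in itertools.product(*(param_grid[n] for n in names)) if names else [()]:
                params = {
                    n: tuple(v) if isinstance(v, list) else v
                    for n, v in zip(names, combo)
                }
                specs.append(
                    ModelSpec(
                        algorithm=algo,
                        params=params,
                        selection=fs["method"],
                        k_fraction=float(fs["k"]),
                    )
                )
    return specs
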