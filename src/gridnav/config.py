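"""Config-file and CSV interfaces.

YAML config schema::

    axis_separation_rad: 1.0471975511965976   # optional, default π/3
    seed: 0                                   # optional
    modules:
      - {scale_cm: 50, orientation_rad: 0.0, cells_per_axis: 32, ellipticity: 1.0}
      - {scale_cm: 30}
      - {scale_cm: 20}

Location CSV: header ``id,x_cm,y_cm``, one row per location, decimal
point, no thousands separators.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import yaml

from .gridcode import GridModule, GridSystem, Location


def system_from_dict(cfg: dict) -> tuple[GridSystem, int]:
    """Build a GridSystem (plus seed) from a parsed config mapping."""
    sep = float(cfg.get("axis_separation_rad", math.pi / 3))
    seed = int(cfg.get("seed", 0))
    mods = []
    for m in cfg["modules"]:
        mods.append(
            GridModule(
                scale=float(m["scale_cm"]),
                orientation=float(m.get("orientation_rad", 0.0)),
                axis_separation=float(m.get("axis_separation_rad", sep)),
                ellipticity=float(m.get("ellipticity", 1.0)),
                cells_per_axis=int(m.get("cells_per_axis", 32)),
            )
        )
    shared = all(
        abs(m.orientation - mods[0].orientation) <= 1e-12
        and abs(m.axis_separation - mods[0].axis_separation) <= 1e-12
        for m in mods
    )
    return GridSystem(modules=tuple(mods), shared_axes=shared), seed


def load_config(path: str | Path) -> tuple[GridSystem, int]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return system_from_dict(cfg)


def read_locations_csv(path: str | Path) -> dict[str, Location]:
    """Read a location table; returns id → Location."""
    df = pd.read_csv(path)
    expected = ["id", "x_cm", "y_cm"]
    if list(df.columns) != expected:
        raise ValueError(f"location CSV must have columns {expected}, got {list(df.columns)}")
    return {
        str(r.id): Location(float(r.x_cm), float(r.y_cm)) for r in df.itertuples()
    }
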