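"""Ecological resistance surface: factor overlay plus terrain correction.

Each cell gets a base resistance by a single-value precedence overlay
(hub > core/bridge importance level > water sub-type > river/lake 100 m
buffer > land use), then the terrain correction R' = R x (1 + i) with i the
slope as a fraction (a 50 % slope multiplies resistance by 1.5).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .grid import WATER_CLASSES, Grid, LandUse, check_congruent
from .mspa import MspaClass
from .patches import HubSet, Patch

#: factor values for the land-use / MSPA overlay (shipped default)
DEFAULT_LANDUSE_FACTORS: dict[str, float] = {
    "river": 200.0,
    "lake": 150.0,
    "other_water": 100.0,
    "farmland": 50.0,
    "bareland": 70.0,
    "forest": 30.0,
    "road": 250.0,
    "construction": 300.0,
}
DEFAULT_LEVEL_FACTORS: dict[str, float] = {
    "extremely important": 1.0,
    "important": 10.0,
    "general": 20.0,
}

_CODE_TO_NAME = {
    int(LandUse.CONSTRUCTION): "construction",
    int(LandUse.RIVER): "river",
    int(LandUse.LAKE): "lake",
    int(LandUse.OTHER_WATER): "other_water",
    int(LandUse.FOREST): "forest",
    int(LandUse.BARELAND): "bareland",
    int(LandUse.FARMLAND): "farmland",
    int(LandUse.ROAD): "road",
}


@dataclass
class ResistanceFactorTable:
    """Base resistance per factor; every value must be >= 1.

    ``level_factors`` applies to core and bridge patches by importance level;
    ``hub_value`` overrides cells of selected hub patches; the water buffer
    value applies to non-water cells within ``buffer_distance_m`` of river or
    lake cells when it is lower than their land-use value.
    """

    landuse: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LANDUSE_FACTORS))
    levels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVEL_FACTORS))
    hub_value: float = 1.0
    buffer_value: float = 80.0
    buffer_distance_m: float = 100.0

    def __post_init__(self) -> None:
        for name, v in {**self.landuse, **self.levels}.items():
            if v < 1:
                raise ValueError(f"resistance factor {name!r} must be >= 1 (got {v})")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "landuse": self.landuse,
                    "levels": self.levels,
                    "hub_value": self.hub_value,
                    "buffer_value": self.buffer_value,
                    "buffer_distance_m": self.buffer_distance_m,
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResistanceFactorTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def base_resistance(
    landuse: Grid,
    cls: Grid,
    patches: list[Patch],
    levels: dict[int, str],
    hubs: HubSet | None = None,
    table: ResistanceFactorTable | None = None,
) -> Grid:
    """Per-cell base resistance by precedence overlay (highest first):

    hub cell -> ``hub_value``; core/bridge cell -> value of its patch's
    importance level; water cell -> sub-type value; non-water cell within the
    100 m buffer of river or lake -> buffer value if lower than its land-use
    value; otherwise the land-use value.
    """
    check_congruent(landuse, cls)
    table = table or ResistanceFactorTable()
    lu = np.asarray(landuse.values)
    nodata = landuse.nodata_mask

    codes = np.unique(lu[~nodata])
    out = np.zeros(lu.shape, dtype=float)
    for code in codes:
        name = _CODE_TO_NAME.get(int(code))
        if name is None or name not in table.landuse:
            raise KeyError(f"land-use code {int(code)} has no resistance factor")
        out[lu == code] = table.landuse[name]

    # river-and-lake buffer (Euclidean, cell centers, inclusive threshold)
    water_core = np.isin(lu, [int(LandUse.RIVER), int(LandUse.LAKE)])
    if water_core.any():
        dist = ndimage.distance_transform_edt(
            ~water_core, sampling=(landuse.cell_size, landuse.cell_size)
        )
        is_water = np.isin(lu, [int(c) for c in WATER_CLASSES])
        in_buffer = (dist <= table.buffer_distance_m) & ~is_water & ~nodata
        out[in_buffer] = np.minimum(out[in_buffer], table.buffer_value)

    # MSPA importance levels for core / bridge patches
    for p in patches:
        level = levels.get(p.id)
        if level is None:
            continue
        if level not in table.levels:
            raise KeyError(f"importance level {level!r} has no resistance factor")
        out[p.rows, p.cols] = table.levels[level]

    # hubs override everything
    if hubs is not None:
        by_id = {p.id: p for p in patches}
        for pid in hubs.hub_ids:
            p = by_id[pid]
            out[p.rows, p.cols] = table.hub_value

    out[nodata] = landuse.nodata if not np.issubdtype(out.dtype, np.integer) else landuse.nodata
    return landuse.with_values(out, nodata=float(landuse.nodata))


def slope_correct(base: Grid, slope: Grid) -> Grid:
    """Terrain correction R' = R x (1 + i); identity on flat ground."""
    check_congruent(base, slope)
    i = np.asarray(slope.values, dtype=float)
    valid = ~slope.nodata_mask & ~base.nodata_mask
    if np.any(i[valid] < 0):
        raise ValueError("negative slope values")
    out = np.asarray(base.values, dtype=float) * (1.0 + np.where(valid, i, 0.0))
    out[~valid] = base.nodata
    return base.with_values(out)
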