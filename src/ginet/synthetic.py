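"""Seeded generator of synthetic mountainous-city scenes.

Scenes emulate the landscape structure the analysis assumes: forested
mountain massifs near the northern and southern borders (superposed Gaussian
hills), a dense low-slope urban basin in the centre with scattered 1–5-cell
green islets, a river meandering through the basin, straight road strips, and
a green-infrastructure (forest + farmland) fraction near a target share of
the scene.  ``plant_bottleneck`` and ``plant_barrier`` insert features with a
known ground truth so the downstream pinch-point and barrier analyses can be
tested for planted-feature recovery.

All randomness flows through one ``numpy.random.default_rng(seed)`` stream
owned by the scene; identical parameters and seed give identical scenes.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import GI_CLASSES, Grid, LandUse, write_raster


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters; defaults state the landscape being emulated."""

    n_rows: int = 200
    n_cols: int = 220
    cell_size: float = 30.0
    seed: int = 0
    #: share of the scene covered by green infrastructure (forest + farmland)
    target_gi_fraction: float = 0.22
    #: massifs split between the northern and southern borders
    n_massifs: int = 4
    #: share of the scene occupied by the low-slope urban basin
    urban_center_fraction: float = 0.35
    river: bool = True
    river_sinuosity: float = 1.5
    n_roads: int = 3
    #: expected number of 1–5-cell green patches inside the urban basin
    islet_rate: float = 25.0
    #: forest share of the GI budget (the rest is farmland fringe)
    forest_share_of_gi: float = 0.75

    def validate(self) -> None:
        if not 0.0 < self.target_gi_fraction < 1.0:
            raise ValueError("target_gi_fraction must be in (0, 1)")
        if self.urban_center_fraction >= 1.0 or self.urban_center_fraction < 0.0:
            raise ValueError("urban_center_fraction must be in [0, 1)")
        if self.target_gi_fraction + self.urban_center_fraction >= 1.0:
            raise ValueError(
                "target GI fraction unattainable: GI share plus urban-core share "
                "must stay below 1"
            )
        if self.n_massifs < 1:
            raise ValueError("need at least one massif")
        if not 0.0 < self.forest_share_of_gi <= 1.0:
            raise ValueError("forest_share_of_gi must be in (0, 1]")


@dataclass
class SyntheticScene:
    """A generated scene: DEM + land use on one grid, plus planted-feature truth."""

    dem: Grid
    landuse: Grid
    truth: dict
    params: SceneParams

    @property
    def gi_fraction(self) -> float:
        lu = np.asarray(self.landuse.values)
        return float(np.isin(lu, [int(c) for c in GI_CLASSES]).mean())

    def to_files(self, outdir: str | Path, format: str = "geotiff") -> None:
        """Write dem, landuse and truth.json (the `simulate` interface)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".tif" if format == "geotiff" else ".asc"
        write_raster(self.dem, outdir / f"dem{suffix}", format=format)
        write_raster(self.landuse, outdir / f"landuse{suffix}", format=format)
        truth = {
            "params": asdict(self.params),
            "massif_centers": [list(map(int, c)) for c in self.truth["massif_centers"]],
            "bottlenecks": {
                f"{a}-{b}": [list(map(int, c)) for c in cells]
                for (a, b), cells in self.truth.get("bottlenecks", {}).items()
            },
            "barriers": {
                f"{a}-{b}": [list(map(int, c)) for c in cells]
                for (a, b), cells in self.truth.get("barriers", {}).items()
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def _line_cells(
    r0: float, c0: float, r1: float, c1: float, shape: tuple[int, int]
) -> np.ndarray:
    """Densely sampled straight line between two cells, as a boolean raster."""
    n = int(4 * max(abs(r1 - r0), abs(c1 - c0)) + 2)
    rr = np.clip(np.rint(np.linspace(r0, r1, n)).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.rint(np.linspace(c0, c1, n)).astype(int), 0, shape[1] - 1)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate a scene; |GI fraction − target| ≤ 0.03 is guaranteed by a
    deterministic top-up/trim on the greenness ranking after all overlays."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    nr, nc = params.n_rows, params.n_cols

    # --- massif placement: split between northern and southern borders
    n_north = (params.n_massifs + 1) // 2
    n_south = params.n_massifs - n_north
    centers = []
    for k in range(n_north):
        row = rng.uniform(0.10, 0.25) * nr
        col = (k + 0.5) / n_north * nc + rng.uniform(-0.06, 0.06) * nc
        centers.append((row, col))
    for k in range(n_south):
        row = rng.uniform(0.75, 0.90) * nr
        col = (k + 0.5) / max(n_south, 1) * nc + rng.uniform(-0.06, 0.06) * nc
        centers.append((row, col))

    # --- DEM: superposed Gaussian hills + low-relief basin + slope texture
    rows, cols = np.mgrid[0:nr, 0:nc]
    dem = np.full((nr, nc), 5.0)
    sigma0 = min(nr, nc) / 7.0
    for row, col in centers:
        amp = rng.uniform(220.0, 380.0)
        sigma = sigma0 * rng.uniform(0.8, 1.2)
        dem += amp * np.exp(-((rows - row) ** 2 + (cols - col) ** 2) / (2 * sigma**2))
    dem += ndimage.gaussian_filter(rng.normal(0.0, 1.0, (nr, nc)), 3.0) * 8.0
    dem = np.clip(dem, 0.0, None)

    # --- land use from an elevation-driven greenness ranking
    greenness = dem + rng.normal(0.0, 0.5, (nr, nc))  # breaks quantile ties
    q_forest = 1.0 - params.forest_share_of_gi * params.target_gi_fraction
    q_gi = 1.0 - params.target_gi_fraction
    thr_forest = np.quantile(greenness, q_forest)
    thr_gi = np.quantile(greenness, q_gi)
    lu = np.full((nr, nc), int(LandUse.CONSTRUCTION), dtype=np.int64)
    lu[greenness >= thr_gi] = int(LandUse.FARMLAND)
    lu[greenness >= thr_forest] = int(LandUse.FOREST)

    # bareland blobs on the non-GI fringe
    blobs = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (nr, nc)), 4.0)
    bare = (lu == int(LandUse.CONSTRUCTION)) & (blobs > np.quantile(blobs, 0.90))
    lu[bare] = int(LandUse.BARELAND)

    # --- river meandering west→east through the basin, with a lake
    if params.river:
        t = np.linspace(0.0, 1.0, nc)
        phase = rng.uniform(0.0, 2 * np.pi)
        river_rows = (
            0.5 * nr
            + 0.12 * nr * np.sin(2 * np.pi * params.river_sinuosity * t + phase)
            + rng.normal(0.0, 0.01 * nr)
        )
        river = np.zeros((nr, nc), dtype=bool)
        for cc_i in range(nc):
            r = int(np.clip(round(river_rows[cc_i]), 1, nr - 2))
            river[r - 1: r + 1, cc_i] = True  # 2 cells wide
        lu[river] = int(LandUse.RIVER)
        lake_c = int(rng.uniform(0.2, 0.8) * nc)
        lake_r = int(np.clip(round(river_rows[lake_c]), 4, nr - 5))
        lake = (rows - lake_r) ** 2 + ((cols - lake_c) / 1.5) ** 2 <= 3.0**2
        lu[lake] = int(LandUse.LAKE)
        for _ in range(2):  # small detached water bodies
            pr = int(rng.uniform(0.3, 0.7) * nr)
            pc_ = int(rng.uniform(0.1, 0.9) * nc)
            pond = (rows - pr) ** 2 + (cols - pc_) ** 2 <= 2.0**2
            lu[pond & ~river] = int(LandUse.OTHER_WATER)

    # --- straight road strips through the urban half of the scene
    water = np.isin(lu, [int(LandUse.RIVER), int(LandUse.LAKE), int(LandUse.OTHER_WATER)])
    for _ in range(params.n_roads):
        if rng.uniform() < 0.5:
            c0, c1 = 0, nc - 1
            r0, r1 = rng.uniform(0.3, 0.7, 2) * nr
        else:
            r0, r1 = 0, nr - 1
            c0, c1 = rng.uniform(0.2, 0.8, 2) * nc
        road = _line_cells(r0, c0, r1, c1, (nr, nc))
        lu[road & ~water] = int(LandUse.ROAD)

    # --- green islets inside the urban basin
    basin = dem < np.quantile(dem, params.urban_center_fraction)
    n_islets = int(rng.poisson(params.islet_rate))
    cand = np.flatnonzero((basin & (lu == int(LandUse.CONSTRUCTION))).ravel())
    if cand.size and n_islets:
        seeds = rng.choice(cand, size=min(n_islets, cand.size), replace=False)
        for s in seeds:
            r, c = divmod(int(s), nc)
            size = int(rng.integers(1, 6))
            rr = np.clip(r + rng.integers(-1, 2, size), 0, nr - 1)
            cc = np.clip(c + rng.integers(-1, 2, size), 0, nc - 1)
            keep = lu[rr, cc] == int(LandUse.CONSTRUCTION)
            lu[rr[keep], cc[keep]] = int(LandUse.FOREST)
            lu[r, c] = int(LandUse.FOREST)

    # --- deterministic top-up / trim to the GI target
    gi = np.isin(lu, [int(c) for c in GI_CLASSES])
    target_cells = int(round(params.target_gi_fraction * nr * nc))
    deficit = target_cells - int(gi.sum())
    if deficit > 0:
        cand = np.flatnonzero(((lu == int(LandUse.CONSTRUCTION)) | (lu == int(LandUse.BARELAND))).ravel())
        order = cand[np.argsort(-greenness.ravel()[cand], kind="stable")]
        take = order[:deficit]
        lu.ravel()[take] = int(LandUse.FARMLAND)
    elif deficit < 0:
        cand = np.flatnonzero((lu == int(LandUse.FARMLAND)).ravel())
        order = cand[np.argsort(greenness.ravel()[cand], kind="stable")]
        take = order[: min(-deficit, order.size)]
        lu.ravel()[take] = int(LandUse.CONSTRUCTION)

    dem_grid = Grid(values=dem, cell_size=params.cell_size)
    lu_grid = Grid(values=lu, cell_size=params.cell_size, nodata=-9999)
    truth = {
        "massif_centers": [(int(round(r)), int(round(c))) for r, c in centers],
        "bottlenecks": {},
        "barriers": {},
    }
    scene = SyntheticScene(dem=dem_grid, landuse=lu_grid, truth=truth, params=params)
    if abs(scene.gi_fraction - params.target_gi_fraction) > 0.03:
        raise RuntimeError(
            f"generated GI fraction {scene.gi_fraction:.3f} misses the target "
            f"{params.target_gi_fraction:.3f} by more than 0.03"
        )
    return scene


def _copy_scene(scene: SyntheticScene) -> SyntheticScene:
    return SyntheticScene(
        dem=scene.dem.with_values(np.array(scene.dem.values)),
        landuse=scene.landuse.with_values(np.array(scene.landuse.values)),
        truth={
            "massif_centers": list(scene.truth["massif_centers"]),
            "bottlenecks": dict(scene.truth.get("bottlenecks", {})),
            "barriers": dict(scene.truth.get("barriers", {})),
        },
        params=scene.params,
    )


def plant_bottleneck(
    scene: SyntheticScene,
    corridor_between: tuple[int, int],
    width_cells: int = 1,
    moat_halfwidth_cells: int = 6,
) -> SyntheticScene:
    """Insert a narrow forest land bridge between two massifs.

    The central section of the straight line between the massif centres is
    surrounded by a construction moat of ``moat_halfwidth_cells``, then a
    forest strip of ``width_cells`` is cut through it — the strip becomes the
    only low-resistance crossing, and its central cells are recorded in
    ``truth["bottlenecks"]`` for recovery tests.
    """
    if width_cells < 1:
        raise ValueError("width_cells must be >= 1")
    ia, ib = corridor_between
    centers = scene.truth["massif_centers"]
    if not (0 <= ia < len(centers) and 0 <= ib < len(centers)):
        raise ValueError(f"massif pair {corridor_between} outside 0..{len(centers)-1}")
    out = _copy_scene(scene)
    lu = np.asarray(out.landuse.values)
    shape = lu.shape
    (r0, c0), (r1, c1) = centers[ia], centers[ib]

    def _segment(t0: float, t1: float) -> np.ndarray:
        return _line_cells(
            r0 + (r1 - r0) * t0, c0 + (c1 - c0) * t0,
            r0 + (r1 - r0) * t1, c0 + (c1 - c0) * t1, shape,
        )

    middle = _segment(0.35, 0.65)
    full = _segment(0.05, 0.95)
    d_middle = ndimage.distance_transform_edt(~middle)
    d_full = ndimage.distance_transform_edt(~full)
    moat = d_middle <= moat_halfwidth_cells
    strip = d_full <= (width_cells - 1) / 2.0
    water = np.isin(lu, [int(LandUse.RIVER), int(LandUse.LAKE), int(LandUse.OTHER_WATER)])
    lu[moat & ~water] = int(LandUse.CONSTRUCTION)
    lu[strip] = int(LandUse.FOREST)
    strip_middle = strip & (d_middle <= max(moat_halfwidth_cells - 1, 1))
    cells = sorted(zip(*np.nonzero(strip_middle & moat | (strip & middle))))
    if not cells:
        cells = sorted(zip(*np.nonzero(strip & (d_middle < 2))))
    out.truth["bottlenecks"][(ia, ib)] = [(int(r), int(c)) for r, c in cells]
    return out


def plant_barrier(
    scene: SyntheticScene,
    on_corridor_between: tuple[int, int],
    plug_cells: int = 6,
) -> SyntheticScene:
    """Plug the low-cost route between two massifs with construction cells.

    If a bottleneck strip was planted for the pair, the plug blocks its
    central cells (the unique cheap crossing); otherwise the straight-line
    route between the massif centres is plugged at its midpoint.  Plug cells
    are recorded in ``truth["barriers"]``.
    """
    if plug_cells < 1:
        raise ValueError("plug_cells must be >= 1")
    ia, ib = on_corridor_between
    out = _copy_scene(scene)
    lu = np.asarray(out.landuse.values)
    if plug_cells > lu.size // 4:
        raise ValueError("plug too large for the scene")
    key = (ia, ib) if (ia, ib) in out.truth["bottlenecks"] else (ib, ia)
    if key in out.truth["bottlenecks"]:
        strip = np.array(out.truth["bottlenecks"][key])
    else:
        centers = scene.truth["massif_centers"]
        if not (0 <= ia < len(centers) and 0 <= ib < len(centers)):
            raise ValueError(f"massif pair {on_corridor_between} is unknown")
        line = _line_cells(*centers[ia], *centers[ib], lu.shape)
        strip = np.column_stack(np.nonzero(line))
    mid = strip.mean(axis=0)
    order = np.argsort(((strip - mid) ** 2).sum(axis=1), kind="stable")
    plug = strip[order[: min(plug_cells, strip.shape[0])]]
    lu[plug[:, 0], plug[:, 1]] = int(LandUse.CONSTRUCTION)
    out.truth["barriers"][(ia, ib)] = [(int(r), int(c)) for r, c in plug]
    return out


def find_massif_patch(scene: SyntheticScene, patches, massif_index: int):
    """The (core) patch nearest to a planted massif centre — truth-to-patch lookup."""
    r0, c0 = scene.truth["massif_centers"][massif_index]
    best, best_d = None, np.inf
    for p in patches:
        if p.mspa_class != "core":
            continue
        d = ((p.rows - r0) ** 2 + (p.cols - c0) ** 2).min()
        if d < best_d:
            best, best_d = p, d
    if best is None:
        raise ValueError("scene has no core patches")
    return best
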