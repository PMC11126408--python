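"""Minimum-cumulative-resistance (MCR) corridors on a resistance raster.

Cost distances are Dijkstra shortest paths over the 8-connected cell graph;
the cost of a move between adjacent cells a, b is
``step_distance x (R_a + R_b) / 2`` with the step distance equal to the cell
size (orthogonal moves) or cell size x sqrt(2) (diagonal moves) — the
conventional GIS cost-distance model.  Hub-to-hub cost is measured
patch-to-patch: all source-patch cells start at cost 0 and the target cost is
the minimum over target-patch cells.
"""
from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .grid import Grid
from .patches import Patch
from .util import round_half_up

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def build_cost_graph(resistance: Grid) -> csr_matrix:
    """Sparse symmetric move-cost graph over the grid (nodes in row-major order).

    Nodata cells carry no edges (unreachable).  Requires resistance >= 1 on
    every data cell.
    """
    r = np.asarray(resistance.values, dtype=float)
    valid = ~resistance.nodata_mask & np.isfinite(r)
    if np.any(r[valid] < 1):
        raise ValueError("resistance must be >= 1 everywhere")
    nr, nc = r.shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    cs = resistance.cell_size
    rows, cols, data = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # forward half of the 8-neighbourhood
        r0s, r0e = max(0, -dr), nr - max(0, dr)
        c0s, c0e = max(0, -dc), nc - max(0, dc)
        src = idx[r0s:r0e, c0s:c0e]
        dst = idx[r0s + dr: r0e + dr, c0s + dc: c0e + dc]
        a = r[np.unravel_index(src.ravel(), r.shape)]
        b = r[np.unravel_index(dst.ravel(), r.shape)]
        ok = (
            valid[np.unravel_index(src.ravel(), r.shape)]
            & valid[np.unravel_index(dst.ravel(), r.shape)]
        )
        step = cs * (math.sqrt(2.0) if dr and dc else 1.0)
        rows.append(src.ravel()[ok])
        cols.append(dst.ravel()[ok])
        data.append(step * (a[ok] + b[ok]) / 2.0)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    n = nr * nc
    g = coo_matrix((data, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


@dataclass
class CostDistanceGrid:
    """Accumulated minimum cost from a source patch, with backlinks for tracing."""

    dist: Grid  # accumulated cost; inf where unreachable
    predecessors: np.ndarray  # flat backlink array from scipy dijkstra
    source: Patch

    def cost_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.asarray(self.dist.values)[rows, cols]


def cost_distance(
    resistance: Grid, source: Patch, graph: csr_matrix | None = None
) -> CostDistanceGrid:
    """Multi-source Dijkstra cost distance from every cell of *source*."""
    if source.n_cells == 0:
        raise ValueError("source patch is empty")
    if graph is None:
        graph = build_cost_graph(resistance)
    nr, nc = resistance.shape
    src_idx = source.rows * nc + source.cols
    dist, pred, _ = dijkstra(
        graph, directed=False, indices=src_idx, min_only=True, return_predecessors=True
    )
    return CostDistanceGrid(
        dist=resistance.with_values(dist.reshape(nr, nc), nodata=np.inf),
        predecessors=pred,
        source=source,
    )


@dataclass
class Corridor:
    """A least-cost path between a hub pair with its accumulated resistance."""

    pair: tuple[int, int]  # hub patch ids
    mcr: float  # accumulated minimum cumulative resistance
    length_m: float
    path: list[tuple[int, int]] = field(default_factory=list)  # (row, col) cells
    label: int | None = None

    @property
    def avg_resistance(self) -> int:
        """Accumulated resistance per metre, rounded to integer at reporting."""
        return int(round_half_up(self.mcr / self.length_m))


def least_cost_path(cd: CostDistanceGrid, target: Patch, cell_size: float) -> Corridor:
    """Trace the minimum-cost path from *target* back to the source patch."""
    costs = cd.cost_at(target.rows, target.cols)
    if not np.any(np.isfinite(costs)):
        raise ValueError(
            f"target patch {target.id} is unreachable from source patch {cd.source.id}"
        )
    best = int(np.argmin(costs))
    nc = cd.dist.n_cols
    node = int(target.rows[best] * nc + target.cols[best])
    path_nodes = [node]
    while cd.predecessors[node] >= 0:
        node = int(cd.predecessors[node])
        path_nodes.append(node)
    path = [(n // nc, n % nc) for n in reversed(path_nodes)]
    length = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        length += cell_size * (math.sqrt(2.0) if r0 != r1 and c0 != c1 else 1.0)
    return Corridor(
        pair=(cd.source.id, target.id),
        mcr=float(costs[best]),
        length_m=length,
        path=path,
    )


def corridor_network(
    hub_patches: list[Patch],
    resistance: Grid,
    prune_through_hub: bool = True,
    prune_triangle: bool = True,
    graph: csr_matrix | None = None,
    cost_distances: dict[int, CostDistanceGrid] | None = None,
) -> list[Corridor]:
    """Least-cost corridors between all hub pairs, pruned to a network.

    A pair is dropped when its path enters a third hub's patch
    (*prune_through_hub*) or when an indirect route over another hub is
    cheaper (*prune_triangle*).  If pruning disconnects a component that the
    full pair graph connected, the cheapest dropped corridors are restored.
    Hubs with no finite path to any other hub are reported with a warning.
    """
    if len(hub_patches) < 2:
        raise ValueError("need at least two hubs")
    if graph is None:
        graph = build_cost_graph(resistance)
    if cost_distances is None:
        cost_distances = {}
    cell_size = resistance.cell_size
    hub_cells = {
        p.id: set(zip(p.rows.tolist(), p.cols.tolist())) for p in hub_patches
    }

    corridors: dict[tuple[int, int], Corridor] = {}
    mcr: dict[tuple[int, int], float] = {}
    for i, src in enumerate(hub_patches):
        if src.id not in cost_distances:
            cost_distances[src.id] = cost_distance(resistance, src, graph=graph)
        cd = cost_distances[src.id]
        for tgt in hub_patches[i + 1:]:
            try:
                cor = least_cost_path(cd, tgt, cell_size)
            except ValueError:
                warnings.warn(
                    f"hub pair ({src.id}, {tgt.id}) is disconnected", stacklevel=2
                )
                continue
            key = (src.id, tgt.id)
            corridors[key] = cor
            mcr[key] = cor.mcr
            mcr[(tgt.id, src.id)] = cor.mcr

    ids = [p.id for p in hub_patches]
    kept: dict[tuple[int, int], Corridor] = dict(corridors)
    dropped: list[Corridor] = []
    for key, cor in corridors.items():
        a, b = key
        drop = False
        if prune_through_hub:
            third = [
                h for h in ids
                if h not in key and any(cell in hub_cells[h] for cell in cor.path)
            ]
            if third:
                drop = True
        if not drop and prune_triangle:
            for j in ids:
                if j in key or (a, j) not in mcr or (j, b) not in mcr:
                    continue
                if cor.mcr > mcr[(a, j)] + mcr[(j, b)]:
                    drop = True
                    break
        if drop:
            dropped.append(kept.pop(key))

    # connectivity repair: the pruned network must connect whatever the full graph did
    def _components(pairs) -> int:
        pos = {h: i for i, h in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)))
        for (a, b) in pairs:
            m[pos[a], pos[b]] = m[pos[b], pos[a]] = 1
        return connected_components(csr_matrix(m), directed=False)[0]

    full_cc = _components(corridors.keys())
    for cor in sorted(dropped, key=lambda c: c.mcr):
        if _components(kept.keys()) <= full_cc:
            break
        kept[cor.pair] = cor
    out = sorted(kept.values(), key=lambda c: c.pair)
    for label, cor in enumerate(out, start=1):
        cor.label = label
    return out


def corridor_table(corridors: list[Corridor]) -> tuple[pd.DataFrame, dict]:
    """Per-corridor statistics plus the summary used in reporting.

    Lengths are printed to the nearest metre, the network total to the nearest
    kilometre, accumulated and average resistances to integers.
    """
    rows = [
        {
            "label": c.label if c.label is not None else i + 1,
            "hub_a": c.pair[0],
            "hub_b": c.pair[1],
            "accumulated_resistance": round_half_up(c.mcr),
            "length_m": round_half_up(c.length_m),
            "avg_resistance": c.avg_resistance,
        }
        for i, c in enumerate(corridors)
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "hub_a", "hub_b",
            "accumulated_resistance", "length_m", "avg_resistance",
        ],
    )
    if corridors:
        summary = {
            "count": len(corridors),
            "total_length_km": round_half_up(sum(c.length_m for c in corridors) / 1000.0),
            "mean_length_m": round_half_up(np.mean([c.length_m for c in corridors])),
            "mean_mcr": round_half_up(np.mean([c.mcr for c in corridors])),
        }
    else:
        summary = {"count": 0, "total_length_km": 0, "mean_length_m": 0, "mean_mcr": 0}
    return table, summary


def corridors_to_geojson(
    corridors: list[Corridor], grid: Grid, path: str | Path
) -> None:
    """Write corridors as a GeoJSON FeatureCollection of LineStrings."""
    features = []
    for c in corridors:
        rows = np.array([p[0] for p in c.path])
        cols = np.array([p[1] for p in c.path])
        x, y = grid.cell_xy(rows, cols)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(xi), float(yi)] for xi, yi in zip(x, y)],
                },
                "properties": {
                    "label": c.label,
                    "hub_a": c.pair[0],
                    "hub_b": c.pair[1],
                    "mcr": c.mcr,
                    "length_m": c.length_m,
                    "avg_resistance": c.avg_resistance,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
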