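"""Circuit-theory network analysis: centrality, pinch points, barriers.

The landscape is treated as a resistive network: conductances are the
reciprocals of edge resistances, ecological flow is the current driven by a
1 A injection between hub pairs.  Three analyses are built on sparse Laplacian
solves:

* **hub centrality** — on the reduced hub graph (nodes = hubs, edge
  resistance = corridor MCR), accumulate each hub's current over all pairwise
  1 A source/ground configurations;
* **pinch points** — per corridor, solve the grid circuit restricted to the
  corridor swath and flag cells whose accumulated current falls in the top
  quantile (flow concentrated with no alternative route);
* **barriers** — moving-window search: short-circuit a circular window to the
  landscape minimum resistance and score the resulting drop of the
  least-cost distances, IS = dLCD / D.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix, diags
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .breaks import classify_values, jenks_breaks
from .corridors import Corridor, CostDistanceGrid, build_cost_graph, cost_distance
from .grid import Grid
from .mspa import CLASS_NAMES, MspaClass
from .patches import Patch
from .util import round_half_up

_KIRCHHOFF_TOL = 1e-8


@dataclass
class CircuitGraph:
    """An undirected resistive network (conductance = 1 / resistance per edge)."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) node index pairs
    resistances: np.ndarray  # (m,) ohms, > 0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.resistances = np.asarray(self.resistances, dtype=float).ravel()
        if np.any(self.resistances <= 0):
            raise ValueError("edge resistances must be positive")
        if self.edges.shape[0] != self.resistances.size:
            raise ValueError("edges and resistances disagree in length")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> csr_matrix:
        c = 1.0 / self.resistances
        m = coo_matrix(
            (c, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )
        return (m + m.T).tocsr()


@dataclass
class CircuitSolution:
    """Node potentials, branch currents and derived per-node currents."""

    potentials: np.ndarray  # volts; ground fixed at 0
    branch_currents: np.ndarray  # amperes, signed along each edge
    node_currents: np.ndarray  # amperes; half the sum of absolute incident currents
    effective_resistance: float  # ohms between the contracted source and ground


def grid_circuit(
    resistance: Grid, mask: np.ndarray
) -> tuple[CircuitGraph, np.ndarray]:
    """Circuit over the cells selected by *mask* (8-neighbour connectivity).

    Edge resistance between adjacent cells = step distance x (R_a + R_b) / 2,
    the same convention as the least-cost moves.  Returns the graph and a flat
    ``cell index -> node index`` map (-1 outside the mask).
    """
    r = np.asarray(resistance.values, dtype=float)
    nr, nc = r.shape
    mask = np.asarray(mask, dtype=bool) & ~resistance.nodata_mask
    node_of = -np.ones(nr * nc, dtype=int)
    cells = np.flatnonzero(mask.ravel())
    node_of[cells] = np.arange(cells.size)
    cs = resistance.cell_size
    edges, res = [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0s, r0e = max(0, -dr), nr - max(0, dr)
        c0s, c0e = max(0, -dc), nc - max(0, dc)
        src_m = mask[r0s:r0e, c0s:c0e]
        dst_m = mask[r0s + dr: r0e + dr, c0s + dc: c0e + dc]
        ok = src_m & dst_m
        if not ok.any():
            continue
        idx = np.arange(nr * nc).reshape(nr, nc)
        src = idx[r0s:r0e, c0s:c0e][ok]
        dst = idx[r0s + dr: r0e + dr, c0s + dc: c0e + dc][ok]
        ra = r.ravel()[src]
        rb = r.ravel()[dst]
        step = cs * (math.sqrt(2.0) if dr and dc else 1.0)
        edges.append(np.column_stack([node_of[src], node_of[dst]]))
        res.append(step * (ra + rb) / 2.0)
    if edges:
        graph = CircuitGraph(
            n_nodes=cells.size,
            edges=np.vstack(edges),
            resistances=np.concatenate(res),
        )
    else:
        graph = CircuitGraph(cells.size, np.empty((0, 2), int), np.empty(0))
    return graph, node_of


def solve_pair(
    g: CircuitGraph,
    source: np.ndarray | list[int],
    ground: np.ndarray | list[int],
    current: float = 1.0,
) -> CircuitSolution:
    """Inject *current* amperes between the source and ground node sets.

    Multi-cell sets are contracted to supernodes (equipotential patches); the
    ground potential is fixed at 0.  Raises when source and ground fall in
    different components, and asserts Kirchhoff's current law at every node to
    1e-8 relative.
    """
    source = np.unique(np.asarray(source, dtype=int))
    ground = np.unique(np.asarray(ground, dtype=int))
    if source.size == 0 or ground.size == 0:
        raise ValueError("source and ground sets must be nonempty")
    if np.intersect1d(source, ground).size:
        raise ValueError("source and ground sets overlap")

    # contract each set to one supernode
    merge = np.arange(g.n_nodes)
    merge[source] = source[0]
    merge[ground] = ground[0]
    new_id = -np.ones(g.n_nodes, dtype=int)
    reps = np.unique(merge)
    new_id[reps] = np.arange(reps.size)
    node_map = new_id[merge]
    n = reps.size
    s_node = node_map[source[0]]
    g_node = node_map[ground[0]]

    e0 = node_map[g.edges[:, 0]]
    e1 = node_map[g.edges[:, 1]]
    external = e0 != e1  # intra-supernode edges carry no potential difference
    cond = 1.0 / g.resistances
    adj = coo_matrix(
        (cond[external], (e0[external], e1[external])), shape=(n, n)
    )
    adj = (adj + adj.T).tocsr()

    n_comp, labels = connected_components(adj, directed=False)
    if labels[s_node] != labels[g_node]:
        raise ValueError(
            f"source (component {labels[s_node]}) and ground (component "
            f"{labels[g_node]}) are not connected"
        )

    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = diags(deg) - adj
    keep = np.ones(n, dtype=bool)
    keep[g_node] = False
    b = np.zeros(n)
    b[s_node] = current
    v = np.zeros(n)
    sub = lap[keep][:, keep].tocsc()
    v[keep] = spsolve(sub, b[keep])

    potentials = v[node_map]
    dv = potentials[g.edges[:, 0]] - potentials[g.edges[:, 1]]
    branch = dv / g.resistances  # positive = flow from edge[0] to edge[1]

    # Kirchhoff check on the contracted network
    net = np.zeros(n)
    np.add.at(net, e0[external], -branch[external])
    np.add.at(net, e1[external], branch[external])
    net[s_node] += current
    net[g_node] -= current
    resid = np.abs(net).max() / max(abs(current), 1e-300)
    if resid > _KIRCHHOFF_TOL:
        raise ArithmeticError(f"Kirchhoff conservation violated: residual {resid:.3e}")

    inj = np.zeros(n)
    inj[s_node] = current
    inj[g_node] = -current
    abs_sum = np.zeros(n)
    np.add.at(abs_sum, e0[external], np.abs(branch[external]))
    np.add.at(abs_sum, e1[external], np.abs(branch[external]))
    node_current_merged = 0.5 * (abs_sum + np.abs(inj))
    node_currents = node_current_merged[node_map]

    eff = (potentials[source[0]] - potentials[ground[0]]) / current
    return CircuitSolution(
        potentials=potentials,
        branch_currents=branch,
        node_currents=node_currents,
        effective_resistance=float(eff),
    )


# ---------------------------------------------------------------------------
# Hub current-flow centrality
# ---------------------------------------------------------------------------

def hub_centrality(corridors: list[Corridor], hub_ids: list[int]) -> pd.DataFrame:
    """Current-flow centrality of each hub on the hub–corridor graph.

    Nodes are hubs, edge resistances are corridor MCR values.  For every
    unordered hub pair in one component, 1 A is injected at one and extracted
    at the other; each hub's node current is accumulated and divided by the
    number of pairs.  Hubs are graded high / medium / low by 3-class natural
    breaks on centrality.
    """
    if len(hub_ids) < 2:
        raise ValueError("need at least two hubs")
    pos = {h: i for i, h in enumerate(hub_ids)}
    edges = np.array([[pos[c.pair[0]], pos[c.pair[1]]] for c in corridors])
    if edges.size == 0:
        raise ValueError("no corridors connect the hubs")
    g = CircuitGraph(
        n_nodes=len(hub_ids),
        edges=edges,
        resistances=np.array([c.mcr for c in corridors]),
    )
    _, labels = connected_components(g.adjacency(), directed=False)
    acc = np.zeros(len(hub_ids))
    n_pairs = 0
    for i in range(len(hub_ids)):
        for j in range(i + 1, len(hub_ids)):
            if labels[i] != labels[j]:
                continue
            sol = solve_pair(g, [i], [j], current=1.0)
            acc += sol.node_currents
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no connected hub pair")
    centrality = acc / n_pairs
    if np.ptp(centrality) == 0:
        level_idx = np.full(len(hub_ids), 2)
    else:
        level_idx = classify_values(centrality, 3)  # 2 = highest class
    names = {2: "high", 1: "medium", 0: "low"}
    return pd.DataFrame(
        {
            "hub": hub_ids,
            "centrality": centrality,
            "level": [names[int(i)] for i in level_idx],
        }
    )


# ---------------------------------------------------------------------------
# Pinch points
# ---------------------------------------------------------------------------

def corridor_swath(
    cd_a: CostDistanceGrid, cd_b: CostDistanceGrid, mcr: float, cutoff: float
) -> np.ndarray:
    """Cells on near-minimal routes: cd_a + cd_b <= mcr x (1 + cutoff)."""
    total = np.asarray(cd_a.dist.values) + np.asarray(cd_b.dist.values)
    with np.errstate(invalid="ignore"):
        return np.isfinite(total) & (total <= mcr * (1.0 + cutoff))


@dataclass
class PinchPointResult:
    current: Grid  # accumulated current per cell (0 outside swaths)
    pinch_cells: np.ndarray  # (k, 2) array of (row, col)
    swath: np.ndarray  # union of corridor swaths (bool)
    threshold: float  # current value at the pinch quantile
    classes: pd.DataFrame  # per-pinch-cell MSPA class (empty frame if cls not given)


def pinchpoint_map(
    resistance: Grid,
    hub_patches: list[Patch],
    corridors: list[Corridor],
    mspa_cls: Grid | None = None,
    quantile: float = 0.05,
    swath_cutoff: float = 0.05,
    cost_distances: dict[int, CostDistanceGrid] | None = None,
    graph=None,
) -> PinchPointResult:
    """Accumulated per-cell current over all corridor circuits; top-quantile pinch set.

    For each corridor (a, b) the circuit is restricted to the corridor swath,
    the two hub patches are contracted, and 1 A is passed between them (by
    current reciprocity this equals the many-to-one iteration up to a constant
    factor).  Pinch cells are swath cells (hub interiors excluded) whose
    accumulated current lies in the top *quantile*.
    """
    if len(hub_patches) < 2:
        raise ValueError("need at least two hubs")
    if not corridors:
        raise ValueError("no corridors to analyse")
    if graph is None:
        graph = build_cost_graph(resistance)
    if cost_distances is None:
        cost_distances = {}
    by_id = {p.id: p for p in hub_patches}
    nr, nc = resistance.shape
    accum = np.zeros((nr, nc))
    union_swath = np.zeros((nr, nc), dtype=bool)
    hub_mask = np.zeros((nr, nc), dtype=bool)
    for p in hub_patches:
        hub_mask[p.rows, p.cols] = True

    for cor in corridors:
        a, b = cor.pair
        for pid in (a, b):
            if pid not in cost_distances:
                cost_distances[pid] = cost_distance(resistance, by_id[pid], graph=graph)
        swath = corridor_swath(cost_distances[a], cost_distances[b], cor.mcr, swath_cutoff)
        pa, pb = by_id[a], by_id[b]
        swath[pa.rows, pa.cols] = True
        swath[pb.rows, pb.cols] = True
        circuit, node_of = grid_circuit(resistance, swath)
        src = node_of[pa.rows * nc + pa.cols]
        gnd = node_of[pb.rows * nc + pb.cols]
        try:
            sol = solve_pair(circuit, src[src >= 0], gnd[gnd >= 0], current=1.0)
        except ValueError:
            warnings.warn(
                f"swath disconnects hub pair ({a}, {b}); pair skipped", stacklevel=2
            )
            continue
        cur = np.zeros(nr * nc)
        cells = np.flatnonzero(swath.ravel())
        cur[cells] = sol.node_currents[node_of[cells]]
        accum += cur.reshape(nr, nc)
        union_swath |= swath

    candidates = union_swath & ~hub_mask
    if not candidates.any():
        raise ValueError("no corridor swath cells outside hub patches")
    vals = accum[candidates]
    threshold = float(np.quantile(vals, 1.0 - quantile))
    pinch_mask = candidates & (accum >= threshold) & (accum > 0)
    rows, cols = np.nonzero(pinch_mask)
    if mspa_cls is not None:
        cls_vals = np.asarray(mspa_cls.values)[rows, cols]
        classes = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "current": accum[rows, cols],
                "mspa_class": [CLASS_NAMES[MspaClass(int(v))] for v in cls_vals],
            }
        )
    else:
        classes = pd.DataFrame(columns=["row", "col", "current", "mspa_class"])
    return PinchPointResult(
        current=resistance.with_values(accum, nodata=-1.0),
        pinch_cells=np.column_stack([rows, cols]),
        swath=union_swath,
        threshold=threshold,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Barrier detection
# ---------------------------------------------------------------------------

@dataclass
class BarrierMap:
    """Improvement-score raster IS = dLCD / D and its 4-level classification.

    ``classes`` holds 0 = non-barrier, 3/2/1 = third- to first-level
    improvement areas (1 = highest improvement potential).
    """

    improvement: Grid  # IS values (0 where no window gain)
    classes: Grid
    search_radius_m: float
    breaks: np.ndarray  # Jenks break values on the positive IS distribution
    lcd0: dict[tuple[int, int], float] = field(default_factory=dict)


def _disk_footprint(radius_cells: float) -> np.ndarray:
    r = int(math.floor(radius_cells))
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (yy**2 + xx**2) <= radius_cells**2 + 1e-9


def barrier_scan(
    resistance: Grid,
    hub_patches: list[Patch],
    corridors: list[Corridor],
    search_radius_m: float = 60.0,
    swath_cutoff: float = 0.05,
    cost_distances: dict[int, CostDistanceGrid] | None = None,
    graph=None,
    seed: int | None = 0,
) -> BarrierMap:
    """Moving-window barrier detection over the corridor swaths.

    A circular window of radius D is stepped at every cell of the dilated
    corridor swaths.  Shorting the window to the landscape minimum resistance
    can reroute each hub pair through it; the resulting least-cost-distance
    drop, summed over affected pairs, gives dLCD and the improvement score
    IS = dLCD / D.  The rerouted distance is evaluated from the hubs'
    precomputed cost-distance rasters (best entry cost from either hub within
    the window), the standard fast approximation for window scans; dLCD >= 0
    by construction.  Cells with IS > 0 are graded by 4-class natural breaks:
    the lowest class is "non-barrier", the upper three are improvement levels
    3, 2, 1.
    """
    if search_radius_m < resistance.cell_size:
        raise ValueError("search radius must be at least one cell")
    if not corridors:
        raise ValueError("no corridors to analyse")
    if graph is None:
        graph = build_cost_graph(resistance)
    if cost_distances is None:
        cost_distances = {}
    by_id = {p.id: p for p in hub_patches}
    nr, nc = resistance.shape
    fp = _disk_footprint(search_radius_m / resistance.cell_size)

    is_map = np.zeros((nr, nc))
    union_centers = np.zeros((nr, nc), dtype=bool)
    lcd0: dict[tuple[int, int], float] = {}
    for cor in corridors:
        a, b = cor.pair
        for pid in (a, b):
            if pid not in cost_distances:
                cost_distances[pid] = cost_distance(resistance, by_id[pid], graph=graph)
        cda = np.asarray(cost_distances[a].dist.values)
        cdb = np.asarray(cost_distances[b].dist.values)
        lcd0[(a, b)] = cor.mcr
        swath = corridor_swath(cost_distances[a], cost_distances[b], cor.mcr, swath_cutoff)
        centers = ndimage.binary_dilation(swath, structure=fp)
        union_centers |= centers
        # best cost of entering the shorted window from each hub
        min_a = ndimage.minimum_filter(np.where(np.isfinite(cda), cda, np.inf), footprint=fp, mode="constant", cval=np.inf)
        min_b = ndimage.minimum_filter(np.where(np.isfinite(cdb), cdb, np.inf), footprint=fp, mode="constant", cval=np.inf)
        with np.errstate(invalid="ignore"):
            lcd1 = np.minimum(cor.mcr, min_a + min_b)
        delta = np.where(centers & np.isfinite(lcd1), cor.mcr - lcd1, 0.0)
        is_map += np.maximum(delta, 0.0) / search_radius_m

    is_map[~union_centers] = 0.0
    classes = np.zeros((nr, nc), dtype=np.uint8)
    positive = is_map > 0
    if positive.sum() >= 4:
        breaks = jenks_breaks(is_map[positive], 4, seed=seed)
        idx = np.searchsorted(breaks, is_map[positive], side="left")
        # class 0 (lowest) -> non-barrier; 1,2,3 -> levels 3,2,1
        level = np.where(idx == 0, 0, 4 - idx)
        classes[positive] = level.astype(np.uint8)
    elif positive.any():
        breaks = np.empty(0)
        classes[positive] = 1
    else:
        breaks = np.empty(0)
    return BarrierMap(
        improvement=resistance.with_values(is_map, nodata=-1.0),
        classes=resistance.with_values(classes, nodata=255),
        search_radius_m=search_radius_m,
        breaks=breaks,
        lcd0=lcd0,
    )


def improvement_area_table(bm: BarrierMap) -> pd.DataFrame:
    """Per-level region count, area and share of the total improvement area."""
    cls = np.asarray(bm.classes.values)
    cell_ha = bm.classes.cell_area_ha
    struct = ndimage.generate_binary_structure(2, 2)
    rows = []
    level_areas = {}
    for level in (1, 2, 3):
        m = cls == level
        level_areas[level] = float(m.sum()) * cell_ha
    total = sum(level_areas.values())
    if total == 0:
        return pd.DataFrame(
            columns=["level", "region_count", "area_ha", "pct_of_improvement_area"]
        )
    for level in (1, 2, 3):
        m = cls == level
        count = int(ndimage.label(m, structure=struct)[1])
        rows.append(
            {
                "level": level,
                "region_count": count,
                "area_ha": round_half_up(level_areas[level], 2),
                "pct_of_improvement_area": round_half_up(
                    100.0 * level_areas[level] / total, 1
                ),
            }
        )
    return pd.DataFrame(rows)


def improvement_shares(areas_ha: dict[int, float]) -> dict[int, float]:
    """Level shares (1 decimal) of the total improvement area — reporting arithmetic."""
    total = sum(areas_ha.values())
    return {
        level: round_half_up(100.0 * a / total, 1) for level, a in areas_ha.items()
    }
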