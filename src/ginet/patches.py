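"""Patch graph and graph-theoretic connectivity indices (IIC, PC, dI).

Nodes are the 8-connected components of the MSPA *core* and *bridge* classes,
kept as separate patches.  Two patches are linked when their edge-to-edge
Euclidean distance is at most the distance threshold theta.  IIC weights
patch-area products by 1/(1 + minimum link count); PC weights them by the
maximum product of per-step dispersal probabilities along any path.  Patch
importance dI is the percent drop of an index when the patch is removed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .breaks import classify_values
from .grid import Grid
from .mspa import MspaClass

LEVELS = ("extremely important", "important", "general")


@dataclass(frozen=True)
class Patch:
    """A core or bridge patch: an 8-connected component with an area in hectares."""

    id: int
    mspa_class: str  # "core" | "bridge"
    rows: np.ndarray
    cols: np.ndarray
    area_ha: float

    @property
    def n_cells(self) -> int:
        return self.rows.size


def extract_patches(cls: Grid) -> list[Patch]:
    """One patch per 8-connected core component and per bridge component.

    Ids are stable: sorted by descending area, ties by top-left cell (row, col).
    Returns an empty list when no core or bridge cells exist.
    """
    values = np.asarray(cls.values)
    struct = ndimage.generate_binary_structure(2, 2)
    cell_ha = cls.cell_area_ha
    raw = []
    for klass, name in ((MspaClass.CORE, "core"), (MspaClass.BRIDGE, "bridge")):
        lab, n = ndimage.label(values == int(klass), structure=struct)
        for k in range(1, n + 1):
            rows, cols = np.nonzero(lab == k)
            raw.append((name, rows, cols))
    raw.sort(key=lambda t: (-t[1].size, int(t[1][0]), int(t[2][0])))
    return [
        Patch(id=i, mspa_class=name, rows=rows, cols=cols, area_ha=rows.size * cell_ha)
        for i, (name, rows, cols) in enumerate(raw)
    ]


def pairwise_distances(patches: list[Patch], cell_size: float) -> np.ndarray:
    """Minimum Euclidean distance between cell centers of every patch pair (metres)."""
    if not patches:
        raise ValueError("need at least one patch")
    n = len(patches)
    coords = [
        np.column_stack([p.rows, p.cols]).astype(float) * cell_size for p in patches
    ]
    trees = [cKDTree(c) for c in coords]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # query the smaller point set against the larger tree
            if coords[i].shape[0] <= coords[j].shape[0]:
                dist, _ = trees[j].query(coords[i], k=1)
            else:
                dist, _ = trees[i].query(coords[j], k=1)
            d[i, j] = d[j, i] = float(dist.min())
    return d


@dataclass
class PatchGraph:
    """Patches plus the threshold-dependent link structure and dispersal model.

    ``p_half`` is the dispersal probability at the threshold distance theta
    (direct probability p_ij = p_half ** (d_ij / theta), the exponential-decay
    convention).  With ``pc_complete=True`` the PC path search runs on the
    complete graph instead of the thresholded link graph.
    """

    patches: list[Patch]
    A_L: float  # total landscape area, hectares
    d: np.ndarray  # edge-to-edge distances, metres
    theta: float  # distance threshold, metres
    p_half: float = 0.5
    pc_complete: bool = False
    _nl: np.ndarray | None = field(default=None, repr=False)
    _p_star: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.A_L <= 0:
            raise ValueError("landscape area A_L must be positive")

    @property
    def n(self) -> int:
        return len(self.patches)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area_ha for p in self.patches])

    @property
    def links(self) -> np.ndarray:
        a = (self.d <= self.theta) & ~np.eye(self.n, dtype=bool)
        return a

    @property
    def nl(self) -> np.ndarray:
        """Minimum link counts over the link graph (inf for disconnected pairs)."""
        if self._nl is None:
            self._nl = _link_counts(self.links)
        return self._nl

    @property
    def p(self) -> np.ndarray:
        """Direct dispersal probabilities for every pair."""
        with np.errstate(over="ignore"):
            pm = self.p_half ** (self.d / self.theta)
        np.fill_diagonal(pm, 1.0)
        return pm

    @property
    def p_star(self) -> np.ndarray:
        """Maximum product-path probabilities (shortest path on -log p weights)."""
        if self._p_star is None:
            self._p_star = _max_product_probability(
                self.p, None if self.pc_complete else self.links
            )
        return self._p_star


def _link_counts(links: np.ndarray) -> np.ndarray:
    n = links.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    g = csr_matrix(links.astype(float))
    nl = shortest_path(g, method="D", directed=False, unweighted=True)
    np.fill_diagonal(nl, 0.0)
    return nl


def _max_product_probability(p: np.ndarray, links: np.ndarray | None) -> np.ndarray:
    n = p.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    with np.errstate(divide="ignore"):
        w = -np.log(p)
    if links is not None:
        edge_mask = links
    else:
        edge_mask = ~np.eye(n, dtype=bool)
    if edge_mask.any():
        graph = csr_matrix((w[edge_mask], np.nonzero(edge_mask)), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    dist = shortest_path(graph, method="D", directed=False)
    p_star = np.exp(-dist)
    p_star[~np.isfinite(dist)] = 0.0
    np.fill_diagonal(p_star, 1.0)
    return p_star


def iic(graph: PatchGraph) -> float:
    """Integral index of connectivity: sum a_i a_j / (1 + nl_ij) over all pairs / A_L^2.

    The sum includes i = j (nl_ii = 0); disconnected pairs contribute 0.
    """
    if graph.n == 0:
        return 0.0
    a = graph.areas
    nl = graph.nl
    with np.errstate(invalid="ignore"):
        terms = np.outer(a, a) / (1.0 + nl)
    terms[~np.isfinite(nl)] = 0.0
    return float(terms.sum() / graph.A_L**2)


def pc(graph: PatchGraph) -> float:
    """Probability of connectivity: sum a_i a_j p*_ij over all pairs / A_L^2."""
    if graph.n == 0:
        return 0.0
    a = graph.areas
    return float((np.outer(a, a) * graph.p_star).sum() / graph.A_L**2)


_INDEX_FUNS = {"IIC": iic, "PC": pc}


def _subgraph(graph: PatchGraph, keep: np.ndarray) -> PatchGraph:
    return PatchGraph(
        patches=[graph.patches[i] for i in np.nonzero(keep)[0]],
        A_L=graph.A_L,
        d=graph.d[np.ix_(keep, keep)],
        theta=graph.theta,
        p_half=graph.p_half,
        pc_complete=graph.pc_complete,
    )


@dataclass
class ImportanceRecord:
    patch_id: int
    dA: float  # 100 x a_i / sum(a)
    dIIC: float
    dPC: float
    rank: int | None = None
    level: str | None = None


def delta_importance(graph: PatchGraph) -> list[ImportanceRecord]:
    """Leave-one-out percent importance dI = 100 (I - I_remove) / I for IIC and PC.

    ``A_L`` is held fixed when a patch is removed.
    """
    if graph.n == 0:
        raise ValueError("empty patch graph")
    a = graph.areas
    base = {name: fun(graph) for name, fun in _INDEX_FUNS.items()}
    records = []
    for k in range(graph.n):
        keep = np.ones(graph.n, dtype=bool)
        keep[k] = False
        sub = _subgraph(graph, keep)
        d_vals = {}
        for name, fun in _INDEX_FUNS.items():
            if base[name] <= 0:
                d_vals[name] = 0.0
            else:
                d_vals[name] = 100.0 * (base[name] - fun(sub)) / base[name]
        records.append(
            ImportanceRecord(
                patch_id=graph.patches[k].id,
                dA=100.0 * a[k] / a.sum(),
                dIIC=d_vals["IIC"],
                dPC=d_vals["PC"],
            )
        )
    return records


def threshold_sweep(
    patches: list[Patch],
    A_L: float,
    thresholds: list[float],
    probe_patches: list[int],
    cell_size: float,
    d: np.ndarray | None = None,
    p_half: float = 0.5,
) -> pd.DataFrame:
    """dIIC/dPC of probe patches at each distance threshold (stability curves).

    Returns the curves; choosing the working threshold from them is a user
    decision (the standard choice is the distance beyond which they flatten).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if d is None:
        d = pairwise_distances(patches, cell_size)
    id_to_pos = {p.id: i for i, p in enumerate(patches)}
    rows = []
    for theta in thresholds:
        g = PatchGraph(patches=patches, A_L=A_L, d=d, theta=theta, p_half=p_half)
        recs = {r.patch_id: r for r in delta_importance(g)}
        for pid in probe_patches:
            if pid not in id_to_pos:
                raise KeyError(f"unknown probe patch id {pid}")
            rows.append(
                {
                    "threshold_m": theta,
                    "patch_id": pid,
                    "dIIC": recs[pid].dIIC,
                    "dPC": recs[pid].dPC,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HubSet:
    """Selected hub patch ids plus the 3-level importance classification."""

    hub_ids: list[int]
    levels: dict[int, str]  # patch id -> level name
    records: list[ImportanceRecord]


def rank_and_select_hubs(
    records: list[ImportanceRecord], k: int = 10, key: str = "dIIC"
) -> HubSet:
    """Rank patches by *key* (descending) and take the top *k* as hubs.

    Hubs are graded "extremely important"; the remaining patches are split into
    "important" / "general" by 2-class natural breaks on the key.  Ties are
    broken by larger dA, then smaller patch id (deterministic).
    """
    if not records:
        raise ValueError("no importance records")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of patches ({len(records)})")
    order = sorted(
        records, key=lambda r: (-getattr(r, key), -r.dA, r.patch_id)
    )
    for rank, rec in enumerate(order, start=1):
        rec.rank = rank
    hubs = [r.patch_id for r in order[:k]]
    levels = {pid: LEVELS[0] for pid in hubs}
    rest = order[k:]
    if rest:
        vals = np.array([getattr(r, key) for r in rest])
        if np.ptp(vals) == 0:
            cls = np.ones(len(rest), dtype=int)  # indistinguishable -> all "important"
        else:
            cls = classify_values(vals, 2)  # 1 = upper class
        for rec, c in zip(rest, cls):
            levels[rec.patch_id] = LEVELS[1] if c == 1 else LEVELS[2]
    for rec in order:
        rec.level = levels[rec.patch_id]
    return HubSet(hub_ids=hubs, levels=levels, records=order)


def importance_table(hubset: HubSet) -> pd.DataFrame:
    """Ranked importance table (rank, label, dA, dIIC, dPC, level)."""
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "label": r.patch_id,
                "dA": r.dA,
                "dIIC": r.dIIC,
                "dPC": r.dPC,
                "level": r.level,
            }
            for r in hubset.records
        ]
    )
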