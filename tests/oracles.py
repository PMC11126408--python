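"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive (loops, exhaustive enumeration, dense
algebra) and shares no code with the package paths it checks.
"""
import heapq
import itertools
import math

import numpy as np


def horn_slope_cell(z_pad: np.ndarray, r: int, c: int, cell: float) -> float:
    """Horn slope at one cell of an edge-padded DEM, written out long-hand."""
    a, b_, cc = z_pad[r - 1, c - 1], z_pad[r - 1, c], z_pad[r - 1, c + 1]
    d, f = z_pad[r, c - 1], z_pad[r, c + 1]
    g, h, i = z_pad[r + 1, c - 1], z_pad[r + 1, c], z_pad[r + 1, c + 1]
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b_ + cc)) / (8 * cell)
    return math.sqrt(dzdx**2 + dzdy**2)


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cci = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cci < mask.shape[1]
                            and mask[rr, cci]
                            and not seen[rr, cci]
                        ):
                            seen[rr, cci] = True
                            stack.append((rr, cci))
    return count


def min_patch_distance(cells_a, cells_b, cell_size: float) -> float:
    """Exhaustive O(|a| x |b|) edge-to-edge distance scan."""
    best = math.inf
    for ra, ca in cells_a:
        for rb, cb in cells_b:
            d = cell_size * math.hypot(ra - rb, ca - cb)
            best = min(best, d)
    return best


def bfs_link_counts(adj: np.ndarray) -> np.ndarray:
    """All-pairs minimum link counts by plain breadth-first search."""
    n = adj.shape[0]
    nl = np.full((n, n), np.inf)
    for s in range(n):
        nl[s, s] = 0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and nl[s, v] == np.inf:
                        nl[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return nl


def max_product_paths(p: np.ndarray, links: np.ndarray) -> np.ndarray:
    """p*_ij by exhaustive enumeration of all simple paths (n <= ~7)."""
    n = p.shape[0]
    p_star = np.zeros((n, n))
    np.fill_diagonal(p_star, 1.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = 0.0
            others = [k for k in range(n) if k not in (i, j)]
            for size in range(len(others) + 1):
                for mid in itertools.permutations(others, size):
                    path = (i, *mid, j)
                    prob = 1.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        if not links[u, v]:
                            ok = False
                            break
                        prob *= p[u, v]
                    if ok:
                        best = max(best, prob)
            p_star[i, j] = best
    return p_star


def iic_bruteforce(areas, nl, A_L) -> float:
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            if np.isfinite(nl[i, j]):
                total += areas[i] * areas[j] / (1.0 + nl[i, j])
    return total / A_L**2


def pc_bruteforce(areas, p_star, A_L) -> float:
    total = 0.0
    n = len(areas)
    for i in range(n):
        for j in range(n):
            total += areas[i] * areas[j] * p_star[i, j]
    return total / A_L**2


def dijkstra_grid(resistance: np.ndarray, cell_size: float, sources) -> np.ndarray:
    """Explicit edge-list Dijkstra with a binary heap over the 8-connected grid."""
    nr, nc = resistance.shape
    dist = np.full((nr, nc), np.inf)
    heap = []
    for (r, c) in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                step = cell_size * (math.sqrt(2.0) if dr and dc else 1.0)
                nd = d + step * (resistance[r, c] + resistance[rr, cc]) / 2.0
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist


def dense_circuit_solve(n, edges, resistances, source, ground, current=1.0):
    """Node potentials by a dense solve of the reduced Laplacian (numpy only)."""
    lap = np.zeros((n, n))
    for (u, v), r in zip(edges, resistances):
        g = 1.0 / r
        lap[u, u] += g
        lap[v, v] += g
        lap[u, v] -= g
        lap[v, u] -= g
    keep = [i for i in range(n) if i != ground]
    b = np.zeros(n)
    b[source] = current
    v = np.zeros(n)
    v_keep = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
    for i, idx in enumerate(keep):
        v[idx] = v_keep[i]
    return v


def jenks_bruteforce(values, k):
    """Optimal k-class partition of sorted values by enumerating all splits."""
    v = sorted(values)
    n = len(v)

    def ssd(seg):
        m = sum(seg) / len(seg)
        return sum((x - m) ** 2 for x in seg)

    best, best_bounds = math.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        parts = []
        prev = 0
        for cut in (*cuts, n):
            parts.append(v[prev:cut])
            prev = cut
        total = sum(ssd(p) for p in parts)
        if total < best - 1e-12:
            best = total
            best_bounds = [p[-1] for p in parts[:-1]]
    return best, best_bounds
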