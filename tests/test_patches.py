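import numpy as np
import pytest

from ginet import (
    Grid,
    ImportanceRecord,
    PatchGraph,
    classify,
    delta_importance,
    extract_patches,
    iic,
    pairwise_distances,
    pc,
    rank_and_select_hubs,
    threshold_sweep,
)
from ginet.mspa import MspaClass
from ginet.patches import Patch

from oracles import (
    bfs_link_counts,
    flood_fill_count,
    iic_bruteforce,
    max_product_paths,
    min_patch_distance,
    pc_bruteforce,
)


def patch(i, a, r=0, c=0):
    return Patch(id=i, mspa_class="core", rows=np.array([r]), cols=np.array([c]), area_ha=a)


def graph_from(areas, d, theta=1.0, A_L=100.0):
    ps = [patch(i, a) for i, a in enumerate(areas)]
    return PatchGraph(patches=ps, A_L=A_L, d=np.asarray(d, float), theta=theta)


def random_graph(rng, n=6, theta=300.0):
    pts = rng.uniform(0, 1000, size=(n, 2))
    d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, 0.0)
    areas = rng.uniform(1.0, 30.0, size=n)
    ps = [patch(i, a) for i, a in enumerate(areas)]
    return PatchGraph(patches=ps, A_L=500.0, d=d, theta=theta)


class TestExtractPatches:
    def test_two_core_blocks(self):
        a = np.zeros((9, 9), np.uint8)
        a[1:4, 1:4] = 1
        a[5:8, 5:8] = 1
        cls = classify(Grid(a, 30.0))
        ps = extract_patches(cls)
        cores = [p for p in ps if p.mspa_class == "core"]
        assert len(cores) == 2
        assert all(p.area_ha == pytest.approx(0.09) for p in cores)

    def test_core_and_bridge_kept_separate(self):
        a = np.zeros((9, 21), np.uint8)
        a[1:8, 1:8] = 1
        a[1:8, 13:20] = 1
        a[4, 8:13] = 1
        ps = extract_patches(classify(Grid(a, 30.0)))
        assert sorted(p.mspa_class for p in ps) == ["bridge", "core", "core"]

    def test_count_matches_flood_fill_oracle(self, rng):
        fg = rng.random((25, 25)) < 0.5
        cls = classify(Grid(fg.astype(np.uint8), 30.0))
        ps = extract_patches(cls)
        expected = flood_fill_count(cls.values == MspaClass.CORE) + flood_fill_count(
            cls.values == MspaClass.BRIDGE
        )
        assert len(ps) == expected

    def test_empty(self):
        assert extract_patches(classify(Grid(np.zeros((4, 4), np.uint8), 30.0))) == []


class TestPairwiseDistances:
    def test_five_columns_apart(self):
        ps = [patch(0, 1.0, 0, 0), patch(1, 1.0, 0, 5)]
        assert pairwise_distances(ps, 30.0)[0, 1] == pytest.approx(150.0)

    def test_three_four_five(self):
        ps = [patch(0, 1.0, 0, 0), patch(1, 1.0, 3, 4)]
        assert pairwise_distances(ps, 30.0)[0, 1] == pytest.approx(150.0)

    def test_matches_exhaustive_scan(self, rng):
        ps = []
        for i in range(10):
            k = int(rng.integers(1, 6))
            rows = rng.integers(0, 40, size=k)
            cols = rng.integers(0, 40, size=k)
            ps.append(Patch(i, "core", rows, cols, k * 0.09))
        d = pairwise_distances(ps, 30.0)
        for i in range(10):
            for j in range(10):
                if i != j:
                    expect = min_patch_distance(
                        list(zip(ps[i].rows, ps[i].cols)),
                        list(zip(ps[j].rows, ps[j].cols)),
                        30.0,
                    )
                    assert d[i, j] == pytest.approx(expect)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


class TestIndices:
    def test_iic_closed_forms(self):
        assert iic(graph_from([10.0], [[0.0]])) == pytest.approx(0.01)
        iso = graph_from([10.0, 10.0], [[0, 5], [5, 0]])  # d > theta
        assert iic(iso) == pytest.approx(0.02)
        linked = graph_from([10.0, 10.0], [[0, 0.5], [0.5, 0]])
        assert iic(linked) == pytest.approx(0.03)

    def test_pc_closed_forms(self):
        assert pc(graph_from([10.0], [[0.0]])) == pytest.approx(0.01)
        half = graph_from([10.0, 10.0], [[0, 1.0], [1.0, 0]])  # p = 0.5 at theta
        assert pc(half) == pytest.approx(0.03)

    def test_pstar_two_step_beats_direct(self):
        # p(1,2) = p(2,3) = 0.8, p(1,3) = 0.5 -> p*(1,3) = 0.64
        d12 = np.log(0.8) / np.log(0.5)
        d = np.array([[0, d12, 1.0], [d12, 0, d12], [1.0, d12, 0]])
        g = graph_from([10, 10, 10], d)
        assert g.p_star[0, 2] == pytest.approx(0.64, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_oracle_equivalence_small_graphs(self, rng, trial):
        """nl, p*, IIC and PC against BFS / exhaustive-path brute force (1e-12)."""
        g = random_graph(rng)
        links = g.links
        nl = bfs_link_counts(links)
        assert np.array_equal(np.isfinite(g.nl), np.isfinite(nl))
        assert np.allclose(g.nl[np.isfinite(nl)], nl[np.isfinite(nl)], atol=1e-12)
        p_star = max_product_paths(g.p, links)
        assert np.allclose(g.p_star, p_star, atol=1e-12)
        assert iic(g) == pytest.approx(iic_bruteforce(g.areas, nl, g.A_L), abs=1e-12)
        assert pc(g) == pytest.approx(pc_bruteforce(g.areas, p_star, g.A_L), abs=1e-12)

    def test_pc_all_links_probability_one(self, rng):
        """With p = 1 on a connected graph, PC = (sum a)^2 / A_L^2."""
        g = random_graph(rng, theta=1e9)
        g.p_half = 1.0 - 1e-15
        total = g.areas.sum()
        assert pc(g) == pytest.approx(total**2 / g.A_L**2, rel=1e-9)

    def test_relabel_invariance(self, rng):
        g = random_graph(rng)
        perm = rng.permutation(g.n)
        g2 = PatchGraph(
            patches=[g.patches[i] for i in perm],
            A_L=g.A_L,
            d=g.d[np.ix_(perm, perm)],
            theta=g.theta,
        )
        assert iic(g2) == pytest.approx(iic(g), abs=1e-14)
        assert pc(g2) == pytest.approx(pc(g), abs=1e-14)


class TestImportance:
    def test_two_identical_isolated(self):
        g = graph_from([10.0, 10.0], [[0, 5], [5, 0]])
        recs = delta_importance(g)
        assert all(r.dIIC == pytest.approx(50.0) for r in recs)
        assert all(r.dPC == pytest.approx(50.0) for r in recs)

    def test_single_patch_full_importance(self):
        recs = delta_importance(graph_from([10.0], [[0.0]]))
        assert recs[0].dIIC == pytest.approx(100.0)

    def test_leave_one_out_oracle(self, rng):
        g = random_graph(rng)
        recs = delta_importance(g)
        base_iic = iic(g)
        base_pc = pc(g)
        for k, rec in enumerate(recs):
            keep = [i for i in range(g.n) if i != k]
            sub = PatchGraph(
                patches=[g.patches[i] for i in keep],
                A_L=g.A_L,
                d=g.d[np.ix_(keep, keep)],
                theta=g.theta,
            )
            sub_links = sub.links
            nl = bfs_link_counts(sub_links)
            p_star = max_product_paths(sub.p, sub_links)
            exp_iic = 100 * (base_iic - iic_bruteforce(sub.areas, nl, g.A_L)) / base_iic
            exp_pc = 100 * (base_pc - pc_bruteforce(sub.areas, p_star, g.A_L)) / base_pc
            assert rec.dIIC == pytest.approx(exp_iic, abs=1e-12)
            assert rec.dPC == pytest.approx(exp_pc, abs=1e-12)
            assert rec.dIIC >= -1e-12 and rec.dPC >= -1e-12


class TestThresholdSweep:
    def test_isolated_closed_form_and_saturation(self, rng):
        g = random_graph(rng, n=5)
        ps, areas = g.patches, g.areas
        tiny = 0.5 * g.d[g.d > 0].min()
        huge = 2.0 * g.d.max()
        curves = threshold_sweep(
            ps, g.A_L, [tiny, huge, 1.1 * huge], [p.id for p in ps], 30.0, d=g.d
        )
        lo = curves[curves.threshold_m == tiny].set_index("patch_id")
        for i, p in enumerate(ps):
            expect = 100.0 * areas[i] ** 2 / (areas**2).sum()
            assert lo.loc[p.id, "dIIC"] == pytest.approx(expect)
        hi1 = curves[curves.threshold_m == huge].set_index("patch_id")
        hi2 = curves[curves.threshold_m == 1.1 * huge].set_index("patch_id")
        # link graph complete -> dIIC frozen; dPC still moves slightly because
        # the dispersal half-distance is tied to the threshold
        assert np.allclose(hi1["dIIC"], hi2["dIIC"])
        assert np.allclose(hi1["dPC"], hi2["dPC"], atol=0.5)

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            threshold_sweep([patch(0, 1.0)], 10.0, [200.0, 100.0], [0], 30.0)


class TestHubSelection:
    def test_printed_importance_ranking(self):
        """Ranking the printed dIIC values reproduces the published hub order."""
        dIIC = [28.374, 10.478, 4.773, 5.642, 2.915, 3.100, 3.728, 18.159, 10.994, 13.935]
        dA = [13.666, 5.202, 2.669, 3.751, 1.829, 1.802, 2.196, 9.590, 6.384, 8.905]
        recs = [
            ImportanceRecord(patch_id=i + 1, dA=dA[i], dIIC=dIIC[i], dPC=0.0)
            for i in range(10)
        ]
        hubs = rank_and_select_hubs(recs, k=10)
        assert [r.patch_id for r in hubs.records] == [1, 8, 10, 9, 2, 4, 3, 7, 6, 5]
        assert all(lvl == "extremely important" for lvl in hubs.levels.values())

    def test_k_equals_n(self):
        recs = [ImportanceRecord(i, 10.0, float(i), 0.0) for i in range(4)]
        hubs = rank_and_select_hubs(recs, k=4)
        assert sorted(hubs.hub_ids) == [0, 1, 2, 3]

    def test_tie_break_deterministic(self):
        recs1 = [ImportanceRecord(i, 5.0, 1.0, 1.0) for i in range(6)]
        recs2 = [ImportanceRecord(i, 5.0, 1.0, 1.0) for i in range(6)]
        h1 = rank_and_select_hubs(recs1, k=2)
        h2 = rank_and_select_hubs(recs2, k=2)
        assert h1.hub_ids == h2.hub_ids == [0, 1]  # smaller id wins ties

    def test_levels_split_below_hubs(self):
        recs = [ImportanceRecord(i, 1.0, v, v) for i, v in enumerate([50, 40, 10, 9, 1, 0.5])]
        hubs = rank_and_select_hubs(recs, k=2)
        assert hubs.levels[0] == hubs.levels[1] == "extremely important"
        assert hubs.levels[2] == hubs.levels[3] == "important"
        assert hubs.levels[4] == hubs.levels[5] == "general"
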