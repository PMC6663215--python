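"""Unit and property tests for the four Mapper stages."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shapegraph as sg


# ---------------------------------------------------------------------------
# lens
# ---------------------------------------------------------------------------

class TestLens:
    def test_identity_returns_columns_verbatim(self, trefoil):
        lens = sg.apply_lens(trefoil, sg.LensConfig("identity", dims=(0, 1)))
        np.testing.assert_array_equal(lens.coords, trefoil.values[:, :2])

    def test_pca_matches_eigendecomposition_oracle(self, rng):
        # all columns constant except column 0 -> the covariance has a single
        # nonzero eigenvalue and PCA must recover the centered column (up to sign)
        col = rng.normal(size=20)
        X = np.column_stack([col, np.full(20, 3.0), np.full(20, -1.0)])
        # independent oracle: brute-force eigendecomposition of the covariance
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc.T, bias=True))
        oracle = Xc @ evecs[:, np.argmax(evals)]
        lens = sg.apply_lens(sg.DataMatrix(X), sg.LensConfig("pca", n_components=1))
        got = lens.coords[:, 0]
        sign = np.sign(np.dot(got, oracle)) or 1.0
        np.testing.assert_allclose(got, sign * oracle, atol=1e-10)
        np.testing.assert_allclose(np.abs(got), np.abs(X[:, 0] - X[:, 0].mean()),
                                   atol=1e-10)

    def test_tsne_reproducible_with_fixed_seed(self, rng):
        X = sg.DataMatrix(rng.normal(size=(30, 4)))
        cfg = sg.LensConfig("tsne", n_components=2, seed=42,
                            method_params={"perplexity": 5.0})
        a = sg.apply_lens(X, cfg)
        b = sg.apply_lens(X, cfg)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_custom_lens_and_errors(self, trefoil):
        cfg = sg.LensConfig("custom", n_components=1,
                            method_params={"function": lambda x: x[:, 2]})
        lens = sg.apply_lens(trefoil, cfg)
        assert lens.coords.shape == (100, 1)
        with pytest.raises(ValueError):
            sg.apply_lens(trefoil, sg.LensConfig("nope"))
        with pytest.raises(ValueError):
            sg.apply_lens(trefoil, sg.LensConfig("identity", dims=(0, 7)))
        with pytest.raises(ValueError):
            sg.apply_lens(trefoil, sg.LensConfig("pca", n_components=99))


# ---------------------------------------------------------------------------
# cover
# ---------------------------------------------------------------------------

def _lens_1d(values):
    return sg.Lens(np.asarray(values, dtype=float)[:, None],
                   sg.LensConfig("identity", dims=(0,)))


class TestCover:
    def test_single_interval_spans_range(self):
        cover = sg.build_cover(_lens_1d([0.0, 10.0]), resolution=1, gain=4)
        assert cover.intervals[0] == [(0.0, 10.0)]

    @pytest.mark.parametrize("gain,expected", [(3, 2 / 3), (5, 4 / 5)])
    def test_printed_overlap_anchors(self, gain, expected):
        cover = sg.build_cover(_lens_1d([0.0, 1.0]), resolution=17, gain=gain)
        assert cover.overlap_fraction(0) == pytest.approx(expected, rel=1e-12)

    @given(R=st.integers(2, 40), G=st.integers(1, 8),
           lo=st.floats(-1e3, 1e3), span=st.floats(1e-6, 1e3))
    def test_cover_geometry_invariants(self, R, G, lo, span):
        cover = sg.build_cover(_lens_1d([lo, lo + span]), R, G)
        ivs = cover.intervals[0]
        assert len(ivs) == R
        widths = np.array([b - a for a, b in ivs])
        assert np.allclose(widths, widths[0], rtol=1e-9)
        # adjacent overlap fraction = (G-1)/G
        assert cover.overlap_fraction(0) == pytest.approx((G - 1) / G, rel=1e-9)
        # sorted by lo; first starts at min, last ends at max; union covers
        assert ivs[0][0] == pytest.approx(lo)
        assert ivs[-1][1] == pytest.approx(lo + span)
        los = [a for a, _ in ivs]
        assert los == sorted(los)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            assert a1 <= b0 + 1e-12  # no gaps

    def test_zero_range_degenerates_with_warning(self):
        with pytest.warns(RuntimeWarning):
            cover = sg.build_cover(_lens_1d([2.0, 2.0, 2.0]), 5, 3)
        assert cover.intervals[0] == [(2.0, 2.0)]

    def test_rejects_zero_resolution_or_gain(self):
        with pytest.raises(ValueError):
            sg.build_cover(_lens_1d([0, 1]), 0, 3)
        with pytest.raises(ValueError):
            sg.build_cover(_lens_1d([0, 1]), 5, 0)


# ---------------------------------------------------------------------------
# bin assignment
# ---------------------------------------------------------------------------

class TestAssignBins:
    def test_minimum_in_first_interval_only(self):
        lens = _lens_1d(np.linspace(0, 1, 20))
        cover = sg.build_cover(lens, 5, 2)
        bins = sg.assign_bins(lens, cover).bins
        holding_min = [t for t, m in bins.items() if 0 in m]
        assert holding_min == [(0,)]

    def test_resolution_one_puts_everything_in_one_bin(self):
        lens = _lens_1d(np.linspace(0, 1, 10))
        bins = sg.assign_bins(lens, sg.build_cover(lens, 1, 3)).bins
        assert list(bins) == [(0,)] and len(bins[(0,)]) == 10

    @given(seed=st.integers(0, 10_000), R=st.integers(2, 25), G=st.integers(1, 6))
    def test_membership_bound_and_total_coverage(self, seed, R, G):
        # no sample in more than G intervals per dimension; every sample binned
        rng = np.random.default_rng(seed)
        lens = _lens_1d(rng.uniform(-5, 5, size=30))
        cover = sg.build_cover(lens, R, G)
        bins = sg.assign_bins(lens, cover).bins
        counts = np.zeros(30, dtype=int)
        for members in bins.values():
            counts[members] += 1
        assert counts.min() >= 1
        assert counts.max() <= G

    def test_interior_point_membership_matches_bruteforce(self):
        lens = _lens_1d(np.linspace(0, 1, 50))
        cover = sg.build_cover(lens, 10, 3)
        bins = sg.assign_bins(lens, cover).bins
        # brute-force enumeration of interval membership for every sample
        for i, x in enumerate(lens.coords[:, 0]):
            expected = {
                (j,) for j, (a, b) in enumerate(cover.intervals[0]) if a <= x <= b
            }
            got = {t for t, m in bins.items() if i in m}
            assert got == expected

    def test_dimension_mismatch_rejected(self, trefoil):
        lens2 = sg.apply_lens(trefoil, sg.LensConfig("identity", dims=(0, 1)))
        lens1 = sg.apply_lens(trefoil, sg.LensConfig("identity", dims=(0,)))
        cover1 = sg.build_cover(lens1, 5, 2)
        with pytest.raises(ValueError):
            sg.assign_bins(lens2, cover1)


# ---------------------------------------------------------------------------
# within-bin clustering
# ---------------------------------------------------------------------------

class TestClusterBin:
    def test_singleton_bin(self, trefoil):
        assert sg.cluster_bin(trefoil, [7]) == [[7]]

    def test_duplicate_rows_form_one_cluster(self):
        d = sg.DataMatrix(np.zeros((5, 3)))
        assert sg.cluster_bin(d, list(range(5))) == [list(range(5))]

    def test_two_tight_pairs_split_by_gap(self):
        # pairs 0.01 apart, separated by a gap 100x larger: the first-empty-
        # histogram-bin cut must yield exactly the two pairs
        d = sg.DataMatrix(np.array([[0.0], [0.01], [1.0], [1.01]]))
        clusters = sg.cluster_bin(d, [0, 1, 2, 3])
        assert sorted(map(sorted, clusters)) == [[0, 1], [2, 3]]

    def test_matches_bruteforce_dendrogram_cut(self, rng):
        # independent oracle: recompute single-linkage heights by brute-force
        # agglomeration, apply the same histogram rule, compare partitions
        pts = np.concatenate([rng.normal(0, 0.05, 6), rng.normal(10, 0.05, 5)])
        d = sg.DataMatrix(pts[:, None])
        clusters = {frozenset(c) for c in sg.cluster_bin(d, list(range(11)))}

        groups = [{i} for i in range(11)]
        heights = []
        while len(groups) > 1:
            best = min(
                ((a, b) for a in range(len(groups)) for b in range(a + 1, len(groups))),
                key=lambda ab: min(abs(pts[i] - pts[j])
                                   for i in groups[ab[0]] for j in groups[ab[1]]),
            )
            a, b = best
            heights.append(min(abs(pts[i] - pts[j])
                               for i in groups[a] for j in groups[b]))
            groups[a] |= groups[b]
            groups.pop(b)
        counts, edges = np.histogram(heights, bins=10)
        threshold = edges[np.flatnonzero(counts == 0)[0]]
        # rebuild the partition by merging below the threshold
        oracle = [{i} for i in range(11)]
        merged = True
        while merged:
            merged = False
            for a in range(len(oracle)):
                for b in range(a + 1, len(oracle)):
                    if min(abs(pts[i] - pts[j])
                           for i in oracle[a] for j in oracle[b]) < threshold:
                        oracle[a] |= oracle.pop(b)
                        merged = True
                        break
                if merged:
                    break
        assert clusters == {frozenset(s) for s in oracle}

    @given(seed=st.integers(0, 2_000))
    @settings(max_examples=25)
    def test_clusters_partition_the_bin(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 15))
        d = sg.DataMatrix(rng.normal(size=(n, 3)))
        members = list(range(n))
        clusters = sg.cluster_bin(d, members)
        flat = sorted(i for c in clusters for i in c)
        assert flat == members  # disjoint cover of the bin
        assert all(len(c) > 0 for c in clusters)


# ---------------------------------------------------------------------------
# linking / nerve
# ---------------------------------------------------------------------------

class TestLinkClusters:
    def test_shared_sample_makes_exactly_one_edge(self):
        g = sg.link_clusters([((0,), [0, 1]), ((1,), [1, 2])], 3)
        assert g.n_edges == 1 and g.edges[0] == (0, 1)

    def test_disjoint_clusters_make_no_edge(self):
        g = sg.link_clusters([((0,), [0, 1]), ((1,), [2, 3])], 4)
        assert g.n_edges == 0

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=30)
    def test_nerve_matches_double_loop_oracle(self, seed):
        # every edge <-> nonempty member intersection, via an independent scan
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        C = int(rng.integers(2, 12))
        clusters = []
        for i in range(C):
            size = int(rng.integers(1, 6))
            clusters.append(((i,), sorted(rng.choice(n, size, replace=False))))
        g = sg.link_clusters(clusters, n)
        expected = set()
        for i in range(C):
            for j in range(i + 1, C):
                if set(clusters[i][1]) & set(clusters[j][1]):
                    expected.add((i, j))
        assert set(g.edges) == expected
        assert all(a != b for a, b in g.edges)  # no self-edges
        assert len(g.edges) == len(set(g.edges))  # no duplicates


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _trefoil_config(**kw):
    return sg.MapperConfig(
        lens=sg.LensConfig("identity", dims=(0, 1)),
        resolution=kw.get("resolution", 6),
        gain=kw.get("gain", 5),
    )


class TestRunMapper:
    def test_single_sample_gives_single_node_no_edges(self):
        d = sg.DataMatrix(np.array([[1.0, 2.0, 3.0]]))
        g = sg.run_mapper(d, _trefoil_config())
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.nodes[0].members == (0,)

    def test_rerun_is_deterministic(self, trefoil):
        a = sg.run_mapper(trefoil, _trefoil_config())
        b = sg.run_mapper(trefoil, _trefoil_config())
        assert [(n.bin, n.members) for n in a.nodes] == [
            (n.bin, n.members) for n in b.nodes
        ]
        assert a.edges == b.edges

    def test_every_sample_lands_in_a_node(self, trefoil):
        g = sg.run_mapper(trefoil, _trefoil_config())
        covered = set()
        for nd in g.nodes:
            covered.update(nd.members)
        assert covered == set(range(100))

    def test_provenance_records_config(self, trefoil):
        g = sg.run_mapper(trefoil, _trefoil_config())
        assert g.provenance["resolution"] == 6
        assert g.provenance["gain"] == 5
        assert g.provenance["lens"]["method"] == "identity"

    def test_graph_json_round_trip(self, tmp_path, trefoil):
        g = sg.run_mapper(trefoil, _trefoil_config())
        sg.save_graph_json(g, tmp_path / "g.json")
        back = sg.load_graph_json(tmp_path / "g.json")
        assert [(n.id, n.bin, n.members) for n in back.nodes] == [
            (n.id, n.bin, n.members) for n in g.nodes
        ]
        assert back.edges == g.edges and back.n_samples == g.n_samples

    def test_trefoil_graph_is_connected_single_component(self, trefoil):
        g = sg.run_mapper(trefoil, _trefoil_config())
        import networkx as nx

        assert nx.is_connected(g.to_networkx())
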