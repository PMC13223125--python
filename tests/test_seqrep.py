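"""Sliding windows, event detection, descriptors, NJ trees, tree maps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drpkit import seqrep, simulate
from drpkit.seqrep import SegmentEvent
from drpkit.simulate import PlannedEvent


class TestWindows:
    @pytest.mark.parametrize(
        "L,Lw,Sw,expected_starts",
        [
            (10, 4, 2, [1, 3, 5, 7]),
            (4, 4, 1, [1]),
            (7, 4, 1, [1, 2, 3, 4]),
        ],
    )
    def test_window_enumeration(self, L, Lw, Sw, expected_starts):
        seq = "ACGT" * 10
        ws = seqrep.make_windows(seq[:L], Lw, Sw)
        assert [w.start for w in ws.windows] == expected_starts
        assert all(len(w.subsequence) == Lw for w in ws.windows)
        # windows are literal substrings at their 1-based positions
        for w in ws.windows:
            assert seq[w.start - 1 : w.start - 1 + Lw] == w.subsequence

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            ws = seqrep.make_windows("ACG", 5, 1)
        assert len(ws) == 0

    @given(
        L=st.integers(1, 80),
        Lw=st.integers(1, 20),
        Sw=st.integers(1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_window_count_formula(self, L, Lw, Sw):
        seq = ("ACGT" * (L // 4 + 1))[:L]
        if L < Lw:
            with pytest.warns(UserWarning):
                ws = seqrep.make_windows(seq, Lw, Sw)
            assert len(ws) == 0
        else:
            ws = seqrep.make_windows(seq, Lw, Sw)
            assert len(ws) == (L - Lw) // Sw + 1


class TestDetectEvents:
    def test_tandem_repeat_called_as_duplication(self):
        segs = seqrep.detect_events("ACGTACGT", "ACGTACGT", k_min=4)
        dups = [s for s in segs.segments if s.kind == "duplication"]
        assert any(s.subsequence == "ACGT" for s in dups)

    def test_whole_window_palindrome_called_as_mirror(self):
        segs = seqrep.detect_events("ACGTTGCA", "ACGTTGCA", k_min=8)
        mirrors = [s for s in segs.segments if s.kind == "mirror"]
        assert [m.subsequence for m in mirrors] == ["ACGTTGCA"]

    def test_identical_windows_emit_no_indels(self):
        w = "ACGTGCTA"
        segs = seqrep.detect_events(w, w, k_min=4)
        assert not any(
            s.kind in ("insertion", "deletion") for s in segs.segments
        )

    def test_plain_window_emits_nothing(self):
        # no repeats, palindromes, or inversions of length >= 4
        segs = seqrep.detect_events("AACGTC", "AACGTC", k_min=4)
        assert len(segs) == 0

    def test_planted_events_recovered(self, rng):
        """Whole-sequence scans recover >= 95% of planted events."""
        kinds = list(simulate.EVENT_KINDS)
        planted = 0
        recovered = 0
        for trial in range(40):
            ref = "".join(rng.choice(list("ACGT"), size=150))
            events = simulate.plan_events(rng, 150, n_events=3, event_length=10)
            variant = simulate.mutate_sequences({"g": ref}, {"g": events})["g"]
            segs = seqrep.scan_sequence(variant, ref, k_min=4)
            by_kind = {}
            for s in segs.segments:
                by_kind.setdefault(s.kind, []).append(s)
            for ev in events:
                planted += 1
                seg_ref = ref[ev.position : ev.position + ev.length]
                if _event_recovered(ev, seg_ref, by_kind, variant):
                    recovered += 1
        assert planted >= 100
        assert recovered / planted >= 0.95


def _event_recovered(ev, seg_ref, by_kind, variant):
    found = by_kind.get(ev.kind, [])
    if ev.kind == "duplication":
        return any(d.subsequence in seg_ref + seg_ref for d in found)
    if ev.kind == "mirror":
        half = seg_ref[: (ev.length + 1) // 2]
        pal = half + half[: ev.length // 2][::-1]
        return any(pal in m.subsequence or m.subsequence in pal for m in found)
    if ev.kind == "inversion":
        return any(seg_ref[::-1] in s.subsequence or s.subsequence in seg_ref[::-1]
                   for s in found)
    if ev.kind == "insertion":
        return any(s.subsequence in ev.payload or ev.payload in s.subsequence
                   for s in found)
    if ev.kind == "deletion":
        return any(s.subsequence in seg_ref or seg_ref in s.subsequence
                   for s in found)
    return False


class TestDescriptors:
    def test_composition_and_gc(self):
        vec = seqrep.segment_descriptor(SegmentEvent("ACGT", "duplication", 0, 4))
        assert vec[0] == 4
        assert vec[1] == pytest.approx(0.5)
        np.testing.assert_allclose(vec[2:6], 0.25)
        assert vec.shape == (seqrep.DESCRIPTOR_LENGTH,)

    def test_homopolymer_has_zero_dimer_entropy(self):
        vec = seqrep.segment_descriptor(SegmentEvent("AAAA", "insertion", 0, 4))
        assert vec[-1] == 0.0

    def test_descriptor_deterministic_and_event_onehot(self):
        seg = SegmentEvent("ACGGT", "mirror", 2, 5)
        a = seqrep.segment_descriptor(seg)
        b = seqrep.segment_descriptor(seg)
        np.testing.assert_array_equal(a, b)
        onehot = a[6:11]
        assert onehot.sum() == 1.0
        assert onehot[seqrep.EVENT_KINDS.index("mirror")] == 1.0


def _random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive branch lengths -> additive matrix."""
    import networkx as nx

    G = nx.Graph()
    nodes = [f"L{i}" for i in range(n_leaves)]
    free = list(nodes)
    nxt = 0
    while len(free) > 2:
        i = rng.integers(len(free))
        a = free.pop(int(i))
        j = rng.integers(len(free))
        b = free.pop(int(j))
        parent = f"X{nxt}"
        nxt += 1
        G.add_edge(a, parent, length=float(rng.uniform(0.5, 2.0)))
        G.add_edge(b, parent, length=float(rng.uniform(0.5, 2.0)))
        free.append(parent)
    if len(free) == 2:
        G.add_edge(free[0], free[1], length=float(rng.uniform(0.5, 2.0)))
    import networkx as nx

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(nodes):
        ln = nx.single_source_dijkstra_path_length(G, a, weight="length")
        for j, b in enumerate(nodes):
            D[i, j] = ln[b]
    D = (D + D.T) / 2.0  # exact symmetry for downstream consumers
    return D, nodes, G


def _leaf_splits(graph, leaves):
    """Set of nontrivial leaf bipartitions induced by the tree's edges."""
    import networkx as nx

    splits = set()
    for u, v in graph.edges:
        H = graph.copy()
        H.remove_edge(u, v)
        comp = nx.node_connected_component(H, u)
        side = frozenset(l for l in leaves if l in comp)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, frozenset(leaves) - side, key=sorted))
    return splits


class TestNeighborJoining:
    def test_two_leaves_single_edge(self):
        tree = seqrep.mnja_build_tree(
            distance_matrix=np.array([[0.0, 3.0], [3.0, 0.0]]), labels=["a", "b"]
        )
        assert tree.graph["a"]["b"]["length"] == pytest.approx(3.0)

    def test_three_leaves_three_point_formula(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = seqrep.mnja_build_tree(distance_matrix=D, labels=["a", "b", "c"])
        hub = [n for n in tree.graph.nodes if n.startswith("I")][0]
        assert tree.graph["a"][hub]["length"] == pytest.approx((5 + 9 - 10) / 2)
        assert tree.graph["b"][hub]["length"] == pytest.approx((5 + 10 - 9) / 2)
        assert tree.graph["c"][hub]["length"] == pytest.approx((9 + 10 - 5) / 2)

    def test_single_descriptor_pair_distance_is_euclidean(self):
        d1 = np.zeros(3)
        d2 = np.array([3.0, 4.0, 0.0])
        tree = seqrep.mnja_build_tree([d1, d2])
        assert tree.graph["S0"]["S1"]["length"] == pytest.approx(5.0)

    def test_additive_matrices_reconstructed_exactly(self, rng):
        """Topology and patristic distances recovered on additive input
        (up to 6 leaves), cross-checked against scikit-bio's NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for n_leaves in (4, 5, 6):
            for _ in range(5):
                D, names, gen_tree = _random_additive_matrix(rng, n_leaves)
                tree = seqrep.mnja_build_tree(
                    distance_matrix=D, labels=names
                )
                # patristic distances reproduce the additive matrix
                P = tree.patristic_distances(names)
                np.testing.assert_allclose(P, D, atol=1e-9)
                # topology matches the generating tree's splits
                assert _leaf_splits(tree.graph, names) == _leaf_splits(
                    gen_tree, names
                )
                # independent oracle agrees on patristic distances
                sk = skbio_nj(DistanceMatrix(D, names))
                for a, b in itertools.combinations(names, 2):
                    d_oracle = sk.find(a).distance(sk.find(b))
                    assert abs(
                        P[names.index(a), names.index(b)] - d_oracle
                    ) < 1e-9

    def test_exhaustive_topology_check_five_leaves(self, rng):
        """NJ's topology equals the best least-squares topology among all
        15 unrooted 5-leaf trees on additive input."""
        D, names, gen_tree = _random_additive_matrix(rng, 5)
        tree = seqrep.mnja_build_tree(distance_matrix=D, labels=names)
        recovered = _leaf_splits(tree.graph, names)
        # enumerate all 15 topologies: choose the 2 leaves paired with
        # leaf 0's cherry partner structure via pair assignments
        best = None
        for splits in _all_five_leaf_topologies(names):
            err = _ls_error(D, names, splits)
            if best is None or err < best[0]:
                best = (err, splits)
        assert best[1] == recovered
        assert best[0] < 1e-18


def _all_five_leaf_topologies(names):
    """Each unrooted binary 5-leaf tree has exactly two nontrivial splits
    (two cherries); enumerate all distinct such pairs."""
    out = []
    for cherry1 in itertools.combinations(names, 2):
        rest = [x for x in names if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            s1 = frozenset(cherry1)
            s2 = frozenset(cherry2)
            key = frozenset({s1, s2})
            if key not in {frozenset(x) for x in out}:
                out.append((s1, s2))
    # dedupe (cherry pairs are unordered)
    dedup = []
    seen = set()
    for pair in out:
        key = frozenset(pair)
        if key not in seen:
            seen.add(key)
            dedup.append(pair)
    return [
        { _canon(s, names) for s in pair } for pair in dedup
    ]


def _canon(side, names):
    side = frozenset(side)
    return min(side, frozenset(names) - side, key=sorted)


def _ls_error(D, names, splits):
    """Least-squares branch-length fit error for a 5-leaf topology given
    by its two cherry splits."""
    import networkx as nx

    splits = list(splits)
    # build the tree: two cherries attached to a central path
    cherries = [set(min(s, frozenset(names) - s, key=len)) for s in splits]
    G = nx.Graph()
    hubs = []
    used = set()
    for t, ch in enumerate(cherries):
        hub = f"H{t}"
        hubs.append(hub)
        for leaf in sorted(ch):
            G.add_edge(leaf, hub)
            used.add(leaf)
    middle = [x for x in names if x not in used]
    center = "Hc"
    G.add_edge(hubs[0], center)
    G.add_edge(hubs[1], center)
    for leaf in middle:
        G.add_edge(leaf, center)
    # least-squares branch lengths for all leaf pairs
    edges = list(G.edges)
    rows, targets = [], []
    for a, b in itertools.combinations(names, 2):
        path = nx.shortest_path(G, a, b)
        row = np.zeros(len(edges))
        for u, v in zip(path, path[1:]):
            row[edges.index((u, v)) if (u, v) in edges else edges.index((v, u))] = 1
        rows.append(row)
        targets.append(D[names.index(a), names.index(b)])
    A = np.array(rows)
    t = np.array(targets)
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    resid = A @ coef - t
    return float(resid @ resid)


class TestTreeMap:
    def test_two_leaf_map_normalized_block(self):
        tree = seqrep.mnja_build_tree(
            distance_matrix=np.array([[0.0, 3.0], [3.0, 0.0]]), labels=["S0", "S1"]
        )
        M = seqrep.tree_to_map(tree, size=8)
        np.testing.assert_allclose(M[:2, :2], [[0, 1], [1, 0]])
        assert M[2:].sum() == 0 and M[:, 2:].sum() == 0

    def test_map_symmetric_zero_diagonal_unit_range(self, rng):
        X = rng.normal(size=(7, 12))
        tree = seqrep.mnja_build_tree(list(X))
        M = seqrep.tree_to_map(tree, size=16)
        np.testing.assert_allclose(M, M.T)
        assert np.all(np.diag(M) == 0)
        assert M.min() >= 0 and M.max() <= 1

    def test_patristic_matches_brute_force_path_sums(self, rng):
        import networkx as nx

        X = rng.normal(size=(6, 12))
        tree = seqrep.mnja_build_tree(list(X))
        order = tree.leaf_order()
        P = tree.patristic_distances(order)
        for i, a in enumerate(order):
            for j, b in enumerate(order):
                path = nx.shortest_path(tree.graph, a, b)
                brute = sum(
                    tree.graph[u][v]["length"] for u, v in zip(path, path[1:])
                )
                assert P[i, j] == pytest.approx(brute, abs=1e-9)

    def test_too_many_leaves_rejected(self, rng):
        X = rng.normal(size=(9, 12))
        tree = seqrep.mnja_build_tree(list(X))
        with pytest.raises(ValueError, match="raise size"):
            seqrep.tree_to_map(tree, size=8)

    def test_newick_export_parses_and_preserves_leaves(self, rng):
        import dendropy

        X = rng.normal(size=(5, 12))
        tree = seqrep.mnja_build_tree(list(X))
        nwk = seqrep.to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert taxa == set(tree.leaves)
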