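"""Topology-aware gene sequence representations.

The pipeline turns each gene sequence into (1) a set of sliding windows,
(2) event-labeled segments found in those windows (insertion, deletion,
inversion, mirror, duplication -- structural-pattern calls, not
evolutionary inference), (3) an unrooted tree organizing the segments by
descriptor dissimilarity, built with a classical neighbor-joining
agglomeration accelerated by cached row sums, and (4) a fixed-size 2D
patristic-distance map suitable as an image channel.

Window enumeration: for a sequence of length L, window length Lw and step
Sw, windows start at 1-based positions p = 1 + m*Sw for
m = 0 .. floor((L - Lw)/Sw), giving floor((L - Lw)/Sw) + 1 windows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

EVENT_KINDS = ("insertion", "deletion", "inversion", "mirror", "duplication")


@dataclass
class Window:
    start: int  # 1-based start position in the source sequence
    subsequence: str


@dataclass
class WindowSet:
    gene_id: str
    window_length: int
    step: int
    windows: list[Window] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class SegmentEvent:
    subsequence: str
    kind: str
    start: int  # 0-based start in the analyzed window (query coordinates)
    length: int


@dataclass
class SegmentSet:
    gene_id: str
    segments: list[SegmentEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)


def make_windows(
    sequence: str, window_length: int, step: int, gene_id: str = ""
) -> WindowSet:
    """Enumerate sliding windows; empty set (with warning) for short input."""
    if window_length < 1 or step < 1:
        raise ValueError("window_length and step must be >= 1")
    ws = WindowSet(gene_id=gene_id, window_length=window_length, step=step)
    L = len(sequence)
    if L < window_length:
        warnings.warn(
            f"sequence shorter than window length ({L} < {window_length}); "
            "returning empty window set",
            stacklevel=2,
        )
        return ws
    n = (L - window_length) // step + 1
    for m in range(n):
        p = m * step  # 0-based; reported start is 1-based
        ws.windows.append(Window(start=p + 1, subsequence=sequence[p : p + window_length]))
    return ws


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------


def _maximal_common_segments(a: str, b: str, k_min: int) -> dict[str, int]:
    """Maximal common substrings of a and b with length >= k_min.

    Pair-extension scan: for every start pair with matching first symbol
    that cannot be extended left, extend right maximally. Returns segment
    -> first start position in ``a``.
    """
    out: dict[str, int] = {}
    la, lb = len(a), len(b)
    for i in range(la):
        for j in range(lb):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not left-maximal
            m = 1
            while i + m < la and j + m < lb and a[i + m] == b[j + m]:
                m += 1
            if m >= k_min:
                seg = a[i : i + m]
                if seg not in out:
                    out[seg] = i
    return out


def _maximal_repeats(s: str, k_min: int) -> dict[str, int]:
    """Maximal substrings occurring >= 2 times in ``s`` (len >= k_min)."""
    out: dict[str, int] = {}
    L = len(s)
    for i in range(L):
        for j in range(i + 1, L):
            if s[i] != s[j]:
                continue
            if i > 0 and s[i - 1] == s[j - 1]:
                continue
            m = 1
            while j + m < L and s[i + m] == s[j + m]:
                m += 1
            if m >= k_min:
                seg = s[i : i + m]
                if seg not in out:
                    out[seg] = i
    return out


def _maximal_palindromes(s: str, k_min: int) -> dict[str, int]:
    """Maximal substrings equal to their own reverse, length >= k_min."""
    found: dict[str, int] = {}
    L = len(s)
    spans: list[tuple[int, int]] = []
    for center in range(2 * L - 1):
        i, j = center // 2, (center + 1) // 2
        while i >= 0 and j < L and s[i] == s[j]:
            i -= 1
            j += 1
        start, end = i + 1, j  # half-open maximal palindrome
        if end - start >= k_min:
            spans.append((start, end))
    # drop palindromes nested inside a longer reported palindrome
    spans.sort(key=lambda t: (t[0] - t[1], t[0]))
    kept: list[tuple[int, int]] = []
    for start, end in spans:
        if not any(a <= start and end <= b for a, b in kept):
            kept.append((start, end))
    for start, end in sorted(kept):
        seg = s[start:end]
        if seg not in found:
            found[seg] = start
    return found


def detect_events(
    window: str,
    reference_window: str,
    k_min: int = 4,
    gene_id: str = "",
) -> SegmentSet:
    """Call structural events in a window relative to its local reference.

    duplication: maximal substring of length >= k_min occurring at least
    twice within the window. mirror: maximal palindromic substring (equal
    to its own reverse). inversion: maximal reference substring whose
    reverse occurs in the window while the forward form does not (and
    which is not itself a palindrome). insertion/deletion: gap runs in the
    global edit alignment of window against reference.
    """
    import edlib

    segs = SegmentSet(gene_id=gene_id)

    for seg, pos in sorted(_maximal_repeats(window, k_min).items()):
        segs.segments.append(SegmentEvent(seg, "duplication", pos, len(seg)))

    for seg, pos in sorted(_maximal_palindromes(window, k_min).items()):
        segs.segments.append(SegmentEvent(seg, "mirror", pos, len(seg)))

    rev_window = window[::-1]
    for seg, ref_pos in sorted(
        _maximal_common_segments(reference_window, rev_window, k_min).items()
    ):
        if seg in window or seg == seg[::-1]:
            continue
        pos = window.find(seg[::-1])
        segs.segments.append(SegmentEvent(seg[::-1], "inversion", pos, len(seg)))

    if window != reference_window:
        aln = edlib.align(window, reference_window, task="path", mode="NW")
        qpos = tpos = 0
        for num, op in _parse_cigar(aln["cigar"]):
            if op in ("=", "X", "M"):
                qpos += num
                tpos += num
            elif op == "I":  # present in window only
                segs.segments.append(
                    SegmentEvent(window[qpos : qpos + num], "insertion", qpos, num)
                )
                qpos += num
            elif op == "D":  # present in reference only
                segs.segments.append(
                    SegmentEvent(
                        reference_window[tpos : tpos + num], "deletion", qpos, num
                    )
                )
                tpos += num
    return segs


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def scan_sequence(
    variant: str, reference: str, k_min: int = 4, gene_id: str = ""
) -> SegmentSet:
    """Whole-sequence event scan (window = full variant sequence)."""
    return detect_events(variant, reference, k_min=k_min, gene_id=gene_id)


# ---------------------------------------------------------------------------
# Segment descriptors
# ---------------------------------------------------------------------------

_EVENT_INDEX = {kind: i for i, kind in enumerate(EVENT_KINDS)}

DESCRIPTOR_LENGTH = 12
DESCRIPTOR_NAMES = (
    "length",
    "gc_fraction",
    "frac_A",
    "frac_C",
    "frac_G",
    "frac_T",
    *(f"event_{k}" for k in EVENT_KINDS),
    "dimer_entropy",
)


def segment_descriptor(segment: SegmentEvent) -> np.ndarray:
    """12-value descriptor: length, GC, base composition, one-hot event,
    2-mer Shannon entropy (bits)."""
    s = segment.subsequence
    if not s:
        raise ValueError("empty segment")
    n = len(s)
    counts = {b: s.count(b) for b in "ACGT"}
    onehot = np.zeros(len(EVENT_KINDS))
    onehot[_EVENT_INDEX[segment.kind]] = 1.0
    if n >= 2:
        dimers = [s[i : i + 2] for i in range(n - 1)]
        _, freq = np.unique(dimers, return_counts=True)
        p = freq / freq.sum()
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    return np.array(
        [
            float(n),
            (counts["G"] + counts["C"]) / n,
            counts["A"] / n,
            counts["C"] / n,
            counts["G"] / n,
            counts["T"] / n,
            *onehot,
            entropy,
        ]
    )


# ---------------------------------------------------------------------------
# Neighbor-joining segment trees
# ---------------------------------------------------------------------------


@dataclass
class SegmentTree:
    """Unrooted tree over segments with branch lengths on the edges."""

    gene_id: str
    graph: nx.Graph
    leaves: list[str]

    def leaf_order(self) -> list[str]:
        """Deterministic depth-first leaf ordering from a fixed root."""
        nodes = sorted(self.graph.nodes, key=str)
        internals = [n for n in nodes if str(n).startswith("I")]
        root = internals[0] if internals else nodes[0]
        order = []
        seen = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in self.leaves:
                order.append(node)
            for nbr in sorted(self.graph.neighbors(node), key=str, reverse=True):
                if nbr not in seen:
                    stack.append(nbr)
        return order

    def patristic_distances(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """All-pairs path-length distances between leaves."""
        order = list(order) if order is not None else self.leaf_order()
        n = len(order)
        D = np.zeros((n, n))
        for i, leaf in enumerate(order):
            lengths = nx.single_source_dijkstra_path_length(
                self.graph, leaf, weight="length"
            )
            for j, other in enumerate(order):
                D[i, j] = lengths[other]
        np.fill_diagonal(D, 0.0)
        return D


def mnja_build_tree(
    descriptors: Optional[Sequence[np.ndarray]] = None,
    distance_matrix: Optional[np.ndarray] = None,
    labels: Optional[Sequence[str]] = None,
    gene_id: str = "",
) -> SegmentTree:
    """Neighbor-joining agglomeration with cached row sums.

    Dissimilarity is Euclidean distance between segment descriptors (or a
    caller-supplied distance matrix). Uses the standard Q-criterion
    Q_ij = (n-2) d_ij - r_i - r_j, the three-point/branch-length formulas
    of classical NJ, ties broken toward the lowest (i, j) index pair, and
    negative branch lengths clipped to zero. The row sums r_i are cached
    and updated incrementally after each merge (the acceleration); merge
    semantics are classical NJ, so additive input distances reconstruct
    the generating topology and branch lengths.
    """
    if distance_matrix is None:
        if descriptors is None:
            raise ValueError("provide descriptors or a distance matrix")
        X = np.asarray(descriptors, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 segment descriptors")
        diff = X[:, None, :] - X[None, :, :]
        distance_matrix = np.sqrt((diff**2).sum(axis=2))
    D = np.array(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with >= 2 rows")
    if labels is None:
        labels = [f"S{i}" for i in range(n)]
    labels = list(labels)

    G = nx.Graph()
    leaves = list(labels)
    active = list(range(n))  # indices into D rows, ascending
    node_of = {i: labels[i] for i in range(n)}
    row_sums = D.sum(axis=1)  # cached; updated incrementally
    next_internal = 0

    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = row_sums[idx]
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) pair among minima: row-major argmin over ascending idx
        flat = int(np.argmin(Q))
        ai, aj = flat // m, flat % m
        if ai > aj:
            ai, aj = aj, ai
        i, j = idx[ai], idx[aj]
        dij = D[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        new_name = f"I{next_internal}"
        next_internal += 1
        G.add_edge(node_of[i], new_name, length=li)
        G.add_edge(node_of[j], new_name, length=lj)

        # distances from the new node u: d_uk = (d_ik + d_jk - d_ij) / 2
        others = [k for k in active if k not in (i, j)]
        new_d = np.zeros(len(others))
        for t, k in enumerate(others):
            new_d[t] = 0.5 * (D[i, k] + D[j, k] - dij)
        # reuse row i's slot for the merged node; retire row j
        for t, k in enumerate(others):
            delta = new_d[t] - D[i, k] - D[j, k]
            row_sums[k] += delta
            D[i, k] = D[k, i] = new_d[t]
        D[i, i] = 0.0
        row_sums[i] = new_d.sum()
        node_of[i] = new_name
        active.remove(j)

    i, j = active
    G.add_edge(node_of[i], node_of[j], length=max(D[i, j], 0.0))
    if G.number_of_nodes() == 0:  # pragma: no cover - n >= 2 guaranteed
        raise ValueError("empty tree")
    return SegmentTree(gene_id=gene_id, graph=G, leaves=leaves)


def to_newick(tree: SegmentTree) -> str:
    """Serialize the (arbitrarily rooted) tree to a Newick string."""
    nodes = sorted(tree.graph.nodes, key=str)
    internals = [n for n in nodes if str(n).startswith("I")]
    root = internals[0] if internals else nodes[0]

    def render(node, parent) -> str:
        children = [c for c in sorted(tree.graph.neighbors(node), key=str) if c != parent]
        label = node if node in tree.leaves else ""
        if not children:
            return str(label)
        inner = ",".join(
            f"{render(c, node)}:{tree.graph[node][c]['length']:.10g}"
            for c in children
        )
        return f"({inner}){label}"

    return render(root, None) + ";"


def tree_to_map(tree: SegmentTree, size: int = 224) -> np.ndarray:
    """Min-max-normalized patristic leaf-distance map, zero-padded.

    Leaves are ordered by the tree's deterministic depth-first traversal;
    cell (i, j) holds the path-length distance between leaves i and j,
    scaled to [0, 1]; the matrix is zero-padded to ``size`` x ``size``.
    """
    order = tree.leaf_order()
    n = len(order)
    if n > size:
        raise ValueError(
            f"tree has {n} leaves but map size is {size}; raise size or "
            "merge segments"
        )
    D = tree.patristic_distances(order)
    dmax = D.max()
    if dmax > 0:
        D = D / dmax
    out = np.zeros((size, size))
    out[:n, :n] = D
    return out


def event_indicator_map(
    segments: Sequence[SegmentEvent], leaf_order: Sequence[int], size: int = 224
) -> np.ndarray:
    """Binary 224x224-style mask marking leaf rows/columns by event type.

    Leaf i's row band is set where its event kind index matches the
    column band modulo the five-event vocabulary; this encodes which
    event each leaf carries while staying strictly binary.
    """
    out = np.zeros((size, size))
    for row, seg_idx in enumerate(leaf_order):
        if row >= size:
            break
        kind_idx = _EVENT_INDEX[segments[seg_idx].kind]
        out[row, kind_idx::len(EVENT_KINDS)] = 1.0
    return out
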