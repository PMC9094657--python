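"""Alignment-based placement of reverse-transcriptase (and envelope)
sequences on a distance tree.

The chain is deliberately simple and fully deterministic: k-mer distances
feed a neighbor-joining guide tree; profiles are merged progressively with
the same substitution scoring used by the homology search; pairwise
Poisson-corrected distances (d = -ln(1 - p) over shared ungapped columns)
feed classic neighbor joining with lowest-index tie-breaking. Negative NJ
branch estimates are clamped to zero and logged. The testable claims are
nearest-neighbor relations, which are robust to replacing maximum
likelihood with NJ at these divergences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scoring import load_blosum62, PROTEIN_ALPHABET
from .search import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 10.0
_GAP_CHARS = "-."


@dataclass
class MSA:
    """A rectangular multiple alignment (ids in input order)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or len(self.rows) < 2:
            raise ValueError("MSA needs >= 2 rows, one id per row")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]


@dataclass
class TreeNode:
    """A rooted view of an unrooted NJ tree (root = final join)."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(
            f"{child._newick_inner()}:{float(length)!r}" for child, length in self.children
        )
        return f"({inner})"


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Jaccard distance between k-mer sets (guide-tree distances only)."""
    k = max(1, min(k, len(a), len(b)))
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    union = sa | sb
    if not union:
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequency profile (gaps contribute no mass)."""
    L = len(rows[0])
    idx = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET[:20])}
    prof = np.zeros((L, 20), dtype=np.float32)
    for row in rows:
        for j, aa in enumerate(row):
            i = idx.get(aa)
            if i is not None:
                prof[j, i] += 1.0
    return prof / len(rows)


def _merge_profiles(rows1: list[str], rows2: list[str], matrix,
                    gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Globally align two alignment blocks (profile-profile sum-of-pairs
    expected score) and return both blocks expanded to the merged columns."""
    p1 = _profile(rows1)
    p2 = _profile(rows2)
    C = (p1 @ matrix.scores[:20, :20].astype(np.float32) @ p2.T).astype(np.float32)
    M, X, Y = _kernels.nw_fill(C, np.float32(gap_open), np.float32(gap_extend))
    a_idx, b_idx, _ = _kernels.nw_traceback(
        M, X, Y, C, np.float32(gap_open), np.float32(gap_extend)
    )
    out1 = [
        "".join(row[i] if i >= 0 else "-" for i in a_idx) for row in rows1
    ]
    out2 = [
        "".join(row[i] if i >= 0 else "-" for i in b_idx) for row in rows2
    ]
    return out1, out2


def progressive_align(
    sequences: list[ProteinRecord],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MSA:
    """Guide-tree progressive alignment (k-mer NJ guide, profile merging).

    Deterministic: guide joins use the NJ Q-criterion with lowest-index
    tie-breaking on sorted taxon ids, and block orientation is fixed by the
    lexicographically smallest member id, so the result is invariant to
    input order.
    """
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    ids = [r.id for r in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    matrix = load_blosum62()
    # canonical processing order: sort by id so input order cannot matter
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    clusters = [
        {"ids": [ids[i]], "rows": [sequences[i].seq]} for i in order
    ]
    n = len(clusters)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = kmer_distance(
            clusters[i]["rows"][0], clusters[j]["rows"][0]
        )
    while len(clusters) > 1:
        m = len(clusters)
        if m == 2:
            i, j = 0, 1
        else:
            r = D.sum(axis=1)
            best = None
            for a, b in itertools.combinations(range(m), 2):
                q = (m - 2) * D[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
            _, i, j = best
        c1, c2 = clusters[i], clusters[j]
        if min(c2["ids"]) < min(c1["ids"]):
            c1, c2 = c2, c1
        rows1, rows2 = _merge_profiles(
            c1["rows"], c2["rows"], matrix, gap_open, gap_extend
        )
        merged = {"ids": c1["ids"] + c2["ids"], "rows": rows1 + rows2}
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newD[a, b] = D[ka, kb]
        for a, ka in enumerate(keep):
            newD[a, -1] = newD[-1, a] = 0.5 * (D[ka, i] + D[ka, j] - D[i, j])
        newD = np.maximum(newD, 0.0)
        clusters = [clusters[k] for k in keep] + [merged]
        D = newD
    final = clusters[0]
    by_id = dict(zip(final["ids"], final["rows"]))
    return MSA(ids=ids, rows=[by_id[i] for i in ids])


def corrected_distance(
    row_i: str, row_j: str, max_distance: float = DEFAULT_MAX_DISTANCE
) -> float:
    """Poisson-corrected distance d = -ln(1 - p) over shared ungapped columns."""
    shared = 0
    mismatches = 0
    for a, b in zip(row_i, row_j):
        if a in _GAP_CHARS or b in _GAP_CHARS:
            continue
        shared += 1
        if a != b:
            mismatches += 1
    if shared == 0:
        raise ValueError("no shared ungapped columns between rows")
    p = mismatches / shared
    if p >= 1.0:
        return max_distance
    return min(-math.log(1.0 - p), max_distance)


def msa_distance_matrix(msa: MSA, max_distance: float = DEFAULT_MAX_DISTANCE) -> DistanceMatrix:
    n = len(msa.rows)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = corrected_distance(
            msa.rows[i], msa.rows[j], max_distance
        )
    return DistanceMatrix(labels=list(msa.ids), values=vals)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining (Saitou-Nei with the Studier-Keppler Q
    matrix). Ties break toward the lowest index pair; additive matrices are
    recovered exactly. Negative branch estimates are clamped to 0."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=label) for label in dm.labels]
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        nonlocal D, active, nodes
        i, j = active[i_pos], active[j_pos]
        for branch, name in ((li, nodes[i].name), (lj, nodes[j].name)):
            if branch < 0:
                logger.info("clamping negative NJ branch %.6g (near %s)", branch, name or "internal")
        new = TreeNode(children=[(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0))])
        nodes.append(new)
        m = len(active)
        newD = np.zeros((m - 1, m - 1))
        keep = [p for p in range(m) if p not in (i_pos, j_pos)]
        for a, pa in enumerate(keep):
            for b, pb in enumerate(keep):
                newD[a, b] = D[pa, pb]
        for a, pa in enumerate(keep):
            newD[a, -1] = newD[-1, a] = 0.5 * (
                D[pa, i_pos] + D[pa, j_pos] - D[i_pos, j_pos]
            )
        D = newD
        active = [active[p] for p in keep] + [len(nodes) - 1]

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        best = None
        for a, b in itertools.combinations(range(m), 2):
            q = (m - 2) * D[a, b] - r[a] - r[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, a, b = best
        li = 0.5 * D[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = D[a, b] - li
        join(a, b, li, lj)

    # terminal 3-taxon star: branch lengths from the three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    for branch in (l0, l1, l2):
        if branch < 0:
            logger.info("clamping negative NJ branch %.6g (root)", branch)
    root = TreeNode(
        children=[
            (nodes[active[0]], max(l0, 0.0)),
            (nodes[active[1]], max(l1, 0.0)),
            (nodes[active[2]], max(l2, 0.0)),
        ]
    )
    return root


def patristic_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path-length distances between all leaf pairs (leaf depths + LCA)."""
    leaf_depth: dict[str, float] = {}
    parent_chain: dict[str, list[tuple[int, float]]] = {}

    counter = itertools.count()

    def walk2(node: TreeNode, depth: float, chain: list[tuple[int, float]]) -> None:
        nid = next(counter)
        chain = chain + [(nid, depth)]
        if node.is_leaf:
            leaf_depth[node.name] = depth
            parent_chain[node.name] = chain
            return
        for child, length in node.children:
            walk2(child, depth + length, chain)

    walk2(tree, 0.0, [])
    out: dict[tuple[str, str], float] = {}
    leaves = sorted(leaf_depth)
    for x, y in itertools.combinations(leaves, 2):
        cx, cy = parent_chain[x], parent_chain[y]
        ids_y = {nid for nid, _ in cy}
        lca_depth = max(d for nid, d in cx if nid in ids_y)
        d = leaf_depth[x] + leaf_depth[y] - 2.0 * lca_depth
        out[(x, y)] = out[(y, x)] = d
    return out


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    leaves = sorted(tree.leaves())
    dist = patristic_distances(tree)
    n = len(leaves)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = dist[(leaves[i], leaves[j])]
    return DistanceMatrix(labels=leaves, values=vals)


def nearest_neighbor(tree: TreeNode, taxon: str) -> str:
    """The leaf with minimal patristic distance to `taxon`; ties break
    alphabetically."""
    leaves = tree.leaves()
    if taxon not in leaves:
        raise ValueError(f"taxon {taxon!r} not in tree")
    dist = patristic_distances(tree)
    others = sorted(l for l in leaves if l != taxon)
    return min(others, key=lambda l: (dist[(taxon, l)], l))


def build_tree(
    sequences: list[ProteinRecord],
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> tuple[MSA, TreeNode]:
    """Align, correct distances, and join: the full placement chain."""
    msa = progressive_align(sequences)
    return msa, neighbor_joining(msa_distance_matrix(msa, max_distance))
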