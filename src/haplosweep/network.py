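"""Haplotype networks: Hamming distances, minimum spanning networks and
distance-break clustering.

Identical haplotypes are collapsed into classes before network
construction; class multiplicity annotates nodes.  The MST is built by
Kruskal's algorithm with deterministic lexicographic tie-breaking on
(weight, node, node); edges that tie the heaviest MST edge on the path they
would close are retained as network (tie) edges but are not used when
cutting components, so clustering stays well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypeDataset


@dataclass
class HaplotypeClasses:
    """Distinct haplotype strings with member column indices."""

    class_of: np.ndarray  # haplotype column -> class id
    members: list  # class id -> list of column indices
    representatives: np.ndarray  # class id -> variant vector


@dataclass
class ClusterTable:
    clusters: pd.DataFrame  # cluster_id, size, n_classes, focal-allele state...
    membership: np.ndarray  # haplotype column -> cluster id
    per_population: pd.DataFrame | None = None


def collapse_classes(matrix: np.ndarray) -> HaplotypeClasses:
    """Group identical haplotype columns (exact duplicates) into classes."""
    if matrix.shape[1] < 1:
        raise ValueError("need at least one haplotype")
    _, first_idx, inverse = np.unique(
        matrix.T, axis=0, return_index=True, return_inverse=True
    )
    # re-number classes by first appearance for order-independent output
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    class_of = rank[inverse]
    members: list[list[int]] = [[] for _ in range(len(order))]
    for col, cls in enumerate(class_of):
        members[cls].append(col)
    reps = np.stack([matrix[:, m[0]] for m in members], axis=1)
    return HaplotypeClasses(class_of=class_of, members=members, representatives=reps)


def hamming_matrix(ds: HaplotypeDataset, region: str | None = None) -> np.ndarray:
    """Integer allele-mismatch counts between all haplotype pairs."""
    sub = ds.region(region) if region else ds
    if sub.n_variants == 0:
        raise ValueError("empty region: no variants to compare")
    if sub.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    m = sub.matrix.astype(np.int32)
    # (a - b)^2 summed over variants == mismatch count for 0/1 data
    gram = m.T @ m
    ones = m.sum(axis=0)
    dist = ones[:, None] + ones[None, :] - 2 * gram
    return dist.astype(int)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_network(dist: np.ndarray) -> pd.DataFrame:
    """MST edges over haplotype classes plus tying alternative edges.

    Returns a frame (node_a, node_b, weight, is_tie_edge).  A non-tree edge
    (u, v) is a tie edge when its weight equals the maximum edge weight on
    the MST path between u and v (i.e. it could replace that edge without
    changing total weight).
    """
    dist = np.asarray(dist)
    k = dist.shape[0]
    if k == 1:
        return pd.DataFrame(columns=["node_a", "node_b", "weight", "is_tie_edge"])
    edges = sorted(
        (int(dist[a, b]), a, b) for a in range(k) for b in range(a + 1, k)
    )
    uf = _UnionFind(k)
    tree: list[tuple[int, int, int]] = []
    rest: list[tuple[int, int, int]] = []
    for w, a, b in edges:
        if uf.union(a, b):
            tree.append((w, a, b))
        else:
            rest.append((w, a, b))
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(k)}
    for w, a, b in tree:
        adj[a].append((b, w))
        adj[b].append((a, w))

    def path_max(u: int, v: int) -> int:
        # DFS over the tree; sizes are small (classes, not haplotypes)
        stack = [(u, -1, 0)]
        while stack:
            node, parent, mx = stack.pop()
            if node == v:
                return mx
            for nxt, w in adj[node]:
                if nxt != parent:
                    stack.append((nxt, node, max(mx, w)))
        raise RuntimeError("tree not connected")

    rows = [(a, b, w, False) for w, a, b in tree]
    for w, a, b in rest:
        if w == path_max(a, b):
            rows.append((a, b, w, True))
    out = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "is_tie_edge"])
    return out.sort_values(["weight", "node_a", "node_b"]).reset_index(drop=True)


def cut_clusters(
    edges: pd.DataFrame,
    classes: HaplotypeClasses,
    ds: HaplotypeDataset | None = None,
    max_break: int = 3,
    focal_variants: list[tuple[str, int]] | None = None,
    min_display_freq: float = 0.01,
) -> ClusterTable:
    """Cut MST edges with weight > ``max_break``; connected components of the
    remaining tree become clusters.

    When a dataset is supplied the table carries per-population and
    per-species counts/frequencies, the allele state at designated focal
    variants, and a flag for clusters below the display frequency (default
    1% of the cohort).
    """
    k = len(classes.members)
    uf = _UnionFind(k)
    tree = edges[~edges["is_tie_edge"].astype(bool)] if len(edges) else edges
    for row in tree.itertuples(index=False):
        if row.weight <= max_break:
            uf.union(int(row.node_a), int(row.node_b))
    comp_of_class = np.array([uf.find(i) for i in range(k)])
    # relabel components by order of first appearance
    _, inv = np.unique(comp_of_class, return_inverse=True)
    first = {}
    relabel = {}
    nxt = 0
    for cls in range(k):
        c = comp_of_class[cls]
        if c not in relabel:
            relabel[c] = nxt
            nxt += 1
    comp_of_class = np.array([relabel[c] for c in comp_of_class])

    n_haps = len(classes.class_of)
    membership = comp_of_class[classes.class_of]
    rows = []
    per_pop_rows = []
    for cid in range(nxt):
        cols = np.flatnonzero(membership == cid)
        row = {
            "cluster_id": cid,
            "size": len(cols),
            "n_classes": int((comp_of_class == cid).sum()),
            "cohort_freq": len(cols) / n_haps,
            "below_display_freq": (len(cols) / n_haps) < min_display_freq,
        }
        if ds is not None and focal_variants:
            for chrom, pos in focal_variants:
                vi = ds.variant_index(chrom, pos)
                row[f"allele_{chrom}:{pos}"] = float(ds.matrix[vi, cols].mean())
        if ds is not None and ds.sample_table is not None:
            pops = ds.hap_population
            for pop in pd.unique(pops):
                pop_cols = np.flatnonzero(pops == pop)
                n_in = int(np.isin(pop_cols, cols).sum())
                per_pop_rows.append(
                    {
                        "cluster_id": cid,
                        "population": pop,
                        "count": n_in,
                        "frequency": n_in / len(pop_cols),
                    }
                )
        rows.append(row)
    per_pop = pd.DataFrame(per_pop_rows) if per_pop_rows else None
    return ClusterTable(
        clusters=pd.DataFrame(rows), membership=membership, per_population=per_pop
    )


def haplotype_network(
    ds: HaplotypeDataset,
    region: str | None = None,
    max_break: int = 3,
    focal_variants: list[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, ClusterTable]:
    """Convenience: distances -> classes -> MSN -> clusters in one call."""
    sub = ds.region(region) if region else ds
    classes = collapse_classes(sub.matrix)
    dist = np.zeros((len(classes.members),) * 2, dtype=int)
    reps = classes.representatives
    diff = reps[:, :, None] != reps[:, None, :]
    dist = diff.sum(axis=0)
    edges = minimum_spanning_network(dist)
    table = cut_clusters(
        edges, classes, ds=sub, max_break=max_break, focal_variants=focal_variants
    )
    return edges, table
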