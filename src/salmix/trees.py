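"""Reporting-region evidence: neighbour-joining trees of the D_A matrix,
locus-bootstrap support with majority-rule consensus, and classical PCoA
ordination.

Reporting regions themselves are inputs (a :class:`~salmix.genotype_io.
HierarchyMap`): this module produces the evidence a curator reads to group
collections, it does not derive regions algorithmically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fstats import DistanceMatrix
from .freqs import AlleleFreqTable
from .genotype_io import BaselineRegistry
from .util import rng_for

__all__ = ["Tree", "Ordination", "BootstrapResult", "nj_tree", "bootstrap_support", "pcoa"]


@dataclass
class _Node:
    label: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if self.label is not None:
            return frozenset([self.label])
        out: set[str] = set()
        for ch, _ in self.children:
            out |= ch.leaves()
        return frozenset(out)

    def newick(self, supports: dict[frozenset[str], float] | None = None) -> str:
        if self.label is not None:
            return self.label
        parts = []
        for ch, ln in self.children:
            sup = ""
            if supports is not None and ch.label is None:
                s = supports.get(ch.leaves())
                if s is not None:
                    sup = f"{s:g}"
            parts.append(f"{ch.newick(supports)}{sup}:{ln:.10g}")
        return "(" + ",".join(parts) + ")"


@dataclass
class Tree:
    """An unrooted tree over collection labels.

    ``splits`` maps each internal edge's bipartition (canonicalised as the
    side *not* containing the reference first label) to its branch length;
    ``supports`` holds bootstrap percentages for those same bipartitions.
    Negative NJ branch lengths are clamped to zero and the clamped total is
    recorded in ``clamped_length``.
    """

    labels: list[str]
    root: _Node
    splits: dict[frozenset[str], float]
    clamped_length: float = 0.0
    supports: dict[frozenset[str], float] | None = None

    def newick(self, with_support: bool = False) -> str:
        return self.root.newick(self.supports if with_support else None) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        return set(self.splits)


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _canonical_split(side: frozenset[str], labels: list[str]) -> frozenset[str] | None:
    n = len(labels)
    if len(side) < 2 or len(side) > n - 2:
        return None
    if labels[0] in side:
        side = frozenset(labels) - side
    return side


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically smallest pair of node
    representative labels, so the topology is deterministic.  Negative
    branch lengths are clamped to zero (deficit recorded on the tree).
    """
    labels = list(D.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(label=lab) for lab in labels]
    reps: list[str] = list(labels)  # representative (min leaf) label per active node
    d = D.values.astype(float).copy()
    active = list(range(n))
    clamped = 0.0
    splits: dict[frozenset[str], float] = {}

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best_key is None or (q < best_key[0] - 1e-12) or (
                    abs(q - best_key[0]) <= 1e-12 and key[1] < best_key[1]
                ):
                    best_key = key
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li), clamp(lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        u = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    order = sorted(zip((a, b, c), (la, lb, lc)), key=lambda t: reps[t[0]])
    root = _Node(children=[(nodes[k], ln) for k, ln in order])

    def collect(node: _Node, length: float) -> None:
        if node.label is not None:
            return
        side = _canonical_split(node.leaves(), labels)
        if side is not None:
            splits[side] = length
        for ch, ln in node.children:
            collect(ch, ln)

    for ch, ln in root.children:
        collect(ch, ln)
    return Tree(labels=labels, root=root, splits=splits, clamped_length=clamped)


@dataclass
class BootstrapResult:
    tree: Tree  # full-data tree annotated with supports
    consensus_newick: str
    split_frequencies: dict[frozenset[str], float]
    n_reps: int


def _da_from_freqs(
    share: list[np.ndarray], typed: np.ndarray, locus_idx: np.ndarray, labels: list[str]
) -> DistanceMatrix:
    U = typed.shape[0]
    d = np.zeros((U, U))
    for u in range(U):
        for v in range(u + 1, U):
            shared = [j for j in locus_idx if typed[u, j] and typed[v, j]]
            val = 1.0 - np.mean([share[j][u, v] for j in shared])
            d[u, v] = d[v, u] = min(max(val, 0.0), 1.0)
    return DistanceMatrix(labels=labels, values=d)


def bootstrap_support(
    registry: BaselineRegistry, n_reps: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Locus-bootstrap support for the D_A neighbour-joining tree.

    Loci are resampled with replacement ``n_reps`` times; each replicate's
    D_A matrix and NJ tree is recomputed, support is the percentage of
    replicates containing each bipartition of the full-data tree, and a
    majority-rule (50%) consensus is also returned.
    """
    L = len(registry.loci)
    if L < 2:
        raise ValueError("locus bootstrap needs at least two loci")
    if len(registry.collections) < 4:
        raise ValueError("bootstrap supports need at least four collections")
    table = AlleleFreqTable.from_registry(registry)
    U = table.n_units
    share = []
    typed = np.zeros((U, L), dtype=bool)
    for j in range(L):
        f = table.ml_freqs(j)
        share.append(np.sqrt(f) @ np.sqrt(f).T)
        typed[:, j] = table.totals[j] > 0
    labels = list(table.units)
    full = nj_tree(_da_from_freqs(share, typed, np.arange(L), labels))

    rng = rng_for(seed, "locus-bootstrap")
    counts: dict[frozenset[str], int] = {}
    newicks = []
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = nj_tree(_da_from_freqs(share, typed, idx, labels))
        newicks.append(rep.newick())
        for s in rep.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    freqs = {s: 100.0 * c / n_reps for s, c in counts.items()}
    full.supports = {s: freqs.get(s, 0.0) for s in full.bipartitions()}

    import dendropy

    tns = dendropy.TaxonNamespace(labels)
    tl = dendropy.TreeList(taxon_namespace=tns)
    for nwk in newicks:
        tl.append(dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns))
    consensus = tl.consensus(min_freq=0.5)
    return BootstrapResult(
        tree=full,
        consensus_newick=consensus.as_string(schema="newick").strip(),
        split_frequencies=freqs,
        n_reps=n_reps,
    )


def pcoa(D: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical (metric) principal-coordinates analysis.

    Double-centres ``-D^2/2``, eigendecomposes, and keeps the top-k
    non-negative eigenpairs; coordinates are eigenvectors scaled by the
    square root of their eigenvalues.  Axis signs follow the convention
    that the first non-zero loading on each axis is positive.
    """
    n = len(D.labels)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    coords = np.zeros((n, k))
    for axis in range(k):
        if pos[axis] > 1e-12:
            v = vecs[:, axis] * np.sqrt(pos[axis])
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
            coords[:, axis] = v
    total = pos.sum()
    prop = pos[:k] / total if total > 0 else np.zeros(k)
    return Ordination(
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=vals[:k],
        proportion_explained=prop,
    )
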