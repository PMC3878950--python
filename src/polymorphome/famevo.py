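"""Gene-family clustering and Dollo-parsimony gain/loss reconstruction.

Families are built by Markov clustering (MCL) of an all-vs-all similarity
graph; each family's presence/absence profile across taxa is then placed on
a rooted species tree under Dollo parsimony: a family arises exactly once
(on the branch above the last common ancestor of all taxa carrying it) and
can only be lost thereafter, so the reconstruction minimizes losses among
single-gain scenarios.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_io import TranscriptRecord


def longest_isoform_filter(records: Sequence[TranscriptRecord]) -> list[TranscriptRecord]:
    """One transcript per component: the longest, ties by smallest id."""
    best: dict[str, TranscriptRecord] = {}
    for r in records:
        cur = best.get(r.component_id)
        if cur is None or (-r.length, r.id) < (-cur.length, cur.id):
            best[r.component_id] = r
    return [best[c] for c in sorted(best)]


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    edges: Mapping[tuple[str, str], float],
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering of a weighted undirected similarity graph.

    ``edges`` maps (node_a, node_b) to a positive weight (for directed hit
    tables use the max bitscore of either direction).  Self-loops are set to
    each node's maximum incident weight (standard regularization).  The
    column-stochastic matrix is alternately expanded (squared) and inflated
    (elementwise power ``inflation``, renormalized) until the largest entry
    change drops below ``tol``.  Clusters are attractor systems; a node
    attracted to several is assigned to its highest-probability attractor,
    ties lexicographic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted({n for pair in edges for n in pair})
    if not nodes:
        raise ValueError("empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in edges.items():
        if w <= 0:
            raise ValueError(f"non-positive edge weight for ({a}, {b})")
        i, j = index[a], index[b]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0  # isolated nodes
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M ** inflation
        M /= M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.abs(M - prev).max():.2e})"
        )

    eps = 1e-6
    attractors = [i for i in range(n) if M[i, i] > eps]
    assigned: dict[int, int] = {}
    for j in range(n):
        cands = [(M[i, j], -1, i) for i in attractors if M[i, j] > eps]
        if cands:
            best = max(cands, key=lambda t: (t[0], -t[2]))
            assigned[j] = best[2]
        else:  # numerically degenerate column: own singleton
            assigned[j] = j
    clusters: dict[int, set[str]] = defaultdict(set)
    for j, a in assigned.items():
        clusters[a].add(nodes[j])
    return sorted(clusters.values(), key=lambda c: sorted(c)[0])


def similarity_edges_from_hits(hits: Iterable, max_evalue: float = 1e-5) -> dict[tuple[str, str], float]:
    """Undirected edge weights (max bitscore of either direction) from an
    all-vs-all hit table at E <= ``max_evalue``."""
    edges: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        edges[key] = max(edges.get(key, 0.0), h.bitscore)
    return edges


# ---------------------------------------------------------------------------
# rooted tree and Dollo reconstruction


class RootedTree:
    """A rooted tree with named leaves; branches are identified by their
    child node id.  Internal nodes keep their Newick label when present and
    otherwise get deterministic preorder ids ``node0``, ``node1``, ...
    """

    def __init__(self, parent: dict[str, str | None], children: dict[str, list[str]], root: str):
        self.parent = parent
        self.children = children
        self.root = root
        self.leaves = sorted(n for n in parent if not children.get(n))
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf names")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        parent: dict[str, str | None] = {}
        children: dict[str, list[str]] = {}
        names: dict[int, str] = {}
        counter = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon else nd.label
                if name is None:
                    raise ValueError("unnamed leaf in tree")
            else:
                name = nd.label
                if name is None:
                    name = f"node{counter}"
                    counter += 1
            names[id(nd)] = name
        for nd in tree.preorder_node_iter():
            name = names[id(nd)]
            if nd.parent_node is None:
                parent[name] = None
                root = name
            else:
                parent[name] = names[id(nd.parent_node)]
            children[name] = [names[id(c)] for c in nd.child_nodes()]
        return cls(parent, children, root)

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def postorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(self.children.get(nd, ()))
        return out[::-1]

    def subtree_leaves(self, node: str) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            nd = stack.pop()
            kids = self.children.get(nd)
            if kids:
                stack.extend(kids)
            else:
                out.add(nd)
        return out

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def lca(self, nodes: Sequence[str]) -> str:
        common: set[str] | None = None
        order: list[str] = []
        for nd in nodes:
            path = self.path_to_root(nd)
            if common is None:
                common = set(path)
                order = path
            else:
                common &= set(path)
        assert common is not None
        for nd in order:  # order runs child -> root, so first common is deepest
            if nd in common:
                return nd
        raise RuntimeError("no common ancestor (disconnected tree?)")


@dataclass(frozen=True)
class DolloReconstruction:
    family_id: str
    gain_branch: str  # child-node id; the root id denotes the root edge
    loss_branches: frozenset[str]
    ancestral_presence: Mapping[str, bool]


def build_profiles(
    clusters: Sequence[set[str]], sequence_to_taxon: Mapping[str, str]
) -> pd.DataFrame:
    """Family-by-taxon presence/absence matrix from sequence clusters."""
    taxa = sorted(set(sequence_to_taxon.values()))
    rows = []
    for i, cluster in enumerate(clusters):
        present = set()
        for seq in cluster:
            if seq not in sequence_to_taxon:
                raise ValueError(f"sequence {seq!r} has no taxon mapping")
            present.add(sequence_to_taxon[seq])
        rows.append([t in present for t in taxa])
    return pd.DataFrame(rows, index=[f"fam{i}" for i in range(len(clusters))], columns=taxa)


def dollo_reconstruct(
    tree: RootedTree, presence: Mapping[str, bool], family_id: str = "fam"
) -> DolloReconstruction:
    """Minimum-loss single-gain reconstruction of one family.

    The gain branch is the edge above the LCA of all presence leaves (the
    root edge when that LCA is the root); losses are the maximal branches
    inside the gain clade whose entire leaf set lacks the family.
    """
    present_leaves = [lf for lf in tree.leaves if presence.get(lf, False)]
    if not present_leaves:
        raise ValueError(f"family {family_id}: all-absent profile")
    extra = set(presence) - set(tree.leaves)
    if extra:
        raise ValueError(f"profile taxa not in tree: {sorted(extra)}")
    gain = tree.lca(present_leaves)

    # bottom-up: a node is "empty" if no leaf below it carries the family
    empty: dict[str, bool] = {}
    for nd in tree.postorder():
        kids = tree.children.get(nd)
        if not kids:
            empty[nd] = not presence.get(nd, False)
        else:
            empty[nd] = all(empty[k] for k in kids)

    losses: set[str] = set()
    ancestral: dict[str, bool] = {}

    def walk(nd: str, alive: bool) -> None:
        if alive and empty[nd]:
            losses.add(nd)
            alive = False
        ancestral[nd] = alive
        for k in tree.children.get(nd, ()):
            walk(k, alive)

    # nodes outside the gain clade are absent
    for nd in tree.parent:
        ancestral[nd] = False
    walk(gain, True)
    return DolloReconstruction(
        family_id=family_id,
        gain_branch=gain,
        loss_branches=frozenset(losses),
        ancestral_presence=ancestral,
    )


def reconstruct_all(tree: RootedTree, profiles: pd.DataFrame) -> list[DolloReconstruction]:
    return [
        dollo_reconstruct(tree, row.to_dict(), family_id=str(fam))
        for fam, row in profiles.iterrows()
    ]


def branch_event_summary(
    reconstructions: Sequence[DolloReconstruction], tree: RootedTree
) -> pd.DataFrame:
    """Per-branch gain/loss tallies and per-node family counts.

    The conservation identity count(child) = count(parent) + gains(child) -
    losses(child) holds by construction of the Dollo reconstruction.
    """
    if not reconstructions:
        raise ValueError("no reconstructions")
    gains = defaultdict(int)
    losses = defaultdict(int)
    node_counts = defaultdict(int)
    for rec in reconstructions:
        gains[rec.gain_branch] += 1
        for b in rec.loss_branches:
            losses[b] += 1
        for nd, present in rec.ancestral_presence.items():
            if present:
                node_counts[nd] += 1
    rows = [
        (
            nd,
            tree.parent[nd] if tree.parent[nd] is not None else "",
            gains[nd],
            losses[nd],
            node_counts[nd],
        )
        for nd in sorted(tree.parent)
    ]
    return pd.DataFrame(
        rows, columns=["branch", "parent", "n_gains", "n_losses", "n_families"]
    )
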