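"""MEGAN-style lowest-common-ancestor (LCA) taxonomic binning of contigs.

Queries are placed on the lowest taxonomy node ancestral to all of their
retained homology hits; low-scoring hits, hits far below the best bitscore
(the "top percent" window) and low-complexity queries are excluded first,
and sparsely supported taxa are promoted toward the root ("min support").
The resulting assignments split the assembly into host ("spider") contigs —
Metazoa minus explicitly excluded clades such as Nematoda — and the
meta-transcriptome of parasites, commensals and contaminants.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import HitRecord

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class TaxonomyNode:
    taxon_id: str
    parent_id: str  # the root points to itself
    rank: str
    name: str


@dataclass(frozen=True)
class LcaParams:
    """Filter thresholds of the LCA binner (defaults mirror common practice
    for contaminant screening of de novo assemblies)."""

    min_support: int = 5
    min_score: float = 35.0
    top_percent: float = 10.0
    min_complexity: float = 0.3

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        if not 0 <= self.min_complexity <= 1:
            raise ValueError("min_complexity must be in [0, 1]")


@dataclass(frozen=True)
class TaxAssignment:
    query_id: str
    taxon_id: str  # a taxon id or UNASSIGNED
    n_hits_used: int


class Taxonomy:
    """A rooted taxonomy with parent links and name lookup."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
        roots = [n.taxon_id for n in self.nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        self._by_name: dict[str, str] = {}
        for n in self.nodes.values():
            self._by_name.setdefault(n.name, n.taxon_id)
        # validate: every parent chain reaches the root without cycles
        for tid in self.nodes:
            self.path_to_root(tid)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def parent(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].parent_id

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` up to and including the root."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        path = [taxon_id]
        seen = {taxon_id}
        while path[-1] != self.root:
            nxt = self.nodes[path[-1]].parent_id
            if nxt in seen:
                raise ValueError(f"cycle in taxonomy at {nxt!r}")
            if nxt not in self.nodes:
                raise ValueError(f"parent {nxt!r} of {path[-1]!r} missing")
            seen.add(nxt)
            path.append(nxt)
        return path

    def depth(self, taxon_id: str) -> int:
        return len(self.path_to_root(taxon_id)) - 1

    def is_ancestor_or_equal(self, ancestor: str, node: str) -> bool:
        return ancestor in self.path_to_root(node)

    def lca(self, taxon_ids: Sequence[str]) -> str:
        if not taxon_ids:
            raise ValueError("lca of empty set")
        common = None
        for tid in taxon_ids:
            path = set(self.path_to_root(tid))
            common = path if common is None else common & path
        # deepest member of the common ancestor set
        return max(common, key=self.depth)

    def resolve_name(self, name: str) -> str:
        if name in self.nodes:
            return name
        if name in self._by_name:
            return self._by_name[name]
        raise KeyError(f"clade {name!r} not found in taxonomy")


def sequence_complexity(sequence: str) -> float:
    """Normalized Shannon entropy of mononucleotide composition, in [0, 1].

    Entropy over {A,C,G,T} divided by log 4; N bases are ignored.  An empty
    effective sequence scores 0.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = [seq.count(b) for b in "ACGT"]
    total = sum(counts)
    if total == 0:
        return 0.0
    h = -sum((c / total) * math.log(c / total) for c in counts if c > 0)
    return h / math.log(4)


def assign_lca(
    query_hits: Sequence[HitRecord],
    taxonomy: Taxonomy,
    params: LcaParams = LcaParams(),
    query_sequence: str | None = None,
) -> TaxAssignment:
    """Support-unaware LCA assignment of one query from its hits.

    Low-complexity queries are unassigned outright; hits below ``min_score``
    or below ``(1 - top_percent/100)`` of the best bitscore are dropped; the
    assignment is the LCA of the surviving hit taxa.
    """
    if not query_hits:
        raise ValueError("assign_lca requires at least one hit")
    qids = {h.query_id for h in query_hits}
    if len(qids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")
    query_id = next(iter(qids))
    if query_sequence is not None:
        if sequence_complexity(query_sequence) < params.min_complexity:
            return TaxAssignment(query_id, UNASSIGNED, 0)
    for h in query_hits:
        if h.subject_taxon is None or h.subject_taxon not in taxonomy:
            raise ValueError(f"hit taxon {h.subject_taxon!r} absent from taxonomy")
    kept = [h for h in query_hits if h.bitscore >= params.min_score]
    if kept:
        best = max(h.bitscore for h in kept)
        floor = (1 - params.top_percent / 100.0) * best
        kept = [h for h in kept if h.bitscore >= floor]
    if not kept:
        return TaxAssignment(query_id, UNASSIGNED, 0)
    taxon = taxonomy.lca([h.subject_taxon for h in kept])
    return TaxAssignment(query_id, taxon, len(kept))


def apply_min_support(
    assignments: Sequence[TaxAssignment],
    taxonomy: Taxonomy,
    min_support: int = 5,
) -> list[TaxAssignment]:
    """Promote sparsely supported assignments toward the root.

    Processing nodes from the deepest upward, any taxon whose subtree holds
    fewer than ``min_support`` assigned queries has its queries moved to its
    parent; queries that reach the root while the whole tree lacks support
    become UNASSIGNED.  The bottom-up order makes the result independent of
    input ordering.
    """
    at_node: dict[str, list[TaxAssignment]] = defaultdict(list)
    passthrough: list[TaxAssignment] = []
    for a in assignments:
        if a.taxon_id == UNASSIGNED:
            passthrough.append(a)
        else:
            if a.taxon_id not in taxonomy:
                raise ValueError(f"assignment to unknown taxon {a.taxon_id!r}")
            at_node[a.taxon_id].append(a)

    subtree: dict[str, int] = defaultdict(int)
    for tid, items in at_node.items():
        for anc in taxonomy.path_to_root(tid):
            subtree[anc] += len(items)

    order = sorted(taxonomy.nodes, key=taxonomy.depth, reverse=True)
    for tid in order:
        if tid == taxonomy.root:
            continue
        if at_node.get(tid) and subtree[tid] < min_support:
            at_node[taxonomy.parent(tid)].extend(at_node.pop(tid))

    out: list[TaxAssignment] = list(passthrough)
    for tid, items in at_node.items():
        target = tid
        if tid == taxonomy.root and subtree[taxonomy.root] < min_support:
            target = UNASSIGNED
        for a in items:
            out.append(TaxAssignment(a.query_id, target, a.n_hits_used))
    out.sort(key=lambda a: a.query_id)
    return out


def split_spider_meta(
    assignments: Sequence[TaxAssignment],
    taxonomy: Taxonomy,
    keep_clade: str = "Metazoa",
    exclude_clades: Iterable[str] = ("Nematoda",),
) -> tuple[list[str], list[str], list[str]]:
    """Partition queries into host ("spider"), meta-transcriptome, unassigned.

    Host contigs are those assigned within ``keep_clade`` but not within any
    excluded clade (by default Nematoda, since these spiders are commonly
    parasitized by nematodes); every other assigned query belongs to the
    meta-transcriptome.
    """
    keep_id = taxonomy.resolve_name(keep_clade)
    exclude_ids = [taxonomy.resolve_name(c) for c in exclude_clades]
    spider: list[str] = []
    meta: list[str] = []
    unassigned: list[str] = []
    for a in assignments:
        if a.taxon_id == UNASSIGNED:
            unassigned.append(a.query_id)
            continue
        path = taxonomy.path_to_root(a.taxon_id)
        if keep_id in path and not any(e in path for e in exclude_ids):
            spider.append(a.query_id)
        else:
            meta.append(a.query_id)
    return sorted(spider), sorted(meta), sorted(unassigned)
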