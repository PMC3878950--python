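"""Best-hit logic: reciprocal best hits, assembly-fragmentation statistics
and annotation keyword searches.

A reciprocal best hit (RBH) — two sequences in different sets that are each
other's top-scoring hit — is the operational orthology criterion used to
confirm pigment-pathway and housekeeping gene homologues.  The unique-best-hit
fraction (how many contigs' best reference protein is claimed by no other
contig) indexes how fragmented an assembly is.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import HitRecord


@dataclass(frozen=True)
class RbhPair:
    a_id: str
    b_id: str
    ab_bitscore: float
    ba_bitscore: float


def best_hit(hits: Iterable[HitRecord], query_id: str) -> HitRecord | None:
    """The best hit of a query: max bitscore, then min E-value, then
    lexicographically smallest subject id.  None when the query has no hits."""
    candidates = [h for h in hits if h.query_id == query_id]
    if not candidates:
        return None
    return min(candidates, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def _best_by_query(hits: Iterable[HitRecord], max_evalue: float) -> dict[str, HitRecord]:
    grouped: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = grouped.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            grouped[h.query_id] = h
    return grouped


def reciprocal_best_hits(
    table_ab: Iterable[HitRecord],
    table_ba: Iterable[HitRecord],
    max_evalue: float = 1e-5,
) -> list[RbhPair]:
    """Pairs (a, b) such that b is a's best hit in A->B and a is b's best hit
    in B->A, both at E <= ``max_evalue``.  Each id occurs in at most one pair."""
    best_ab = _best_by_query(table_ab, max_evalue)
    best_ba = _best_by_query(table_ba, max_evalue)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == a:
            pairs.append(
                RbhPair(
                    a_id=a,
                    b_id=hit.subject_id,
                    ab_bitscore=hit.bitscore,
                    ba_bitscore=back.bitscore,
                )
            )
    return pairs


def unique_best_hit_fraction(
    hits: Iterable[HitRecord],
    contig_lengths: Mapping[str, int],
    min_len: int = 200,
) -> tuple[int, int, float]:
    """Fraction of hit-bearing contigs whose best-hit protein is shared with
    no other retained contig.

    Restricted to queries of length >= ``min_len`` with at least one hit;
    returns (n_unique, n_with_hits, fraction).  A rising fraction as short
    contigs are excluded indicates the short tail is rich in gene fragments.
    """
    hits = list(hits)
    queries = {h.query_id for h in hits}
    missing = [q for q in queries if q not in contig_lengths]
    if missing:
        raise ValueError(f"no length for queries: {sorted(missing)[:5]}")
    kept = {q for q in queries if contig_lengths[q] >= min_len}
    best = _best_by_query((h for h in hits if h.query_id in kept), max_evalue=float("inf"))
    subject_counts: dict[str, int] = defaultdict(int)
    for h in best.values():
        subject_counts[h.subject_id] += 1
    n_with_hits = len(best)
    n_unique = sum(1 for h in best.values() if subject_counts[h.subject_id] == 1)
    fraction = n_unique / n_with_hits if n_with_hits else 0.0
    return n_unique, n_with_hits, fraction


def keyword_search(
    annotations: Mapping[str, str], keywords: Sequence[str]
) -> dict[str, list[str]]:
    """Case-insensitive substring search of keywords in description texts.

    Returns {id: [matched keywords]} for ids with at least one match.
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    lowered = [(k, k.lower()) for k in keywords]
    out: dict[str, list[str]] = {}
    for qid, desc in annotations.items():
        d = desc.lower()
        matched = [k for k, kl in lowered if kl in d]
        if matched:
            out[qid] = matched
    return out


RBH = "RBH"
ONE_WAY = "ONE_WAY"
NOT_DETECTED = "NOT_DETECTED"


def rbh_panel_report(
    rbh_pairs: Sequence[RbhPair],
    one_way_hits: Iterable[HitRecord],
    panel: pd.DataFrame,
    searched_queries: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene detection status for a candidate-gene panel.

    ``panel`` needs columns symbol, pathway, query_id (the reference protein
    searched with).  Status is RBH when the query participates in a
    reciprocal best hit, ONE_WAY when it has only a forward hit, and
    NOT_DETECTED otherwise — mirroring the three support levels used for
    pigment-pathway gene tables.  When ``searched_queries`` is given, a panel
    protein that was never part of the search is an error rather than a
    NOT_DETECTED.
    """
    for col in ("symbol", "pathway", "query_id"):
        if col not in panel.columns:
            raise ValueError(f"panel is missing column {col!r}")
    if searched_queries is not None:
        unsearched = set(panel["query_id"]) - searched_queries
        if unsearched:
            raise ValueError(f"panel proteins not in query set: {sorted(unsearched)}")
    rbh_queries = {p.a_id for p in rbh_pairs} | {p.b_id for p in rbh_pairs}
    forward = {h.query_id for h in one_way_hits}
    rows = []
    for r in panel.itertuples(index=False):
        if r.query_id in rbh_queries:
            status = RBH
        elif r.query_id in forward:
            status = ONE_WAY
        else:
            status = NOT_DETECTED
        rows.append((r.symbol, r.pathway, r.query_id, status))
    return pd.DataFrame(rows, columns=["symbol", "pathway", "query_id", "status"])
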