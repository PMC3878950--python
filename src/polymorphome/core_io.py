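"""Readers, writers and assembly statistics for the pipeline's external formats.

All on-disk formats are plain text: FASTA for contigs, 12/13-column
tab-separated hit tables (BLAST ``outfmt 6`` column order, with an optional
trailing subject-taxon column), a two-file taxonomy (nodes + names), Newick
trees, TSV count matrices and JSON configuration.  Hit-table coordinates are
1-based inclusive as in BLAST tabular output; internal sequence coordinates
throughout the package are 0-based half-open.
"""

from __future__ import annotations

import json
import logging
import math
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("polymorphome")

#: BLAST tabular (outfmt 6) column order; a 13th "staxid" column is optional.
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

#: Default pattern mapping a contig id to its component ("gene") id by
#: stripping a trailing Trinity-style isoform suffix (``_seqN`` or ``_iN``).
DEFAULT_COMPONENT_PATTERN = r"^(?P<component>.+?)_(?:seq|i)\d+$"


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled contig with its component ("gene") identity."""

    id: str
    sequence: str
    component_id: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One homology-alignment row of a tabular hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    subject_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_id}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length < 1 for {self.query_id}")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_len: float
    median_len: float
    n50: int
    max_len: int
    min_len: int
    gc_percent: float
    total_bp: int


def parse_component_id(contig_id: str, pattern: str = DEFAULT_COMPONENT_PATTERN) -> str:
    """Extract the component id from a contig id; the id itself if no match."""
    m = re.match(pattern, contig_id)
    if m:
        return m.group("component")
    return contig_id


def read_fasta(
    path: str | Path,
    component_pattern: str = DEFAULT_COMPONENT_PATTERN,
) -> list[TranscriptRecord]:
    """Read transcript contigs from FASTA.

    Sequences are upper-cased and U (RNA) is mapped to T.  Duplicate ids and
    empty sequences raise ``ValueError``.  Input order is preserved.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {rec.id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        records.append(
            TranscriptRecord(
                id=rec.id,
                sequence=seq,
                component_id=parse_component_id(rec.id, component_pattern),
            )
        )
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_hit_table(
    path: str | Path,
    max_evalue: float = 1e-3,
    max_hits_per_query: int = 20,
) -> pd.DataFrame:
    """Read a 12/13-column tabular hit file, filter and truncate.

    Rows with E-value above ``max_evalue`` are dropped; per query the rows are
    sorted by descending bitscore and truncated to ``max_hits_per_query``
    (default 20, the acceptance rule used for the homology searches).
    Returns a DataFrame with outfmt-6 column names plus ``staxid`` when the
    13th column is present.
    """
    if max_hits_per_query < 1:
        raise ValueError("max_hits_per_query must be >= 1")
    rows: list[list[str]] = []
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated columns, got {len(parts)}"
                )
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            rows.append(parts)
    columns = list(OUTFMT6_COLUMNS) + (["staxid"] if n_cols == 13 else [])
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        return pd.DataFrame(columns=columns)
    for col in ("pident", "evalue", "bitscore"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df = df[df["evalue"] <= max_evalue]
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    df = df.groupby("qseqid", sort=False).head(max_hits_per_query).reset_index(drop=True)
    logger.info("read_hit_table: %d rows kept from %s", len(df), path)
    return df


def hit_records(df: pd.DataFrame) -> list[HitRecord]:
    """Convert a hit-table DataFrame to ``HitRecord`` objects."""
    has_tax = "staxid" in df.columns
    return [
        HitRecord(
            query_id=r.qseqid,
            subject_id=r.sseqid,
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            subject_taxon=str(r.staxid) if has_tax else None,
        )
        for r in df.itertuples(index=False)
    ]


def assembly_stats(records: Sequence[TranscriptRecord], min_len: int = 200) -> AssemblyStats:
    """Summary statistics (N50, mean/median, %GC) over contigs ``>= min_len``.

    The N50 is the length L, drawn from the observed length multiset, such
    that contigs of length >= L contain at least half of all assembled bases
    (largest-first cumulative scan).  %GC counts G+C over A+C+G+T; N bases
    count toward length but are excluded from the GC denominator.
    """
    kept = [r for r in records if r.length >= min_len]
    if not kept:
        raise ValueError(f"no contigs of length >= {min_len}")
    lengths = sorted((r.length for r in kept), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    n = len(lengths)
    mid = n // 2
    median = float(lengths[mid]) if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0
    gc = at = 0
    for r in kept:
        gc += r.sequence.count("G") + r.sequence.count("C")
        at += r.sequence.count("A") + r.sequence.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0
    return AssemblyStats(
        n_contigs=n,
        mean_len=total / n,
        median_len=median,
        n50=n50,
        max_len=lengths[0],
        min_len=lengths[-1],
        gc_percent=gc_percent,
        total_bp=total,
    )


def coding_size_range(
    blast_positive_ids: Iterable[str],
    markov_positive_ids: Iterable[str],
    records: Sequence[TranscriptRecord],
) -> tuple[float, float]:
    """(min, max) total size in Mbp over two coding-set definitions.

    The two id sets are alternative definitions of the coding transcriptome
    (homology-positive vs Markov-model-positive); the range brackets the
    coding transcriptome size.
    """
    by_id = {r.id: r.length for r in records}
    sizes = []
    for ids in (set(blast_positive_ids), set(markov_positive_ids)):
        missing = ids - by_id.keys()
        if missing:
            raise ValueError(f"ids not in records: {sorted(missing)[:5]}")
        sizes.append(sum(by_id[i] for i in ids) / 1e6)
    return (min(sizes), max(sizes))


# ---------------------------------------------------------------------------
# taxonomy / tree / counts / config plumbing


def read_taxonomy(nodes_path: str | Path, names_path: str | Path):
    """Read a taxonomy from nodes (id, parent_id, rank) and names (id, name) TSVs.

    Returns a :class:`polymorphome.taxflow.Taxonomy`.
    """
    from .taxflow import Taxonomy, TaxonomyNode

    names: dict[str, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{names_path}:{lineno}: expected 2 columns")
            names[parts[0]] = parts[1]
    nodes: list[TaxonomyNode] = []
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{nodes_path}:{lineno}: expected 3 columns")
            tid, parent, rank = parts
            nodes.append(
                TaxonomyNode(
                    taxon_id=tid, parent_id=parent, rank=rank, name=names.get(tid, tid)
                )
            )
    return Taxonomy(nodes)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; leaf labels must be unique."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate leaf labels in {path}")
    return tree


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix TSV (gene_id column + sample columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] < 1:
        raise ValueError(f"{path}: count matrix needs >= 1 sample column")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative counts in sample {col!r}")
        if not (vals == vals.round()).all():
            raise ValueError(f"{path}: non-integer counts in sample {col!r}")
        df[col] = vals.astype(int)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level JSON value must be an object")
    return cfg


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
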