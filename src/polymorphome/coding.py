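"""Six-frame ORF finding and hexamer-Markov coding-potential classification.

The classifier follows the geneid-style construction: the longest ORFs found
across the whole dataset parameterize a 5th-order (hexamer) nucleotide Markov
chain; the same ORFs, shuffled per sequence to preserve mononucleotide
composition, parameterize a null chain.  Each transcript's best ORF is then
scored by the log-likelihood ratio of the two chains and called coding or
non-coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """A maximal open reading frame in forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand and span
    the start codon through the terminating stop codon inclusive, so
    ``aa_len = (end - start) / 3 - 1``.
    """

    transcript_id: str
    strand: str  # "+" or "-"
    frame: int  # 0, 1, 2 on the reading strand
    start: int
    end: int

    @property
    def nt_len(self) -> int:
        return self.end - self.start

    @property
    def aa_len(self) -> int:
        return self.nt_len // 3 - 1


@dataclass(frozen=True)
class OrfCall:
    orf: Orf
    llr: float
    is_coding: bool


def orf_sequence(orf: Orf, transcript_seq: str) -> str:
    """ORF nucleotides read 5'->3' on the ORF's own strand."""
    span = transcript_seq[orf.start : orf.end]
    return span if orf.strand == "+" else reverse_complement(span)


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """Maximal ATG..stop ORFs in one frame of ``seq`` (reading-strand coords).

    Codons containing N are never treated as start or stop codons but do not
    break the frame.
    """
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    for pos in range(offset, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            if start is not None:
                orfs.append((start, pos + 3))
                start = None
        elif start is None and codon == START_CODON:
            start = pos
    return orfs


def find_orfs(record: TranscriptRecord, min_aa: int = 100, allow_partial: bool = False) -> list[Orf]:
    """Every maximal ORF of at least ``min_aa`` amino acids in all six frames.

    An ORF runs from the first ATG following a stop (or the frame start) to
    the next in-frame stop.  With ``allow_partial`` a trailing stopless ORF at
    the 3' edge of a frame is also reported (its span then holds no stop and
    ``aa_len = nt_len/3``).  Results are in forward-strand coordinates,
    ordered by (start, end, strand).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.sequence
    n = len(seq)
    out: list[Orf] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            spans = _scan_frame(s, frame)
            if allow_partial:
                spans += _trailing_partial(s, frame)
            for a, b in spans:
                has_stop = s[b - 3 : b] in STOP_CODONS
                aa = (b - a) // 3 - (1 if has_stop else 0)
                if aa < min_aa:
                    continue
                if strand == "+":
                    start, end = a, b
                else:
                    start, end = n - b, n - a
                out.append(Orf(record.id, strand, frame, start, end))
    out.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return out


def _trailing_partial(seq: str, offset: int) -> list[tuple[int, int]]:
    last_stop_end = offset
    start: int | None = None
    pos = offset
    for pos in range(offset, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            last_stop_end = pos + 3
            start = None
        elif start is None and codon == START_CODON:
            start = pos
    if start is not None and start >= last_stop_end:
        end = start + ((len(seq) - start) // 3) * 3
        if end > start:
            return [(start, end)]
    return []


class HexamerModel:
    """5th-order nucleotide Markov chain over {A,C,G,T}.

    Stores log conditional probabilities of the 6th base given each 5-mer
    context, estimated from 6-mer counts with an additive pseudocount.
    Contexts never observed in training fall back to the uniform 0.25.
    """

    ORDER = 5

    def __init__(self, log_cond: dict[str, np.ndarray], pseudocount: float):
        self.log_cond = log_cond
        self.pseudocount = pseudocount
        self._uniform = np.full(4, math.log(0.25))

    def log_p(self, context: str, base: str) -> float:
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(f"non-ACGT base {base!r}")
        return float(self.log_cond.get(context, self._uniform)[idx])

    def context_probabilities(self, context: str) -> np.ndarray:
        return np.exp(self.log_cond.get(context, self._uniform))


def train_hexamer_model(sequences: Iterable[str], pseudocount: float = 1.0) -> HexamerModel:
    """Estimate hexamer conditionals from nucleotide sequences.

    P(base | context) = (count(context+base) + pseudocount) /
    (count(context, any) + 4 * pseudocount); windows containing N are skipped.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    seqs = list(sequences)
    if not seqs:
        raise ValueError("training set is empty")
    counts: dict[str, np.ndarray] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(HexamerModel.ORDER, len(seq)):
            window = seq[i - HexamerModel.ORDER : i + 1]
            if "N" in window:
                continue
            ctx, base = window[:-1], window[-1]
            arr = counts.get(ctx)
            if arr is None:
                arr = counts[ctx] = np.zeros(4)
            arr[_BASE_INDEX[base]] += 1
    log_cond = {
        ctx: np.log((arr + pseudocount) / (arr.sum() + 4 * pseudocount))
        for ctx, arr in counts.items()
    }
    return HexamerModel(log_cond, pseudocount)


def build_null_model(
    sequences: Iterable[str], seed: int, pseudocount: float = 1.0
) -> HexamerModel:
    """Null chain trained on per-sequence mononucleotide shuffles.

    Each training sequence is independently permuted (seeded Fisher-Yates via
    the numpy generator), destroying hexamer structure while preserving base
    composition; the shuffles then train an ordinary hexamer chain.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for seq in sequences:
        chars = np.array(list(seq))
        shuffled.append("".join(rng.permutation(chars)))
    return train_hexamer_model(shuffled, pseudocount)


def score_llr(model: HexamerModel, null: HexamerModel, sequence: str) -> float:
    """Log-likelihood ratio (coding vs null) of a nucleotide sequence.

    Sum over positions with a full 5-mer context of
    log P_model(base|context) - log P_null(base|context); windows containing
    N are skipped.
    """
    sequence = sequence.upper()
    if len(sequence) < 6:
        raise ValueError("sequence shorter than 6 nt cannot be scored")
    total = 0.0
    for i in range(HexamerModel.ORDER, len(sequence)):
        window = sequence[i - HexamerModel.ORDER : i + 1]
        if "N" in window:
            continue
        ctx, base = window[:-1], window[-1]
        total += model.log_p(ctx, base) - null.log_p(ctx, base)
    return total


def classify_transcripts(
    records: Sequence[TranscriptRecord],
    n_train: int = 500,
    min_aa: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
    allow_partial: bool = False,
) -> list[OrfCall]:
    """Classify each transcript's best ORF as coding or non-coding.

    The ``n_train`` longest ORFs dataset-wide (ties broken by transcript id,
    then coordinate) train the coding chain; their shuffles train the null.
    Per transcript the candidate is the ORF maximizing the LLR of its oriented
    sequence (ties: longer ORF, then lexicographic coordinates).  The call is
    coding when the LLR is positive and the reading orientation outscores the
    reverse-complement reading of the same span.  Transcripts containing no
    ORF of at least ``min_aa`` amino acids yield no call.
    """
    by_transcript: dict[str, list[Orf]] = {}
    all_orfs: list[Orf] = []
    for rec in records:
        orfs = find_orfs(rec, min_aa=min_aa, allow_partial=allow_partial)
        if orfs:
            by_transcript[rec.id] = orfs
            all_orfs.extend(orfs)
    if not all_orfs:
        raise ValueError(
            f"no ORFs >= {min_aa} aa found in {len(records)} records; cannot train"
        )
    seq_by_id = {rec.id: rec.sequence for rec in records}
    ranked = sorted(
        all_orfs, key=lambda o: (-o.nt_len, o.transcript_id, o.start, o.end, o.strand)
    )
    train_seqs = [orf_sequence(o, seq_by_id[o.transcript_id]) for o in ranked[:n_train]]
    model = train_hexamer_model(train_seqs, pseudocount)
    null = build_null_model(train_seqs, seed=seed, pseudocount=pseudocount)

    calls: list[OrfCall] = []
    for rec in records:
        orfs = by_transcript.get(rec.id)
        if not orfs:
            continue
        scored = []
        for o in orfs:
            fwd = orf_sequence(o, rec.sequence)
            scored.append((score_llr(model, null, fwd), o, fwd))
        scored.sort(key=lambda t: (-t[0], -t[1].nt_len, t[1].start, t[1].end, t[1].strand))
        llr, best, fwd = scored[0]
        rev_llr = score_llr(model, null, reverse_complement(fwd))
        calls.append(OrfCall(orf=best, llr=llr, is_coding=bool(llr > 0 and llr > rev_llr)))
    return calls
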