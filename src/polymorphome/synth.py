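"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the shape of the study's data — de novo contigs with
composition-biased coding regions, homology hit tables with planted ortholog
pairs and contaminant taxa, negative-binomial count matrices with a stable
housekeeping set and a differentially expressed pigment panel, and gene
families evolving by single gain and repeated loss on a known species tree —
without any sequencing reads.  Every generator is deterministic under a
fixed seed; each draws from its own derived substream so adding one
generator never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import HitRecord, TranscriptRecord
from .coding import STOP_CODONS, reverse_complement
from .famevo import RootedTree
from .taxflow import TaxonomyNode

_BASES = np.array(list("ACGT"))

# substream tags so each generator owns an independent RNG
_STREAMS = {"transcripts": 1, "hits": 2, "counts": 3, "families": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults for all generators.

    The coding/non-coding set sizes, ORF lengths and the minimum-ORF
    convention (100 aa) mirror the annotation stage; the count matrix has
    four samples (two species x Yellow/Colored), a zero-fold-change
    housekeeping set of 196 genes and a 40-gene pigment panel, matching the
    sizes the differential-expression procedure is anchored on.
    """

    seed: int = 0
    n_coding: int = 200
    n_noncoding: int = 200
    coding_bias: float = 1.0
    orf_len_range: tuple[int, int] = (120, 300)  # amino acids
    flank_len_range: tuple[int, int] = (50, 200)  # nucleotides
    min_orf_aa: int = 100  # classifier minimum the planted ORFs must exceed
    n_orthologs: int = 30
    n_decoys: int = 10
    n_fragment_groups: int = 5
    fragment_group_size: int = 3
    contaminant_fraction: float = 0.2
    nb_dispersion: float = 0.2
    hk_n: int = 196
    pigment_n: int = 40
    n_background: int = 200
    pigment_log2fc_range: tuple[float, float] = (1.0, 4.0)
    mean_count: float = 500.0
    tree_leaves: int = 8
    n_families: int = 300
    family_loss_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_noncoding", "hk_n", "pigment_n", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        if not 0 <= self.family_loss_prob <= 1:
            raise ValueError("family_loss_prob must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion (phi) must be >= 0")
        if self.coding_bias < 0:
            raise ValueError("coding_bias must be >= 0")


# ---------------------------------------------------------------------------
# transcripts with hexamer-biased coding regions


class _HexamerSource:
    """5th-order Markov nucleotide source.

    The coding source perturbs each 5-mer context's conditional distribution
    away from uniform by a Dirichlet draw, with the perturbation scaled by
    ``bias`` — at bias 0 the source is exactly uniform, matching the
    non-coding source in distribution.
    """

    def __init__(self, bias: float, rng: np.random.Generator):
        self.bias = bias
        # one conditional per 5-mer context, enumerated in base-4 order
        raw = rng.dirichlet(np.ones(4), size=4 ** 5)
        uniform = np.full((4 ** 5, 4), 0.25)
        w = min(1.0, bias)
        self.cond = (1 - w) * uniform + w * raw
        # extra sharpening for bias > 1: exponentiate and renormalize
        if bias > 1:
            self.cond = self.cond ** bias
            self.cond /= self.cond.sum(axis=1, keepdims=True)
        self._cdf = np.cumsum(self.cond, axis=1)

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``length`` base indices from the chain (uniform start)."""
        out = np.empty(length, dtype=np.int64)
        u = rng.random(length)
        ctx = 0
        warm = min(length, 5)
        start = rng.integers(0, 4, size=warm)
        out[:warm] = start
        for i in range(warm):
            ctx = (ctx * 4 + int(out[i])) % (4 ** 5)
        for i in range(warm, length):
            b = min(int(np.searchsorted(self._cdf[ctx], u[i], side="right")), 3)
            out[i] = b
            ctx = (ctx * 4 + b) % (4 ** 5)
        return out


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(_BASES[idx])


def _sample_orf(source: _HexamerSource, aa_len: int, rng: np.random.Generator) -> str:
    """An ATG...stop ORF of ``aa_len`` amino acids drawn from the source.

    In-frame stop codons are resampled so the reading frame stays open; a
    terminal stop codon is appended.
    """
    body_codons = aa_len - 1  # codons after ATG, before the stop
    chars = ["ATG"]
    n_nt = body_codons * 3
    raw = _indices_to_seq(source.sample(n_nt + 30, rng))
    pos = 0
    made = 0
    while made < body_codons:
        if pos + 3 > len(raw):
            raw += _indices_to_seq(source.sample(n_nt, rng))
        codon = raw[pos : pos + 3]
        pos += 3
        if codon in STOP_CODONS:
            continue
        chars.append(codon)
        made += 1
    stop = str(rng.choice(sorted(STOP_CODONS)))
    chars.append(stop)
    return "".join(chars)


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    is_coding: bool
    orf_start: int | None = None  # forward-strand, 0-based half-open
    orf_end: int | None = None


def simulate_transcripts(
    config: SynthConfig,
) -> tuple[list[TranscriptRecord], list[TranscriptTruth]]:
    """Coding records with one embedded ORF in non-coding flanks, plus
    non-coding records from the unbiased source."""
    lo, hi = config.orf_len_range
    if lo <= config.min_orf_aa:
        raise ValueError(
            f"orf_len_range minimum {lo} must exceed the classifier minimum "
            f"({config.min_orf_aa} aa)"
        )
    rng = _rng(config.seed, "transcripts")
    coding_source = _HexamerSource(config.coding_bias, rng)
    records: list[TranscriptRecord] = []
    truths: list[TranscriptTruth] = []
    flo, fhi = config.flank_len_range
    for i in range(config.n_coding):
        aa = int(rng.integers(lo, hi + 1))
        orf = _sample_orf(coding_source, aa, rng)
        left = _indices_to_seq(rng.integers(0, 4, size=int(rng.integers(flo, fhi + 1))))
        right = _indices_to_seq(rng.integers(0, 4, size=int(rng.integers(flo, fhi + 1))))
        seq = left + orf + right
        tid = f"syncod{i}_i1"
        records.append(TranscriptRecord(id=tid, sequence=seq, component_id=f"syncod{i}"))
        truths.append(
            TranscriptTruth(tid, True, orf_start=len(left), orf_end=len(left) + len(orf))
        )
    # length-match the non-coding records to the coding length distribution
    for i in range(config.n_noncoding):
        aa = int(rng.integers(lo, hi + 1))
        length = aa * 3 + int(rng.integers(flo, fhi + 1)) + int(rng.integers(flo, fhi + 1))
        seq = _indices_to_seq(rng.integers(0, 4, size=length))
        tid = f"synnc{i}_i1"
        records.append(TranscriptRecord(id=tid, sequence=seq, component_id=f"synnc{i}"))
        truths.append(TranscriptTruth(tid, False))
    return records, truths


# ---------------------------------------------------------------------------
# hit tables with planted orthologs, decoys, contaminants and fragments


@dataclass(frozen=True)
class HitTruth:
    rbh_pairs: frozenset[tuple[str, str]]
    contaminant_queries: frozenset[str]
    fragment_groups: tuple[tuple[str, ...], ...]
    decoy_queries: frozenset[str]


def toy_taxonomy() -> list[TaxonomyNode]:
    """A small taxonomy with Metazoa (incl. Araneae and Nematoda), bacteria
    and fungi — enough structure for LCA binning and the host/meta split."""
    edges = [
        ("root", "root", "no rank", "root"),
        ("131567", "root", "no rank", "cellular organisms"),
        ("2759", "131567", "superkingdom", "Eukaryota"),
        ("2", "131567", "superkingdom", "Bacteria"),
        ("33208", "2759", "kingdom", "Metazoa"),
        ("4751", "2759", "kingdom", "Fungi"),
        ("6231", "33208", "phylum", "Nematoda"),
        ("6656", "33208", "phylum", "Arthropoda"),
        ("6854", "6656", "class", "Arachnida"),
        ("6893", "6854", "order", "Araneae"),
        ("50587", "6893", "species", "Theridion grallator"),
        ("1112257", "6893", "species", "Theridion californicum"),
        ("6945", "6854", "species", "Ixodes scapularis"),
        ("7227", "6656", "species", "Drosophila melanogaster"),
        ("6279", "6231", "species", "Brugia malayi"),
        ("1423", "2", "species", "Bacillus subtilis"),
        ("562", "2", "species", "Escherichia coli"),
        ("4932", "4751", "species", "Saccharomyces cerevisiae"),
    ]
    return [TaxonomyNode(*e) for e in edges]


def simulate_hits(
    config: SynthConfig,
) -> tuple[list[HitRecord], list[HitRecord], list[TaxonomyNode], HitTruth]:
    """Hit tables A->B and B->A with known structure.

    Plants ``n_orthologs`` mutual-best pairs, ``n_decoys`` one-way hits,
    contaminant-taxon queries at ``contaminant_fraction`` of the spider-taxon
    query count, and fragment groups of contigs sharing one best subject (so
    none of them is a unique best hit).  Fragment-group contigs get short
    lengths so the fragmentation statistic rises when they are excluded.
    """
    rng = _rng(config.seed, "hits")
    ab: list[HitRecord] = []
    ba: list[HitRecord] = []
    spider_taxon = "50587"
    contaminant_taxa = ["1423", "562", "4932", "6279"]
    rbh = set()
    for i in range(config.n_orthologs):
        a, b = f"contigA{i}_i1", f"protB{i}"
        top = float(rng.uniform(200, 400))
        ab.append(HitRecord(a, b, 90.0, 150, 1e-50, top, spider_taxon))
        ba.append(HitRecord(b, a, 90.0, 150, 1e-50, top))
        # weaker cross hits to a neighboring subject keep best-hit logic honest
        if i + 1 < config.n_orthologs:
            ab.append(
                HitRecord(a, f"protB{i + 1}", 60.0, 100, 1e-10, top * 0.5, spider_taxon)
            )
        rbh.add((a, b))
    decoys = set()
    for i in range(config.n_decoys):
        q = f"decoyA{i}_i1"
        # one-way: decoy hits an ortholog's subject, but that subject's best
        # hit remains its planted partner
        ab.append(
            HitRecord(q, f"protB{i % max(1, config.n_orthologs)}", 55.0, 80, 1e-8,
                      60.0, spider_taxon)
        )
        decoys.add(q)
    frag_groups = []
    for g in range(config.n_fragment_groups):
        group = []
        subject = f"fragProt{g}"
        for m in range(config.fragment_group_size):
            q = f"fragA{g}_{m}_i1"
            ab.append(HitRecord(q, subject, 70.0, 40, 1e-6, 50.0, spider_taxon))
            group.append(q)
        frag_groups.append(tuple(group))
    n_spider = len({h.query_id for h in ab})
    n_contam = int(round(config.contaminant_fraction * n_spider))
    contaminants = set()
    for i in range(n_contam):
        q = f"contamA{i}_i1"
        taxon = contaminant_taxa[int(rng.integers(0, len(contaminant_taxa)))]
        ab.append(HitRecord(q, f"envProt{i}", 95.0, 120, 1e-30, 250.0, taxon))
        contaminants.add(q)
    truth = HitTruth(
        rbh_pairs=frozenset(rbh),
        contaminant_queries=frozenset(contaminants),
        fragment_groups=tuple(frag_groups),
        decoy_queries=frozenset(decoys),
    )
    return ab, ba, toy_taxonomy(), truth


def synthetic_contig_lengths(config: SynthConfig) -> dict[str, int]:
    """Lengths for the queries of :func:`simulate_hits`: fragment-group
    contigs are short (100-199 bp), everything else >= 300 bp."""
    lengths: dict[str, int] = {}
    for i in range(config.n_orthologs):
        lengths[f"contigA{i}_i1"] = 300 + 10 * i
    for i in range(config.n_decoys):
        lengths[f"decoyA{i}_i1"] = 400 + 10 * i
    for g in range(config.n_fragment_groups):
        for m in range(config.fragment_group_size):
            lengths[f"fragA{g}_{m}_i1"] = 100 + 10 * m
    n_spider = len(lengths)
    n_contam = int(round(config.contaminant_fraction * n_spider))
    for i in range(n_contam):
        lengths[f"contamA{i}_i1"] = 500
    return lengths


# ---------------------------------------------------------------------------
# NB count matrices


@dataclass(frozen=True)
class CountTruth:
    mu: Mapping[str, float]
    log2fc: Mapping[str, float]
    phi: float
    sample_factors: Mapping[str, float]
    hk_ids: tuple[str, ...]
    pigment_ids: tuple[str, ...]


SAMPLES = ("speciesA-Yellow", "speciesA-Colored", "speciesB-Yellow", "speciesB-Colored")
SAMPLE_CLASS = {
    "speciesA-Yellow": "Yellow",
    "speciesA-Colored": "Colored",
    "speciesB-Yellow": "Yellow",
    "speciesB-Colored": "Colored",
}
SAMPLE_SPECIES = {s: s.split("-")[0] for s in SAMPLES}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi*mu^2 (phi=0 reduces to Poisson)."""
    if phi == 0:
        return rng.poisson(mu)
    k = 1.0 / phi
    p = k / (k + mu)
    return rng.negative_binomial(k, p)


def simulate_counts(config: SynthConfig) -> tuple[pd.DataFrame, CountTruth]:
    """Four-sample count matrix: HK genes at zero fold change, pigment genes
    up-regulated in Colored samples, plus neutral background genes."""
    rng = _rng(config.seed, "counts")
    hk = [f"hk{i}" for i in range(config.hk_n)]
    pig = [f"pig{i}" for i in range(config.pigment_n)]
    bg = [f"bg{i}" for i in range(config.n_background)]
    genes = hk + pig + bg
    # log-normal spread of baseline means around mean_count
    mu = config.mean_count * rng.lognormal(0.0, 0.5, size=len(genes))
    lo, hi = config.pigment_log2fc_range
    lfc = {g: 0.0 for g in hk}
    for g in pig:
        lfc[g] = float(rng.uniform(lo, hi))
    for g in bg:
        lfc[g] = 0.0
    factors = {s: float(rng.uniform(0.8, 1.25)) for s in SAMPLES}
    data = {}
    for s in SAMPLES:
        fold = np.array(
            [2 ** lfc[g] if SAMPLE_CLASS[s] == "Colored" else 1.0 for g in genes]
        )
        data[s] = _nb_draw(rng, mu * fold * factors[s], config.nb_dispersion)
    counts = pd.DataFrame(data, index=genes)
    truth = CountTruth(
        mu=dict(zip(genes, mu)),
        log2fc=lfc,
        phi=config.nb_dispersion,
        sample_factors=factors,
        hk_ids=tuple(hk),
        pigment_ids=tuple(pig),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# gene-family presence/absence by single gain / repeated loss


@dataclass(frozen=True)
class FamilyTruth:
    gain_branch: Mapping[str, str]
    loss_branches: Mapping[str, tuple[str, ...]]


def default_species_tree(n_leaves: int = 8) -> RootedTree:
    """A ladder-shaped rooted tree with leaves t1..tn."""
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    newick = f"t{n_leaves}"
    for i in range(n_leaves - 1, 0, -1):
        newick = f"(t{i},{newick})"
    return RootedTree.from_newick(newick + ";")


def simulate_family_profiles(
    tree: RootedTree,
    n_families: int,
    family_loss_prob: float,
    seed: int,
) -> tuple[pd.DataFrame, FamilyTruth]:
    """Presence/absence profiles from a single-gain, multiple-loss process.

    Each family gains on one uniformly chosen branch (the root id denotes
    the root edge); below the gain every branch whose parent still carries
    the family loses it independently with ``family_loss_prob``, the whole
    clade under a loss going absent.  Loss patterns erasing the family from
    every leaf are redrawn so each profile retains at least one presence.
    """
    if not 0 <= family_loss_prob <= 1:
        raise ValueError("family_loss_prob must be in [0, 1]")
    rng = _rng(seed, "families")
    branches = sorted(tree.parent)  # every node id, incl. root = root edge
    gain_of: dict[str, str] = {}
    losses_of: dict[str, tuple[str, ...]] = {}
    rows = []
    for i in range(n_families):
        fam = f"fam{i}"
        gain = branches[int(rng.integers(0, len(branches)))]
        while True:
            losses: list[str] = []
            present_leaves: set[str] = set()

            def walk(nd: str, alive: bool) -> None:
                if alive and nd != gain and rng.random() < family_loss_prob:
                    losses.append(nd)
                    alive = False
                if alive and not tree.children.get(nd):
                    present_leaves.add(nd)
                for k in tree.children.get(nd, ()):
                    walk(k, alive)

            walk(gain, True)
            if present_leaves:
                break
        gain_of[fam] = gain
        losses_of[fam] = tuple(sorted(losses))
        rows.append([lf in present_leaves for lf in tree.leaves])
    profiles = pd.DataFrame(
        rows, index=[f"fam{i}" for i in range(n_families)], columns=tree.leaves
    )
    return profiles, FamilyTruth(gain_branch=gain_of, loss_branches=losses_of)


def truth_to_json(truth, path) -> None:
    """Serialize any generator truth object to JSON."""

    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=default)
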