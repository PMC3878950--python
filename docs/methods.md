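# Methods

This note documents the models and procedures implemented in
`polymorphome`, the choices made where the published analysis chain leaves
details open, and what the synthetic study conditions do and do not
establish about real data.

## Coding-potential classification

**Model.** "Hexamer-based" scoring is implemented as a 5th-order Markov
chain over {A,C,G,T}: 6-mer counts give the conditional probability of the
sixth base on its 5-mer context, with an additive pseudocount (default 1.0)
and a uniform 0.25 fallback for unseen contexts. The coding chain is
trained on the `n_train = 500` longest ORFs found dataset-wide in all six
frames (ties broken by transcript id then coordinate); the null chain is
trained on the same ORFs after an independent seeded per-sequence
permutation, which preserves mononucleotide composition while destroying
hexamer structure. A candidate ORF's log-likelihood ratio is the sum of
per-position log-probability differences over all positions with a full
ACGT 5-mer context (windows containing N are skipped).

**ORF conventions.** An ORF runs from the first ATG after a stop (or frame
start) to the next in-frame stop, inclusive, so `aa_len = nt_len/3 − 1`;
the default minimum is 100 aa. Complete ORFs (with a terminating stop) are
the default; a flag admits trailing stopless ORFs at the 3′ edge. Codons
containing N are never starts or stops and do not break the frame.
Coordinates are reported 0-based half-open on the forward strand.

**Decision rule.** Per transcript the candidate is the ORF maximizing the
LLR of its oriented sequence (ties: longer ORF, then coordinates). The
call is coding when the LLR is positive *and* the oriented reading
outscores the reverse complement of the same span. A non-phased hexamer
chain assigns one likelihood per strand — same-strand frame shifts change
the scored stream only by one or two edge terms — so the six-frame
comparison collapses, correctly, to this two-strand comparison; comparing
raw frame-shifted scores strictly would reduce to coin flips on edge noise.

**What the classifier can and cannot show.** On the synthetic defaults the
planted composition bias is strong and accuracy is ≈ 1.0; this verifies
the machinery, not performance on real assemblies, where coding bias is
weaker and ORFs fragmentary. Note that even with *zero* planted
composition bias the classifier detects planted coding records at a high
rate: real ORFs are in-frame-stop-free, and stop-codon depletion is itself
hexamer signal. The bias-null check is therefore framed as loss of
*discrimination*: at zero bias, coding-call rates for planted-coding
versus ORF-bearing non-coding records are statistically indistinguishable.

## LCA-based meta-transcriptome filtering

Queries are binned MEGAN-style from tabular hits: (1) queries whose
normalized mononucleotide entropy (Shannon entropy / log 4, N ignored)
falls below `min_complexity = 0.3` are unassigned; (2) hits with bitscore
below `min_score = 35.0` or below `(1 − top_percent/100)` of the query's
best bitscore are dropped (`top_percent = 10.0`); (3) the assignment is
the LCA of the surviving hit taxa; (4) taxa whose subtree holds fewer than
`min_support = 5` assigned queries promote their queries to the parent,
processed bottom-up (deterministic, order-independent); queries without
support anywhere become unassigned. Host contigs are those assigned within
Metazoa but not within Nematoda (these spiders are commonly parasitized by
mermithid nematodes); all other assigned contigs form the
meta-transcriptome. MEGAN's exact internal complexity measure is
undocumented; normalized entropy preserves the threshold's semantics
(filter low-complexity queries before assignment). Bitscore, not E-value,
defines the top-percent window, matching MEGAN convention. `min_support`
must be scaled to the data: the default 5 suits study-scale tables, while
the toy synthetic tables (tens of queries) are analyzed at `min_support
= 1` — at 5, the handful of nematode hits would correctly promote up into
Metazoa, which a dedicated test demonstrates rather than hides.

## Orthology and fragmentation statistics

Best hits maximize bitscore with deterministic tie-breaking (min E-value,
then lexicographic subject id; the source analyses do not specify ties).
An RBH pair requires mutual best hits at `E ≤ 1e-5` in both directions.
The unique-best-hit fraction restricts to queries of length ≥ `min_len`
with ≥ 1 hit and counts queries whose best-hit subject no other retained
query shares — the protein-sharing reading: a reference protein claimed by
several contigs marks probable fragments of one gene. Keyword search is
case-insensitive substring matching against description text.

## Housekeeping-anchored differential expression

The design pools individuals per morph (Yellow vs Colored) in two species
with no biological replicates, so per-gene variance is inestimable. All
inference is anchored on housekeeping (HK) genes — candidates kept only if
their hits fall in exactly one component ("gene") per species, occur in
both species, and are RBH-verified.

* **Normalization**: per-sample factors proportional to HK read totals,
  rescaled to geometric mean 1; dividing counts by the factors equalizes
  HK totals across samples. HK-total scaling (not TMM) is used because the
  HK set *is* the normalization reference in this design; the choice is
  isolated behind `hk_normalization_factors` and swappable.
* **Dispersion**: a single NB dispersion φ (Var = μ + φμ²) maximizes the
  conditional log-likelihood of the factor-equalized, rounded HK counts
  given their within-class totals — the conditional is beta-binomial-like
  and free of the per-gene means — by bounded golden-section search on
  φ ∈ [1e-6, 10]. The two species act as replicates within each color
  class. Exact numeric agreement with any edgeR version is a non-goal
  (edgeR quantile-adjusts libraries rather than rounding); recovery
  simulations (φ = 0.2, 200 genes, μ = 500, 4 samples) land in [0.1, 0.3]
  in ≥ 90% of seeds.
* **Exact test**: counts are rescaled to the geometric-mean effective size
  and rounded; conditional on the total t, P(a | t) under independent
  equal-mean NB margins is beta-binomial (mean-free; φ → 0 gives
  Binomial(t, ½)), and the two-sided p-value sums all splits with
  conditional probability ≤ the observed one (with a 1e-12 relative tie
  tolerance). This definition is deterministic and checkable against full
  enumeration.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels), applied within
  the tested panel.
* **Fold changes and the band**: log₂((mean normalized Colored + 0.5) /
  (mean normalized Yellow + 0.5)); the 0.5 prior keeps zero-count genes
  finite and symmetric (its handling is not specified in the source
  analyses). The HK band is the sample mean ± 2 sample SD (n−1
  denominator) of HK log₂ fold-changes. Band classes partition the line on
  the edges {lo, mean, hi}: DOWN_BEYOND_BAND < lo ≤ DOWN < mean = WITHIN
  < UP ≤ hi < UP_BEYOND_BAND; "meaningful" regulation is the two
  beyond-band classes.

## Gene-family evolution

Families come from Markov clustering of the all-vs-all similarity graph:
edge weight = max bitscore of either direction at `E ≤ 1e-5`, self-loops
set to each node's maximum incident weight (standard regularization),
column-stochastic matrix iterating expansion (squaring) and inflation
(elementwise power 2.0, renormalize) to a 1e-8 residual; clusters are
attractor systems, with overlapping attractors resolved to the
highest-probability one (ties lexicographic). Only the inflation factor is
fixed by the source analysis; other choices are stated here. Isoforms are
reduced to one transcript per component (longest; ties by id) before
clustering.

Dollo parsimony allows one gain and unlimited losses per family: the gain
branch is the edge above the LCA of all presence taxa (root edge if that
LCA is the root); losses are the maximal branches inside the gain clade
whose whole leaf set lacks the family. This is the unique minimum-loss
single-gain scenario (verified against exhaustive search on small trees).
Branch summaries obey count(child) = count(parent) + gains − losses by
construction. Tree inference and ultrametricization are out of scope; the
rooted tree is an input.

## Synthetic study conditions

Defaults mirror the anchored analysis sizes: 200 coding + 200 non-coding
transcripts with planted ORFs of 120–300 aa (classifier minimum 100 aa)
inside 50–200 nt flanks; 30 planted ortholog pairs, 10 one-way decoys, 5
fragment groups of 3 short (100–199 bp) contigs, contaminants at 20% of
spider queries; a 4-sample count matrix (2 species × Yellow/Colored) with
196 HK genes at zero fold change, a 40-gene pigment panel with log₂
fold-changes uniform in (1, 4) on the Colored pools, 200 neutral
background genes, baseline means log-normal around 500 and φ = 0.2; 300
families on an 8-leaf ladder tree with loss probability 0.2. Coding bias
is a Dirichlet perturbation of each 5-mer context's conditional
distribution, scaled so bias 0 is exactly uniform. One integer seed
drives independent per-generator substreams, so adding a generator never
perturbs another; fixed seed ⇒ byte-identical outputs.

Deliberate simplifications: no read-level error or coverage structure, no
isoform-level expression, flanks are uniform-random rather than UTR-like,
hit bitscores are planted rather than alignment-derived, and family loss
is branch-independent. Passing tests therefore validate algorithmic
correctness and parameter recovery under the stated model — not
performance on real assemblies, whose signal is weaker and structured.

## Numerical conventions

Hit-table coordinates are 1-based inclusive (BLAST outfmt 6); internal
sequence coordinates 0-based half-open. %GC excludes N from the
denominator but counts it in lengths. N50 is taken from the observed
length multiset by largest-first cumulative scan. All orderings that could
be ambiguous (training-set ties, best-hit ties, cluster output, table
sorts) are made deterministic, and outputs are sorted for diffability.
Problem sizes in tests (500-sequence ORF oracles, totals ≤ 200 for exact
test enumeration, ≤ 8-leaf trees for Dollo search, 20-seed dispersion
recovery) keep the full suite around ten seconds on one CPU.
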