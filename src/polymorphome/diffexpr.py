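"""Housekeeping-gene-anchored differential expression between color morphs.

The study design pools individuals per morph (Yellow vs Colored) without
biological replicates, so ordinary per-gene variance estimation is
impossible.  The procedure anchors everything on a curated set of
housekeeping (HK) genes assumed equally expressed across morphs:

* per-sample normalization factors equalize the HK read totals;
* a single negative-binomial dispersion phi (variance = mu + phi*mu^2) is
  estimated from the HK genes by conditional maximum likelihood, treating
  the two species as replicates of each color class;
* each candidate gene is tested with an exact conditional NB test;
* p-values are Benjamini-Hochberg adjusted;
* fold-changes are interpreted against the band mean +/- 2 SD of the HK
  log2 fold-changes, the empirical "no change" envelope of the design.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .homology import RbhPair

YELLOW = "Yellow"
COLORED = "Colored"

UP_BEYOND_BAND = "UP_BEYOND_BAND"
UP = "UP"
WITHIN = "WITHIN"
DOWN = "DOWN"
DOWN_BEYOND_BAND = "DOWN_BEYOND_BAND"


@dataclass(frozen=True)
class HkSet:
    """RBH-verified housekeeping genes, one component per species."""

    components_a: tuple[str, ...]
    components_b: tuple[str, ...]
    candidates: tuple[str, ...]  # reference protein ids that passed


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    n_genes_used: int


@dataclass(frozen=True)
class BandModel:
    """The +/- 2 SD envelope of HK log2 fold-changes."""

    hk_mean: float
    hk_sd: float

    @property
    def lo(self) -> float:
        return self.hk_mean - 2 * self.hk_sd

    @property
    def hi(self) -> float:
        return self.hk_mean + 2 * self.hk_sd

    def classify(self, log2fc: float) -> str:
        if log2fc > self.hi:
            return UP_BEYOND_BAND
        if log2fc < self.lo:
            return DOWN_BEYOND_BAND
        if log2fc > self.hk_mean:
            return UP
        if log2fc < self.hk_mean:
            return DOWN
        return WITHIN


def select_hk_genes(
    hits_a: Iterable,
    hits_b: Iterable,
    rbh_pairs_a: Sequence[RbhPair],
    rbh_pairs_b: Sequence[RbhPair],
    component_of_a: Mapping[str, str],
    component_of_b: Mapping[str, str],
) -> HkSet:
    """Select valid housekeeping genes from candidate-protein hit tables.

    A candidate reference protein is kept when its hits fall in exactly one
    component in each species and the hit components are RBH-verified against
    the candidate (the candidate participates in a reciprocal best hit whose
    transcript belongs to that component).
    """
    comps_a = defaultdict(set)
    for h in hits_a:
        comps_a[h.query_id].add(component_of_a[h.subject_id])
    comps_b = defaultdict(set)
    for h in hits_b:
        comps_b[h.query_id].add(component_of_b[h.subject_id])

    rbh_comp_a = {
        (p.a_id, component_of_a[p.b_id]) for p in rbh_pairs_a if p.b_id in component_of_a
    }
    rbh_comp_b = {
        (p.a_id, component_of_b[p.b_id]) for p in rbh_pairs_b if p.b_id in component_of_b
    }

    kept_cand, kept_a, kept_b = [], [], []
    for cand in sorted(set(comps_a) & set(comps_b)):
        if len(comps_a[cand]) != 1 or len(comps_b[cand]) != 1:
            continue
        (ca,) = comps_a[cand]
        (cb,) = comps_b[cand]
        if (cand, ca) in rbh_comp_a and (cand, cb) in rbh_comp_b:
            kept_cand.append(cand)
            kept_a.append(ca)
            kept_b.append(cb)
    return HkSet(tuple(kept_a), tuple(kept_b), tuple(kept_cand))


def hk_normalization_factors(counts: pd.DataFrame, hk_ids: Sequence[str]) -> pd.Series:
    """Per-sample scaling factors proportional to HK read totals.

    Factors are rescaled to geometric mean 1; dividing a sample's counts by
    its factor equalizes HK totals across samples.
    """
    hk_ids = list(hk_ids)
    if not hk_ids:
        raise ValueError("hk_ids is empty")
    missing = set(hk_ids) - set(counts.index)
    if missing:
        raise ValueError(f"HK genes absent from count matrix: {sorted(missing)[:5]}")
    totals = counts.loc[hk_ids].sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero HK total in samples {bad}")
    log_factors = np.log(totals) - np.log(totals).mean()
    return pd.Series(np.exp(log_factors), index=counts.columns, name="factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts.div(factors, axis=1)


def _nb_conditional_loglik(phi: float, counts: np.ndarray) -> float:
    """Sum over genes of log P(counts_row | row total) for iid NB(mu, phi)
    replicates within a row; the conditional is beta-binomial-like and free
    of mu."""
    k = 1.0 / phi
    r = counts.shape[1]
    t = counts.sum(axis=1)
    ll = (
        gammaln(counts + k).sum(axis=1)
        - gammaln(counts + 1).sum(axis=1)
        - r * gammaln(k)
        - gammaln(t + r * k)
        + gammaln(t + 1)
        + gammaln(r * k)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    counts: pd.DataFrame,
    hk_ids: Sequence[str],
    factors: pd.Series,
    sample_class: Mapping[str, str],
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood on HK genes.

    Within each color class the (factor-equalized, rounded) HK counts are
    treated as iid NB replicates; the conditional likelihood of the counts
    given their class totals is independent of the per-gene means and is
    maximized over phi by bounded 1-D search.
    """
    classes = defaultdict(list)
    for s in counts.columns:
        if s not in sample_class:
            raise ValueError(f"sample {s!r} has no class")
        classes[sample_class[s]].append(s)
    usable = {c: ss for c, ss in classes.items() if len(ss) >= 2}
    if not usable:
        raise ValueError("need >= 2 samples in at least one class")
    pseudo = normalized_counts(counts.loc[list(hk_ids)], factors).round()
    blocks = [pseudo[ss].to_numpy(dtype=float) for ss in usable.values()]

    def neg_ll(phi: float) -> float:
        return -sum(_nb_conditional_loglik(phi, b) for b in blocks)

    res = minimize_scalar(neg_ll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    return DispersionEstimate(phi=float(res.x), n_genes_used=len(hk_ids))


def _nb_conditional_logpmf(t: int, phi: float) -> np.ndarray:
    """log P(a | y1 + y2 = t), a = 0..t, for iid NB(mu, phi) margins.

    Free of mu; the phi -> 0 limit is Binomial(t, 1/2).
    """
    a = np.arange(t + 1)
    if phi <= 0:
        logp = gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1) + t * math.log(0.5)
        return logp
    k = 1.0 / phi
    logp = (
        gammaln(a + k)
        - gammaln(a + 1)
        + gammaln(t - a + k)
        - gammaln(t - a + 1)
        - 2 * gammaln(k)
        + gammaln(t + 1)
        + gammaln(2 * k)
        - gammaln(t + 2 * k)
    )
    return logp - logsumexp(logp)


def exact_nb_test(y1: float, y2: float, n1: float, n2: float, phi: float) -> float:
    """Two-sided exact NB test of equal relative abundance in two pools.

    Counts are rescaled to a common effective size (geometric mean of n1, n2)
    and rounded; conditional on the rescaled total t the p-value is the sum
    of conditional probabilities P(a | t) not exceeding that of the observed
    split, under independent equal-mean NB margins with dispersion phi.
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("effective sizes must be positive")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    n_common = math.sqrt(n1 * n2)
    a_obs = int(round(y1 * n_common / n1))
    b_obs = int(round(y2 * n_common / n2))
    t = a_obs + b_obs
    if t == 0:
        return 1.0
    logp = _nb_conditional_logpmf(t, phi)
    obs = logp[a_obs]
    mask = logp <= obs + 1e-12
    return float(min(1.0, math.exp(logsumexp(logp[mask]))))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(
    y_colored: Sequence[float],
    y_yellow: Sequence[float],
    factors_colored: Sequence[float],
    factors_yellow: Sequence[float],
    prior_count: float = 0.5,
) -> float:
    """log2((mean normalized Colored + prior) / (mean normalized Yellow + prior)).

    Colored is the numerator; the prior keeps zero-count genes finite and
    symmetric (all-zero input gives 0).
    """
    num = np.mean(np.asarray(y_colored, dtype=float) / np.asarray(factors_colored, dtype=float))
    den = np.mean(np.asarray(y_yellow, dtype=float) / np.asarray(factors_yellow, dtype=float))
    return math.log2((num + prior_count) / (den + prior_count))


def hk_band(hk_log2fcs: Sequence[float]) -> BandModel:
    """Mean +/- 2 sample SD (n-1 denominator) of HK log2 fold-changes."""
    vals = np.asarray(hk_log2fcs, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 HK fold-changes")
    return BandModel(hk_mean=float(vals.mean()), hk_sd=float(vals.std(ddof=1)))


def mean_abs_mapped_read_difference(
    counts: pd.DataFrame, gene_ids: Sequence[str],
    yellow_samples: Sequence[str], colored_samples: Sequence[str],
) -> float:
    """Mean over genes of |proportion mapped in Yellow - proportion in Colored|.

    Proportions are of each pool's total mapped reads; the ratio of this
    quantity between a candidate panel and the HK set measures how much more
    the panel moves between morphs than the stable background does.
    """
    totals = counts.sum(axis=0).astype(float)
    sub = counts.loc[list(gene_ids)]
    py = sub[list(yellow_samples)].div(totals[list(yellow_samples)], axis=1).mean(axis=1)
    pc = sub[list(colored_samples)].div(totals[list(colored_samples)], axis=1).mean(axis=1)
    return float((py - pc).abs().mean())


def pigment_panel_de(
    counts: pd.DataFrame,
    panel_ids: Sequence[str],
    hk_ids: Sequence[str],
    sample_class: Mapping[str, str],
    prior_count: float = 0.5,
) -> tuple[pd.DataFrame, BandModel, dict[str, int]]:
    """The full HK-anchored DE chain for a candidate-gene panel.

    Normalization factors and the common dispersion come from the HK genes;
    each panel gene gets an exact NB test on its class-summed pseudo-counts,
    BH adjustment within the panel, and a band class against the +/-2 SD HK
    envelope.  Samples of the two species within a color class act as
    replicates.  Returns (table sorted by decreasing log2fc, band model,
    band-class counts).
    """
    missing = (set(panel_ids) | set(hk_ids)) - set(counts.index)
    if missing:
        raise ValueError(f"genes absent from count matrix: {sorted(missing)[:5]}")
    yellow = [s for s in counts.columns if sample_class[s] == YELLOW]
    colored = [s for s in counts.columns if sample_class[s] == COLORED]
    if not yellow or not colored:
        raise ValueError("need samples of both classes")
    factors = hk_normalization_factors(counts, hk_ids)
    disp = estimate_common_dispersion(counts, hk_ids, factors, sample_class)
    pseudo = normalized_counts(counts, factors)

    def gene_log2fc(g: str) -> float:
        return log2_fold_change(
            counts.loc[g, colored], counts.loc[g, yellow],
            factors[colored], factors[yellow], prior_count,
        )

    band = hk_band([gene_log2fc(g) for g in hk_ids])

    rows = []
    for g in panel_ids:
        yc = float(pseudo.loc[g, colored].sum())
        yy = float(pseudo.loc[g, yellow].sum())
        p = exact_nb_test(yc, yy, len(colored), len(yellow), disp.phi)
        lfc = gene_log2fc(g)
        rows.append((g, lfc, p))
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    table["fdr"] = bh_fdr(table["pvalue"].to_numpy())
    table["band_class"] = [band.classify(x) for x in table["log2fc"]]
    table = table.sort_values(
        ["log2fc", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    band_counts = {
        c: int((table["band_class"] == c).sum())
        for c in (UP_BEYOND_BAND, UP, WITHIN, DOWN, DOWN_BEYOND_BAND)
    }
    return table, band, band_counts


def rank_expression(
    counts: pd.DataFrame, factors: pd.Series, top_n: int = 100
) -> pd.DataFrame:
    """Top genes by mean normalized count (ties broken by gene id)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mean_norm = normalized_counts(counts, factors).mean(axis=1)
    df = pd.DataFrame({"gene_id": counts.index, "mean_norm_count": mean_norm.to_numpy()})
    df = df.sort_values(
        ["mean_norm_count", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
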