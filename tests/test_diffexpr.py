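import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polymorphome import diffexpr, synth
from polymorphome.diffexpr import (
    BandModel,
    bh_fdr,
    estimate_common_dispersion,
    exact_nb_test,
    hk_band,
    hk_normalization_factors,
    log2_fold_change,
    pigment_panel_de,
    rank_expression,
)
from polymorphome.homology import RbhPair


def exact_test_oracle(y1: int, y2: int, phi: float) -> float:
    """Full conditional enumeration via scipy's NB pmf (equal library sizes).

    Independent route: conditional probabilities are built from marginal NB
    pmfs at an arbitrary mean and the convolved total, rather than from the
    beta-binomial closed form used by the implementation.
    """
    t = y1 + y2
    mu = 7.3  # arbitrary: the conditional distribution is mean-free
    a = np.arange(t + 1)
    if phi == 0:
        probs = stats.binom.pmf(a, t, 0.5)
    else:
        k = 1.0 / phi
        p = k / (k + mu)
        probs = stats.nbinom.pmf(a, k, p) * stats.nbinom.pmf(t - a, k, p)
        probs /= stats.nbinom.pmf(t, 2 * k, p)
    obs = probs[y1]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


class TestNormalizationFactors:
    def _counts(self, totals):
        return pd.DataFrame({f"s{i}": [t] for i, t in enumerate(totals)}, index=["hk1"])

    def test_equal_totals_give_unit_factors(self):
        f = hk_normalization_factors(self._counts([1000, 1000]), ["hk1"])
        assert np.allclose(f, 1.0)

    def test_closed_form_for_two_samples(self):
        f = hk_normalization_factors(self._counts([1000, 2000]), ["hk1"])
        assert f.iloc[0] == pytest.approx(1 / math.sqrt(2))
        assert f.iloc[1] == pytest.approx(math.sqrt(2))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(10, 1000, size=(50, 4)), columns=list("abcd"),
            index=[f"hk{i}" for i in range(50)],
        )
        f = hk_normalization_factors(counts, counts.index.tolist())
        assert np.prod(f) == pytest.approx(1.0, abs=1e-12)
        # dividing by the factors equalizes HK totals
        norm_totals = (counts / f).sum(axis=0)
        assert np.allclose(norm_totals, norm_totals.iloc[0], rtol=1e-9)

    def test_doubling_one_sample_doubles_its_relative_factor(self):
        base = self._counts([1000, 1000])
        doubled = self._counts([2000, 1000])
        f0 = hk_normalization_factors(base, ["hk1"])
        f1 = hk_normalization_factors(doubled, ["hk1"])
        assert (f1.iloc[0] / f1.iloc[1]) == pytest.approx(2 * f0.iloc[0] / f0.iloc[1])

    def test_zero_hk_total_is_error(self):
        with pytest.raises(ValueError):
            hk_normalization_factors(self._counts([0, 1000]), ["hk1"])


class TestExactNbTest:
    def test_equal_counts_give_p_one(self):
        assert exact_nb_test(17, 17, 1, 1, 0.2) == 1.0

    def test_binomial_closed_form_at_phi_zero(self):
        assert exact_nb_test(0, 10, 1, 1, 0.0) == pytest.approx(2 * 0.5**10)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(150):
            t = int(rng.integers(1, 201))
            y1 = int(rng.integers(0, t + 1))
            phi = float(rng.choice([0.0, 0.05, 0.2, 1.0]))
            got = exact_nb_test(y1, t - y1, 1, 1, phi)
            want = exact_test_oracle(y1, t - y1, phi)
            assert got == pytest.approx(want, abs=1e-12), (y1, t, phi)

    def test_symmetric_in_counts_for_equal_sizes(self):
        assert exact_nb_test(3, 30, 1, 1, 0.1) == exact_nb_test(30, 3, 1, 1, 0.1)

    def test_small_phi_approaches_binomial(self):
        p_small = exact_nb_test(5, 20, 1, 1, 1e-9)
        p_binom = exact_nb_test(5, 20, 1, 1, 0.0)
        assert p_small == pytest.approx(p_binom, abs=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(-1, 5, 1, 1, 0.1)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        assert log2_fold_change([10, 10], [10, 10], [1, 1], [1, 1]) == 0.0

    def test_four_fold_with_large_counts(self):
        lfc = log2_fold_change([4000, 4000], [1000, 1000], [1, 1], [1, 1])
        assert lfc == pytest.approx(2.0, abs=0.01)

    def test_zero_counts_give_zero(self):
        assert log2_fold_change([0], [0], [1], [1]) == 0.0


class TestHkBand:
    def test_degenerate_band(self):
        band = hk_band([0.0, 0.0, 0.0])
        assert (band.lo, band.hi) == (0.0, 0.0)

    def test_band_edges_to_fold_changes(self):
        # a band with mean 0.14 and sd 0.45 has edges (-0.76, 1.04); on the
        # linear scale those are fold-changes of about 0.6 and 2.1
        band = BandModel(hk_mean=0.14, hk_sd=0.45)
        assert band.hi == pytest.approx(1.04)
        assert 2**band.hi == pytest.approx(2.056, abs=0.001)
        assert 2**band.lo == pytest.approx(0.590, abs=0.001)

    def test_sd_uses_n_minus_one(self):
        band = hk_band([0.0, 1.0])
        assert band.hk_sd == pytest.approx(np.std([0, 1], ddof=1))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            hk_band([0.1])


class TestDispersionEstimation:
    def _simulate(self, phi, seed, n_genes=200, mu=500.0):
        rng = np.random.default_rng(seed)
        samples = ["aY", "aC", "bY", "bC"]
        means = mu * rng.lognormal(0, 0.3, size=n_genes)
        data = {}
        for s in samples:
            if phi == 0:
                data[s] = rng.poisson(means)
            else:
                k = 1 / phi
                data[s] = rng.negative_binomial(k, k / (k + means))
        counts = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
        classes = {"aY": "Yellow", "bY": "Yellow", "aC": "Colored", "bC": "Colored"}
        factors = hk_normalization_factors(counts, counts.index.tolist())
        return counts, factors, classes

    def test_poisson_counts_give_near_zero_phi(self):
        counts, factors, classes = self._simulate(0.0, seed=5)
        est = estimate_common_dispersion(counts, counts.index.tolist(), factors, classes)
        assert est.phi < 0.01

    def test_identical_counts_hit_lower_bound(self):
        counts = pd.DataFrame(
            {"aY": [100] * 20, "bY": [100] * 20, "aC": [100] * 20, "bC": [100] * 20},
            index=[f"g{i}" for i in range(20)],
        )
        classes = {"aY": "Yellow", "bY": "Yellow", "aC": "Colored", "bC": "Colored"}
        factors = hk_normalization_factors(counts, counts.index.tolist())
        est = estimate_common_dispersion(counts, counts.index.tolist(), factors, classes)
        assert est.phi == pytest.approx(1e-6, abs=1e-4)

    def test_single_sample_per_class_is_error(self):
        counts = pd.DataFrame({"aY": [10], "aC": [12]}, index=["g0"])
        with pytest.raises(ValueError):
            estimate_common_dispersion(
                counts, ["g0"], pd.Series([1.0, 1.0], index=["aY", "aC"]),
                {"aY": "Yellow", "aC": "Colored"},
            )


class TestSelectHkGenes:
    def _hit(self, q, s):
        from polymorphome.core_io import HitRecord

        return HitRecord(q, s, 90.0, 100, 1e-20, 100.0)

    def test_selection_rules(self):
        comp_a = {"a1_i1": "a1", "a2_i1": "a2", "a2_i2": "a2", "a3_i1": "a3"}
        comp_b = {"b1_i1": "b1", "b2_i1": "b2"}
        hits_a = [
            self._hit("HK1", "a1_i1"),           # single component in A
            self._hit("HK2", "a2_i1"), self._hit("HK2", "a3_i1"),  # two comps
            self._hit("HK3", "a3_i1"),           # missing in B
        ]
        hits_b = [self._hit("HK1", "b1_i1"), self._hit("HK2", "b2_i1")]
        rbh_a = [RbhPair("HK1", "a1_i1", 100, 100)]
        rbh_b = [RbhPair("HK1", "b1_i1", 100, 100)]
        hk = diffexpr.select_hk_genes(hits_a, hits_b, rbh_a, rbh_b, comp_a, comp_b)
        assert hk.candidates == ("HK1",)
        assert hk.components_a == ("a1",) and hk.components_b == ("b1",)


class TestPanelDe:
    def test_planted_up_regulation_recovered(self):
        counts, truth = synth.simulate_counts(synth.SynthConfig(seed=11))
        table, band, band_counts = pigment_panel_de(
            counts, list(truth.pigment_ids), list(truth.hk_ids), synth.SAMPLE_CLASS
        )
        by_gene = table.set_index("gene_id")
        # strong planted effects: sign recovered for every pigment gene
        strong = [g for g in truth.pigment_ids if truth.log2fc[g] >= 3.0]
        assert strong, "generator should plant some strong effects"
        for g in strong:
            assert by_gene.loc[g, "log2fc"] > 0
            assert by_gene.loc[g, "band_class"] == diffexpr.UP_BEYOND_BAND

    def test_zero_fc_panel_mostly_inside_band(self):
        cfg = synth.SynthConfig(seed=13, pigment_log2fc_range=(0.0, 0.0))
        counts, truth = synth.simulate_counts(cfg)
        table, band, _ = pigment_panel_de(
            counts, list(truth.pigment_ids), list(truth.hk_ids), synth.SAMPLE_CLASS
        )
        inside = table["band_class"].isin(
            [diffexpr.UP, diffexpr.WITHIN, diffexpr.DOWN]
        ).mean()
        assert inside >= 0.85

    def test_output_sorted_by_decreasing_fold_change(self):
        counts, truth = synth.simulate_counts(synth.SynthConfig(seed=17))
        table, _, _ = pigment_panel_de(
            counts, list(truth.pigment_ids), list(truth.hk_ids), synth.SAMPLE_CLASS
        )
        assert (table["log2fc"].diff().dropna() <= 1e-12).all()


class TestRankExpression:
    def test_hand_ranking(self):
        counts = pd.DataFrame(
            {"s1": [10, 100, 50], "s2": [12, 110, 55]}, index=["low", "high", "mid"]
        )
        factors = pd.Series([1.0, 1.0], index=["s1", "s2"])
        ranked = rank_expression(counts, factors, top_n=3)
        assert ranked["gene_id"].tolist() == ["high", "mid", "low"]

    def test_top_n_larger_than_matrix(self):
        counts = pd.DataFrame({"s1": [5]}, index=["only"])
        ranked = rank_expression(counts, pd.Series([1.0], index=["s1"]), top_n=10)
        assert len(ranked) == 1 and ranked.iloc[0]["rank"] == 1
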