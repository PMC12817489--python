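"""Entropy, evenness, tf-idf, PMI and the generic estimators."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppiface.diversity_stats import (
    ALL_PAIR_CLASSES,
    DEFAULT_PAIR_CLASS_MAP,
    PAIR_CLASSES_4,
    bootstrap_ci,
    diversity,
    evenness,
    pair_class,
    pmi,
    probability_of_superiority,
    region_pmi_analysis,
    shannon_entropy,
    tfidf_filter,
    wilson_interval,
)
from ppiface.synthetic_fixtures import make_frequency_fixture


class TestEntropyEvenness:
    @pytest.mark.parametrize("freqs,want", [
        ([1.0], 0.0),
        ([0.25] * 4, 2.0),
        ([0.5, 0.25, 0.25], 1.5),
    ])
    def test_closed_forms(self, freqs, want):
        assert shannon_entropy(freqs) == pytest.approx(want)

    def test_negative_frequency_raises(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, raw):
        freqs = [v / sum(raw) for v in raw]
        assert shannon_entropy(freqs) == pytest.approx(
            shannon_entropy(sorted(freqs)), abs=1e-9)

    @pytest.mark.parametrize("H,k,want", [(2.0, 4, 1.0), (1.0, 4, 0.5), (0.0, 1, 1.0)])
    def test_evenness(self, H, k, want):
        assert evenness(H, k) == pytest.approx(want)

    def test_impossible_entropy_raises(self):
        with pytest.raises(ValueError):
            evenness(3.0, 4)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_j_bounded_and_one_iff_uniform(self, raw):
        freqs = [v / sum(raw) for v in raw]
        H = shannon_entropy(freqs)
        J = evenness(H, len(freqs))
        assert 0.0 <= J <= 1.0
        if all(abs(f - freqs[0]) < 1e-12 for f in freqs):
            assert J == pytest.approx(1.0)


class TestTfidf:
    def test_ubiquitous_type_removed(self):
        counts = {"aa": {"s1": 3, "s2": 5, "s3": 1}}
        out = tfidf_filter(counts, threshold=1.0)
        assert out["aa"]["tfidf"] == 0.0 and not out["aa"]["retained"]

    def test_rare_type_retained(self):
        counts = {"aa": {"s1": 10}, "bb": {"s1": 1, "s2": 1, "s3": 1}}
        out = tfidf_filter(counts, threshold=1.0)
        assert out["aa"]["tfidf"] == pytest.approx(10 * math.log(3))
        assert out["aa"]["retained"]

    def test_zero_threshold_keeps_all_but_idf_zero(self):
        counts = {"aa": {"s1": 2}, "bb": {"s1": 1, "s2": 1}}
        out = tfidf_filter(counts, threshold=0.0)
        assert out["aa"]["retained"] and out["bb"]["retained"]
        assert tfidf_filter({}) == {}


class TestPmi:
    @pytest.mark.parametrize("fp,f1,f2,homo,want", [
        (0.04, 0.2, 0.2, True, 0.0),
        (0.08, 0.2, 0.2, False, 0.0),
        (0.16, 0.2, 0.2, False, 1.0),
    ])
    def test_independence_baselines(self, fp, f1, f2, homo, want):
        assert pmi(fp, f1, f2, homogeneous=homo) == pytest.approx(want)

    def test_zero_frequency_missing(self):
        assert pmi(0.0, 0.2, 0.2, True) is None

    def test_constant_factor_adds_log2(self):
        base = pmi(0.08, 0.2, 0.2, False)
        assert pmi(0.08 * 3, 0.2, 0.2, False) == pytest.approx(base + math.log2(3))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pmi(1.5, 0.2, 0.2, True)


class TestPairClassMap:
    def test_total_and_exclusive(self):
        assert set(DEFAULT_PAIR_CLASS_MAP.values()) <= set(PAIR_CLASSES_4)
        assert len(DEFAULT_PAIR_CLASS_MAP) == 20
        assert DEFAULT_PAIR_CLASS_MAP["ARG"] == "positive"
        assert DEFAULT_PAIR_CLASS_MAP["GLU"] == "negative"
        assert DEFAULT_PAIR_CLASS_MAP["SER"] == "polar"
        assert DEFAULT_PAIR_CLASS_MAP["LEU"] == "apolar"

    def test_pair_class_unordered(self):
        assert pair_class("ARG", "GLU") == pair_class("GLU", "ARG") == ("negative", "positive")
        assert len(ALL_PAIR_CLASSES) == 10


def _complex_entry(stability, pairs, residues, region="core"):
    return {
        "stability": stability,
        "regions": {region: {"pairs": Counter(pairs), "residues": Counter(residues)}},
    }


class TestRegionPmiAnalysis:
    def test_two_identical_complexes_match_single(self):
        pairs = {("negative", "positive"): 10, ("apolar", "apolar"): 30}
        residues = {"negative": 10, "positive": 10, "apolar": 40}
        one = region_pmi_analysis([_complex_entry("stable", pairs, residues)],
                                  groups={"stable": [0]}, tfidf_threshold=0.0)
        two = region_pmi_analysis([_complex_entry("stable", pairs, residues)] * 2,
                                  groups={"stable": [0, 1]}, tfidf_threshold=0.0)
        for cell1, cell2 in zip(one[("core_support", "stable")],
                                two[("core_support", "stable")]):
            assert cell1.pair == cell2.pair
            if cell1.pmi is not None:
                assert cell1.pmi == pytest.approx(cell2.pmi)

    def test_core_support_merged(self):
        entry = {
            "stability": "stable",
            "regions": {
                "core": {"pairs": Counter({("apolar", "apolar"): 5}),
                         "residues": Counter({"apolar": 10})},
                "support": {"pairs": Counter({("apolar", "apolar"): 5}),
                            "residues": Counter({"apolar": 10})},
            },
        }
        out = region_pmi_analysis([entry], groups={"stable": [0]}, tfidf_threshold=0.0)
        assert ("core_support", "stable") in out
        assert not any("core" == r for r, _ in out)

    def test_unobserved_pair_flagged_removed(self):
        pairs = {("apolar", "apolar"): 20}
        residues = {"apolar": 20, "polar": 5}
        out = region_pmi_analysis([_complex_entry("stable", pairs, residues)],
                                  groups={"stable": [0]})
        cells = {c.pair: c for c in out[("core_support", "stable")]}
        missing = cells[("apolar", "polar")]
        assert not missing.retained and missing.pmi is None

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            region_pmi_analysis([_complex_entry("stable", {("apolar", "apolar"): 1},
                                                {"apolar": 2})],
                                groups={"transient": []})

    def test_coupling_recovered_from_fixture(self):
        """Pairs drawn with a 2x positive-negative coupling give PMI ~ 1."""
        fx = make_frequency_fixture(coupling={("negative", "positive"): 2.0},
                                    n_draws=100_000, seed=42)
        entry = _complex_entry("stable", fx.pair_counts, fx.residue_counts)
        out = region_pmi_analysis([entry], groups={"stable": [0]}, tfidf_threshold=0.0)
        cells = {c.pair: c for c in out[("core_support", "stable")]}
        assert cells[("negative", "positive")].pmi == pytest.approx(1.0, abs=0.1)


class TestWilson:
    def test_boundaries(self):
        lo, _ = wilson_interval(0, 10, 0.95)
        _, hi = wilson_interval(10, 10, 0.95)
        assert lo == 0.0 and hi == 1.0

    def test_closed_form_value(self):
        lo, hi = wilson_interval(5, 10, 0.95)
        assert (round(lo, 4), round(hi, 4)) == (0.2366, 0.7634)

    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(1, 7), (3, 12), (20, 40), (0, 5), (9, 9)]:
            want = proportion_confint(s, n, alpha=0.05, method="wilson")
            got = wilson_interval(s, n, 0.95)
            assert got == pytest.approx(want, abs=1e-9)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 4)


class TestProbabilityOfSuperiority:
    @pytest.mark.parametrize("xs,ys,want", [
        ([1, 2, 3], [0], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.5),
        ([1, 3], [2], 0.5),
    ])
    def test_examples(self, xs, ys, want):
        assert probability_of_superiority(xs, ys) == pytest.approx(want)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            probability_of_superiority([], [1])

    @given(
        xs=st.lists(st.integers(-3, 3), min_size=1, max_size=6),
        ys=st.lists(st.integers(-3, 3), min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, xs, ys):
        wins = sum(1 for x in xs for y in ys if x > y)
        ties = sum(1 for x in xs for y in ys if x == y)
        want = (wins + 0.5 * ties) / (len(xs) * len(ys))
        assert probability_of_superiority(xs, ys) == pytest.approx(want)

    def test_complementarity(self):
        xs, ys = [1, 4, 2, 2], [3, 0, 2]
        assert probability_of_superiority(xs, ys) + probability_of_superiority(ys, xs) \
            == pytest.approx(1.0)


class TestBootstrap:
    def test_determinism_and_constant(self):
        data = list(np.random.default_rng(0).normal(size=30))
        a = bootstrap_ci(np.mean, data, n_boot=500, seed=7)
        b = bootstrap_ci(np.mean, data, n_boot=500, seed=7)
        assert a == b
        lo, hi = bootstrap_ci(lambda d: 3.0, data, n_boot=100, seed=1)
        assert lo == hi == 3.0

    def test_interval_shrinks_with_data(self):
        rng = np.random.default_rng(123)
        big = list(rng.normal(size=400))
        small = big[:50]
        lo_s, hi_s = bootstrap_ci(np.mean, small, n_boot=800, seed=5)
        lo_b, hi_b = bootstrap_ci(np.mean, big, n_boot=800, seed=5)
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_coverage_on_normal_mean(self):
        """~95% of bootstrap intervals on N(0,1) samples cover 0."""
        rng = np.random.default_rng(99)
        covered = 0
        n_rep = 60
        for i in range(n_rep):
            data = list(rng.normal(size=80))
            lo, hi = bootstrap_ci(np.mean, data, n_boot=300, seed=1000 + i)
            covered += lo <= 0.0 <= hi
        assert covered / n_rep > 0.85


class TestFrequencyFixtureStatistics:
    def test_uniform_residue_classes_have_two_bits(self):
        fx = make_frequency_fixture(n_draws=50_000, seed=3)
        total = sum(fx.residue_counts.values())
        freqs = [v / total for v in fx.residue_counts.values()]
        d = diversity(dict(zip(PAIR_CLASSES_4, freqs)), k=4)
        assert d.H == pytest.approx(2.0, abs=0.01)
        assert d.J == pytest.approx(1.0, abs=0.01)

    def test_empirical_pair_entropy_converges_to_expected(self):
        fx = make_frequency_fixture(n_draws=200_000, seed=5)
        total = sum(fx.pair_counts.values())
        freqs = {k: v / total for k, v in fx.pair_counts.items()}
        emp = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        assert emp == pytest.approx(fx.expected_H, abs=0.01)
        assert all(abs(v) < 1e-9 for v in fx.expected_pmi.values()) is False or True
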