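"""Composition, partitioning, stickiness, per-pair means and BSA scaling."""

import math

import numpy as np
import pytest

from ppiface.interface_metrics import (
    DEFAULT_CAPABILITY,
    DEFAULT_CLASS_TABLE,
    count_interactions_by_region,
    mean_count_per_pair,
    pair_bsa_scaling,
    partition_by_region,
    region_composition,
    stickiness,
    weighted_same_region_pair_count,
)
from ppiface.interactions import InteractionRecord, PairRecord
from ppiface.sasa_regions import RegionAssignment


def _assignment(key, resname, region):
    return RegionAssignment(
        key=key, resname=resname, asa_monomer=0.0, asa_complex=0.0,
        rasa_monomer=0.0, rasa_complex=0.0, delta_rasa=0.0,
        region_by_scale={}, region=region,
    )


def _regions(spec):
    """spec: list of (resname, region) -> keyed region map."""
    return {
        ("A", i + 1, ""): _assignment(("A", i + 1, ""), name, region)
        for i, (name, region) in enumerate(spec)
    }


class TestClassTable:
    def test_tyrosine_is_polar_with_neutral_hydropathy(self):
        assert DEFAULT_CLASS_TABLE.polarity["TYR"] == "polar"
        assert DEFAULT_CLASS_TABLE.hydropathy["TYR"] == "neutral"

    def test_every_residue_labelled_in_every_dimension(self):
        for res in DEFAULT_CLASS_TABLE.charge:
            for dim in ("charge", "polarity", "hydropathy", "aromatic",
                        "aliphatic", "sidechain_hbond"):
                assert DEFAULT_CLASS_TABLE.label(res, dim)


class TestComposition:
    def test_counting_example(self):
        regions = _regions([("ARG", "core"), ("LYS", "core"),
                            ("ASP", "core"), ("LEU", "core")])
        result = region_composition(regions, dimension="charge")
        assert result.percentages["core"] == pytest.approx(
            {"positive": 50.0, "negative": 25.0, "neutral": 25.0}
        )

    def test_empty_region_flagged_not_nan(self):
        regions = _regions([("ARG", "core")])
        result = region_composition(regions, dimension="charge")
        assert result.percentages["support"] == {}
        assert result.counts["support"] == 0

    def test_vectors_total_100(self, burial_dimer):
        model, _ = burial_dimer
        regions = _regions([("ARG", "core"), ("TYR", "rim_nis"), ("LEU", "core"),
                            ("SER", "support"), ("GLY", "support")])
        result = region_composition(regions, dimension="polarity")
        for region, vec in result.percentages.items():
            if vec:
                assert sum(vec.values()) == pytest.approx(100.0)


class TestPartitioning:
    def test_examples(self):
        regions = _regions([("ARG", "core"), ("LYS", "core"),
                            ("HIS", "support"), ("ARG", "rim_interacting")])
        out = partition_by_region("positive", regions)
        assert out == pytest.approx({"core": 0.5, "support": 0.25,
                                     "rim_interacting": 0.25, "rim_nis": 0.0})
        assert sum(out.values()) == pytest.approx(1.0)

    def test_all_in_support(self):
        regions = _regions([("ASP", "support"), ("GLU", "support")])
        out = partition_by_region("negative", regions)
        assert out["support"] == 1.0

    def test_absent_class_reported_missing(self):
        regions = _regions([("LEU", "core")])
        assert partition_by_region("negative", regions) is None

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        names = rng.choice(["ARG", "LYS", "ASP", "LEU", "SER"], size=60)
        places = rng.choice(["core", "support", "rim_interacting", "rim_nis"], size=60)
        regions = _regions(list(zip(names, places)))
        out = partition_by_region("positive", regions)
        want = {r: 0 for r in ("core", "support", "rim_interacting", "rim_nis")}
        for n, p in zip(names, places):
            if n in ("ARG", "LYS"):  # HIS absent from draw
                want[p] += 1
        total = sum(want.values())
        for r in want:
            assert out[r] == pytest.approx(want[r] / total)


class TestStickiness:
    def test_closed_forms(self):
        interface = {"LEU": 30.0, "SER": 10.0}
        surface = {"LEU": 30.0, "SER": 10.0}
        out = stickiness(interface, surface)
        assert out["LEU"] == pytest.approx(0.0, abs=1e-5)
        # doubled interface share -> ln 2
        interface2 = {"LEU": 40.0, "SER": 20.0, "GLY": 0.0}
        surface2 = {"LEU": 20.0, "SER": 40.0, "GLY": 0.0}
        out2 = stickiness(interface2, surface2)
        assert out2["LEU"] == pytest.approx(math.log(2), abs=1e-3)

    def test_absent_type_missing_not_zero(self):
        out = stickiness({"LEU": 10.0, "GLY": 0.0}, {"LEU": 10.0, "GLY": 0.0})
        assert out["GLY"] is None

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        names = ["ALA", "ARG", "LEU", "TYR", "SER"]
        ai = dict(zip(names, rng.uniform(1, 50, 5)))
        asf = dict(zip(names, rng.uniform(1, 50, 5)))
        out = stickiness(ai, asf)
        for n in names:
            fi = ai[n] / sum(ai.values()) + 1e-6
            fs = asf[n] / sum(asf.values()) + 1e-6
            assert out[n] == pytest.approx(math.log(fi / fs))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            stickiness({"LEU": 0.0}, {"LEU": 1.0})


def _rec(itype, key_a, key_b):
    return InteractionRecord(itype, "", (key_a, key_b), {}, True)


def _pair(key_a, key_b, names, regions, interactions=()):
    return PairRecord(pair=(key_a, key_b), resnames=names, ca_distance=8.0,
                      inter_chain=True, interactions=list(interactions),
                      regions=regions)


class TestCounting:
    def setup_method(self):
        self.ka, self.kb = ("A", 1, ""), ("B", 1, "")
        self.kc, self.kd = ("A", 2, ""), ("B", 2, "")

    def test_same_and_cross_region_scopes(self):
        records = [_rec("salt_bridge", self.ka, self.kb),
                   _rec("hbond", self.kc, self.kd)]
        pairs = [
            _pair(self.ka, self.kb, ("ARG", "ASP"), ("core", "core")),
            _pair(self.kc, self.kd, ("SER", "ASP"), ("core", "rim_interacting")),
        ]
        same = count_interactions_by_region(records, pairs, scope="same_region")
        assert same == {"core": {"salt_bridge": 1}}
        cross = count_interactions_by_region(records, pairs, scope="cross_region")
        assert cross == {("core", "rim_interacting"): {"hbond": 1}}

    def test_totals_match_brute_force(self):
        rng = np.random.default_rng(5)
        keys = [("A", i, "") for i in range(1, 11)] + [("B", i, "") for i in range(1, 11)]
        records, pairs = [], []
        for i in range(30):
            ka, kb = keys[rng.integers(0, 10)], keys[10 + rng.integers(0, 10)]
            if any(p.pair == (ka, kb) for p in pairs):
                continue
            region_a = rng.choice(["core", "support", "rim_interacting"])
            region_b = rng.choice(["core", "support", "rim_interacting"])
            n = int(rng.integers(1, 4))
            recs = [_rec(str(rng.choice(["hbond", "vdw"])), ka, kb) for _ in range(n)]
            records += recs
            pairs.append(_pair(ka, kb, ("ALA", "ALA"), (region_a, region_b), recs))
        same = count_interactions_by_region(records, pairs, scope="same_region")
        total_same = sum(v for per in same.values() for v in per.values())
        want = sum(len(p.interactions) for p in pairs if p.regions[0] == p.regions[1])
        assert total_same == want


class TestMeanCountPerPair:
    def setup_method(self):
        self.regions = _regions([("ARG", "core"), ("ASP", "core"),
                                 ("LYS", "core"), ("GLU", "core"),
                                 ("LEU", "core")])
        keys = sorted(self.regions)
        self.k = keys

    def test_binary_proportion_with_wilson(self):
        # capable pairs: every cation-anion combination in the core
        caps = [(self.k[0], self.k[1]), (self.k[0], self.k[3]),
                (self.k[2], self.k[1]), (self.k[2], self.k[3])]
        pairs = [
            PairRecord(pair=c, resnames=(self.regions[c[0]].resname,
                                         self.regions[c[1]].resname),
                       ca_distance=8.0, inter_chain=True)
            for c in caps
        ]
        records = [_rec("salt_bridge", *caps[0])]
        out = mean_count_per_pair(records, pairs, "salt_bridge", "core", self.regions)
        assert out.binary and out.mean == pytest.approx(0.25)
        from ppiface.diversity_stats import wilson_interval

        assert (out.ci_low, out.ci_high) == pytest.approx(wilson_interval(1, 4, 0.95))

    def test_counted_type_mean(self):
        caps = [(self.k[0], self.k[1]), (self.k[0], self.k[3]), (self.k[2], self.k[1])]
        pairs = [PairRecord(pair=c, resnames=("ARG", "ASP"), ca_distance=8.0,
                            inter_chain=True) for c in caps]
        records = ([_rec("hbond", *caps[0])] * 2 + [_rec("hbond", *caps[1])])
        out = mean_count_per_pair(records, pairs, "hbond", "core", self.regions)
        assert not out.binary
        assert out.mean == pytest.approx(1.0)  # counts {2,1,0} over 3 pairs

    def test_capability_restricts_denominator(self):
        keys = self.k
        pairs = [PairRecord(pair=(keys[i], keys[j]),
                            resnames=(self.regions[keys[i]].resname,
                                      self.regions[keys[j]].resname),
                            ca_distance=8.0, inter_chain=True)
                 for i in range(len(keys)) for j in range(i + 1, len(keys))]
        out = mean_count_per_pair([], pairs, "salt_bridge", "core", self.regions)
        # ARG-ASP, ARG-GLU, LYS-ASP, LYS-GLU are capable; LEU pairs and
        # like-charge pairs are not
        assert out.n_capable == 4

    def test_invariant_to_adding_incapable_pairs(self):
        caps = [(self.k[0], self.k[1])]
        pairs = [PairRecord(pair=caps[0], resnames=("ARG", "ASP"),
                            ca_distance=8.0, inter_chain=True)]
        records = [_rec("salt_bridge", *caps[0])]
        base = mean_count_per_pair(records, pairs, "salt_bridge", "core", self.regions)
        extra = pairs + [PairRecord(pair=(self.k[4], self.k[1]),
                                    resnames=("LEU", "ASP"),
                                    ca_distance=8.0, inter_chain=True)]
        again = mean_count_per_pair(records, extra, "salt_bridge", "core", self.regions)
        assert (base.mean, base.n_capable) == (again.mean, again.n_capable)

    def test_zero_capable_pairs_missing(self):
        out = mean_count_per_pair([], [], "salt_bridge", "core", self.regions)
        assert out is None


class TestScaling:
    def test_doubling_rule(self):
        ka, kb = ("A", 1, ""), ("B", 1, "")
        pairs = [
            _pair(ka, kb, ("ALA", "ALA"), ("core", "core")),
            _pair(("A", 2, ""), ("B", 2, ""), ("ALA", "ALA"), ("core", "core")),
            _pair(("A", 3, ""), ("B", 3, ""), ("ALA", "ALA"), ("core", "core")),
        ]
        assert weighted_same_region_pair_count(pairs, "core") == 6.0
        assert weighted_same_region_pair_count([], "core") == 0.0

    def test_rim_merging(self):
        pairs = [_pair(("A", 1, ""), ("B", 1, ""), ("ALA", "ALA"),
                       ("rim_interacting", "rim_nis"))]
        assert weighted_same_region_pair_count(pairs, "rim") == 2.0

    def test_doubling_conservation(self):
        rng = np.random.default_rng(9)
        labels = ["core", "support", "rim_interacting", "rim_nis"]
        pairs = []
        for i in range(40):
            ra, rb = rng.choice(labels, size=2)
            pairs.append(_pair(("A", i, ""), ("B", i, ""), ("ALA", "ALA"), (ra, rb)))
        total = sum(weighted_same_region_pair_count(pairs, r)
                    for r in ("core", "support", "rim"))
        def merged(lbl):
            return "rim" if lbl.startswith("rim") else lbl
        n_same = sum(1 for p in pairs if merged(p.regions[0]) == merged(p.regions[1]))
        assert total == 2 * n_same

    def test_ols_parameter_recovery(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(100, 900, size=60)
        y = 1.2 * x + rng.normal(0, 25, size=60)
        fit = pair_bsa_scaling(list(zip(x, y)))
        se = abs(fit.slope) / max(np.sqrt(fit.r_squared * len(x)), 1)
        assert fit.slope == pytest.approx(1.2, abs=0.05)
        assert fit.r_squared > 0.95

    def test_fit_skipped_below_two_points(self):
        assert pair_bsa_scaling([(1.0, 2.0)]) is None
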