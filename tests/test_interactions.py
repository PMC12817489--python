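"""Interaction detectors: fixtures, boundaries, invariances, bookkeeping."""

import math

import numpy as np
import pytest

from ppiface.interactions import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    INTERACTION_TYPES,
    detect_all,
    detect_clash_repulsion,
    detect_pair,
    enumerate_candidate_pairs,
)
from ppiface.interface_metrics import DEFAULT_CAPABILITY
from ppiface.structure_io import AtomRecord, ResidueRecord, StructureModel
from ppiface.synthetic_fixtures import (
    ANGLE_VIOLATION_TYPES,
    make_interaction_geometry,
    _model,
    _res,
)


def _pair_of(model):
    return model.chains["A"][0], model.chains["B"][0]


def _types(model, cfg=DEFAULT_GEOMETRY):
    a, b = _pair_of(model)
    return {r.type for r in detect_pair(a, b, cfg)}


class TestDetectorFixtures:
    @pytest.mark.parametrize("itype", INTERACTION_TYPES)
    def test_positive_fires(self, itype):
        model = make_interaction_geometry(itype, positive=True)
        assert itype in _types(model)

    @pytest.mark.parametrize("itype", INTERACTION_TYPES)
    def test_negative_by_distance_silent(self, itype):
        model = make_interaction_geometry(itype, positive=False, violate="distance")
        assert itype not in _types(model)

    @pytest.mark.parametrize("itype", sorted(ANGLE_VIOLATION_TYPES))
    def test_negative_by_angle_silent(self, itype):
        model = make_interaction_geometry(itype, positive=False, violate="angle")
        assert itype not in _types(model)

    @pytest.mark.parametrize("itype", INTERACTION_TYPES)
    def test_symmetric_in_argument_order(self, itype):
        model = make_interaction_geometry(itype, positive=True)
        a, b = _pair_of(model)
        fwd = sorted((r.type, r.subtype) for r in detect_pair(a, b))
        rev = sorted((r.type, r.subtype) for r in detect_pair(b, a))
        assert fwd == rev

    @pytest.mark.parametrize("itype", INTERACTION_TYPES)
    def test_rigid_motion_invariance(self, itype):
        from scipy.spatial.transform import Rotation

        model = make_interaction_geometry(itype, positive=True)
        a, b = _pair_of(model)
        reference = sorted((r.type, r.subtype) for r in detect_pair(a, b))
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-50, 50, size=3)

            def moved(res):
                return ResidueRecord(
                    res.chain_id, res.seq_number, res.insertion_code, res.name,
                    [AtomRecord(x.name, x.element, rot @ x.coords + shift)
                     for x in res.atoms],
                )

            got = sorted((r.type, r.subtype) for r in detect_pair(moved(a), moved(b)))
            assert got == reference, f"{itype} changed under rigid motion (seed {seed})"

    def test_capability_soundness(self):
        """Every record's type is permitted by the capability table."""
        for itype in INTERACTION_TYPES:
            model = make_interaction_geometry(itype, positive=True)
            a, b = _pair_of(model)
            for rec in detect_pair(a, b):
                assert DEFAULT_CAPABILITY.capable(rec.type, a.name, b.name), (
                    f"{rec.type} recorded for incapable pair {a.name}-{b.name}"
                )


class TestBoundarySemantics:
    def test_hbond_at_exact_cutoff_fires(self):
        model = make_interaction_geometry("hbond", positive=True, margin=0.0)
        assert "hbond" in _types(model)

    def test_hbond_just_beyond_cutoff_silent(self):
        model = make_interaction_geometry("hbond", positive=False, margin=0.001,
                                          self_test=False)
        assert "hbond" not in _types(model)

    def test_vdw_at_exact_cutoff_fires(self):
        model = make_interaction_geometry("vdw", positive=True, margin=0.0)
        assert "vdw" in _types(model)


class TestSpecialRules:
    def test_sse_hbond_routes_away_from_plain_hbond(self):
        model = make_interaction_geometry("sse_hbond", positive=True, margin=0.6)
        a, b = _pair_of(model)
        records = detect_pair(a, b)
        assert sum(r.type == "sse_hbond" for r in records) == 1
        assert sum(r.type == "hbond" for r in records) == 0

    def test_stacked_arg_arg_excluded_from_charge_clash(self):
        model = make_interaction_geometry("arg_arg_stacking", positive=True)
        a, b = _pair_of(model)
        records = detect_pair(a, b)
        assert any(r.type == "arg_arg_stacking" for r in records)
        assert not any(r.type == "charge_clash" for r in records)

    def test_unstacked_like_charge_arg_pair_can_clash(self):
        # side-by-side guanidiniums: backbones and side chains close, no stacking
        model = make_interaction_geometry("arg_arg_stacking", positive=False,
                                          violate="angle")
        a, b = _pair_of(model)
        types = {r.type for r in detect_pair(a, b)}
        assert "arg_arg_stacking" not in types
        assert "charge_clash" in types

    def test_vdw_does_not_double_count_directional_atoms(self):
        model = make_interaction_geometry("hbond", positive=True)
        a, b = _pair_of(model)
        records = detect_pair(a, b)
        hb_atoms = {frozenset(r.atoms) for r in records if r.type == "hbond"}
        vdw_atoms = {frozenset(r.atoms) for r in records if r.type == "vdw"}
        assert hb_atoms and not (hb_atoms & vdw_atoms)

    def test_glycine_pair_skipped_for_clash(self):
        gly = _res("GLY", "A", 1, [
            ("N", "N", (0, 0, 0)), ("CA", "C", (1.46, 0, 0)),
            ("C", "C", (2.0, 1.4, 0)), ("O", "O", (3.23, 1.4, 0)),
        ])
        leu = _res("LEU", "B", 1, [
            ("N", "N", (5, 0, 0)), ("CA", "C", (6.46, 0, 0)),
            ("C", "C", (7.0, 1.4, 0)), ("O", "O", (8.23, 1.4, 0)),
            ("CB", "C", (6.9, -1.4, 0)),
        ])
        assert detect_clash_repulsion(gly, leu) == []

    def test_his_cation_flag(self):
        import dataclasses

        model = make_interaction_geometry("salt_bridge", positive=True)
        # replace ARG by a HIS-like imidazole donor: just flip the flag path
        cfg_off = dataclasses.replace(DEFAULT_GEOMETRY, his_as_cation=False)
        assert DEFAULT_CAPABILITY.capable("salt_bridge", "HIS", "ASP")
        from ppiface.interface_metrics import CapabilityTable

        assert not CapabilityTable(his_as_cation=False).capable("salt_bridge", "HIS", "ASP")
        # the ARG fixture itself is unaffected by the flag
        assert "salt_bridge" in _types(model, cfg_off)


class TestCandidatePairs:
    def _two_res_model(self, d):
        a = _res("ALA", "A", 1, [("CA", "C", (0, 0, 0)), ("CB", "C", (0, 1.5, 0))])
        b = _res("ALA", "B", 1, [("CA", "C", (d, 0, 0)), ("CB", "C", (d, 1.5, 0))])
        return _model("toy", [a, b])

    @pytest.mark.parametrize("d,kept", [(13.9, True), (14.0, True), (14.1, False)])
    def test_cutoff_is_inclusive(self, d, kept):
        pairs = enumerate_candidate_pairs(self._two_res_model(d), ca_cutoff=14.0)
        assert bool(pairs) is kept

    def test_matches_brute_force_on_toy_chain(self):
        rng = np.random.default_rng(7)
        residues = []
        pos = np.zeros(3)
        for i in range(50):
            pos = pos + rng.normal(3.0, 1.0, size=3) * rng.choice([-1, 1], size=3)
            residues.append(_res("ALA", "A", i + 1, [("CA", "C", tuple(pos))]))
        model = _model("chain", residues)
        got = {
            p.pair for p in enumerate_candidate_pairs(
                model, ca_cutoff=14.0, scope="intra_chain", min_seq_separation=2)
        }
        coords = {r.key: r.atom("CA").coords for r in residues}
        keys = sorted(coords)
        want = set()
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if abs(keys[i][1] - keys[j][1]) < 2:
                    continue
                if np.linalg.norm(coords[keys[i]] - coords[keys[j]]) <= 14.0:
                    want.add((keys[i], keys[j]))
        assert got == want

    def test_single_residue_empty(self):
        model = _model("one", [_res("ALA", "A", 1, [("CA", "C", (0, 0, 0))])])
        assert enumerate_candidate_pairs(model) == []

    def test_no_record_beyond_candidate_cutoff(self):
        model = self._two_res_model(20.0)
        result = detect_all(model)
        assert result.records == [] and result.candidates == []


class TestDetectAll:
    def test_composed_dimer_yields_expected_pairs(self, hbond_salt_dimer_pdb):
        from ppiface.structure_io import load_structure

        model = load_structure(hbond_salt_dimer_pdb)
        result = detect_all(model)
        assert len(result.pairs) == 2
        types = {t for p in result.pairs for t in {r.type for r in p.interactions}}
        assert {"salt_bridge", "hbond"} <= types

    def test_far_separated_chains_give_nothing(self):
        a = _res("ALA", "A", 1, [("CA", "C", (0, 0, 0))])
        b = _res("ALA", "B", 1, [("CA", "C", (50, 0, 0))])
        result = detect_all(_model("far", [a, b]))
        assert result.records == [] and result.pairs == []

    def test_pair_records_only_for_interacting(self):
        model = make_interaction_geometry("hbond", positive=False, violate="distance",
                                          self_test=False)
        result = detect_all(model)
        interacting = {p.pair for p in result.pairs}
        for p in result.candidates:
            assert (p.pair in interacting) == bool(p.interactions)


def test_geometry_config_from_file(tmp_path):
    p = tmp_path / "geom.cfg"
    p.write_text("d_hb = 3.2\nca_cutoff = 12\nhis_as_cation = false\n# comment\n")
    cfg = GeometryConfig.from_file(p)
    assert cfg.d_hb == 3.2 and cfg.ca_cutoff == 12.0 and cfg.his_as_cation is False
    assert cfg.d_sb == DEFAULT_GEOMETRY.d_sb
    p2 = tmp_path / "bad.cfg"
    p2.write_text("no_such_key = 1\n")
    with pytest.raises(KeyError):
        GeometryConfig.from_file(p2)
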