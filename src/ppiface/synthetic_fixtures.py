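"""Download-free synthetic test inputs.

Four fixture families, all deterministic under a fixed seed:

* multi-sphere "structures" with analytically known SASA (isolated-sphere
  and two-sphere spherical-cap closed forms),
* two-chain burial dimers whose probe residues have prescribed monomer /
  complex rASA bands, so their region labels are ground truth by
  construction (verified internally with the package's own SASA),
* residue-pair geometries built to satisfy — or to violate exactly one
  criterion of — each interaction detector,
* random pair-frequency tables with known entropy, evenness and PMI.

Interaction and burial fixtures can be written as standard PDB files so the
full pipeline path, parser included, is exercised. All scaffolds use
idealized local geometry (standard-ish bond lengths), not fragments of real
structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import AtomRecord, ResidueRecord, StructureModel
from .sasa_regions import (
    DEFAULT_SCALES,
    RegionThresholds,
    VDW_RADII,
    assign_regions,
    compute_sasa,
)
from .interactions import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    INTERACTION_TYPES,
    detect_pair,
)
from .diversity_stats import ALL_PAIR_CLASSES, PAIR_CLASSES_4

# ---------------------------------------------------------------------------
# Model assembly and PDB writing

def _res(name: str, chain: str, seq: int, atoms: list[tuple[str, str, tuple]]) -> ResidueRecord:
    return ResidueRecord(
        chain_id=chain,
        seq_number=seq,
        insertion_code="",
        name=name,
        atoms=[AtomRecord(n, el, np.asarray(xyz, dtype=float)) for n, el, xyz in atoms],
    )


def _model(structure_id: str, residues: list[ResidueRecord]) -> StructureModel:
    chains: dict[str, list[ResidueRecord]] = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return StructureModel(structure_id, chains, {"format": "synthetic"})


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a fixed-column PDB file."""
    lines = []
    serial = 1
    for chain_id in model.chains:
        for res in model.chains[chain_id]:
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} {chain_id:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SASA toys with analytic oracles

_RADIUS_TO_ELEMENT = {round(v, 3): k for k, v in VDW_RADII.items() if k != "H"}


def _cap_buried_area(R1: float, R2: float, d: float) -> float:
    """Area of sphere 1 (radius R1) buried inside sphere 2 at distance d."""
    if d >= R1 + R2:
        return 0.0
    if d + R1 <= R2:
        return 4.0 * math.pi * R1 * R1  # fully inside
    if d + R2 <= R1:
        return 0.0  # sphere 2 fully inside sphere 1: surface 1 untouched
    x = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h = R1 - x
    return 2.0 * math.pi * R1 * h


def make_sasa_toy(
    radii: list[float],
    placements: list[tuple[float, float, float]],
    probe_radius: float = 1.4,
) -> tuple[StructureModel, dict]:
    """Up to three spheres with exact expected per-sphere SASA.

    Each sphere becomes a one-atom residue; the van der Waals radius is
    looked up by value in the bundled element table. Placements must not
    create triple overlaps (the closed forms cover pairwise caps only).
    """
    n = len(radii)
    if n < 1 or n > 3 or len(placements) != n:
        raise ValueError("supported: 1-3 spheres with matching placements")
    elements = []
    for r in radii:
        el = _RADIUS_TO_ELEMENT.get(round(r, 3))
        if el is None:
            raise ValueError(f"no element with van der Waals radius {r} "
                             f"(available: {sorted(_RADIUS_TO_ELEMENT)})")
        elements.append(el)
    centers = [np.asarray(p, dtype=float) for p in placements]
    R = [r + probe_radius for r in radii]

    # guard against triple overlap: caps on any sphere must be disjoint
    for i in range(n):
        caps = []
        for j in range(n):
            if i == j:
                continue
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d >= R[i] + R[j] or d + R[j] <= R[i]:
                continue
            if d + R[i] <= R[j]:
                caps.append((None, math.pi))  # fully buried
                continue
            x = (d * d + R[i] ** 2 - R[j] ** 2) / (2.0 * d)
            alpha = math.acos(max(-1.0, min(1.0, x / R[i])))
            caps.append(((centers[j] - centers[i]) / d, alpha))
        for a in range(len(caps)):
            for b in range(a + 1, len(caps)):
                ua, aa = caps[a]
                ub, ab = caps[b]
                if ua is None or ub is None:
                    continue
                gamma = math.acos(max(-1.0, min(1.0, float(np.dot(ua, ub)))))
                if gamma < aa + ab:
                    raise ValueError("placement creates a triple overlap; "
                                     "closed forms do not apply")

    residues = []
    expected = {}
    for i, (el, c) in enumerate(zip(elements, centers)):
        res = _res("GLY", "A", i + 1, [("C1", el, tuple(c))])
        residues.append(res)
        area = 4.0 * math.pi * R[i] ** 2
        for j in range(n):
            if j != i:
                d = float(np.linalg.norm(centers[i] - centers[j]))
                area -= _cap_buried_area(R[i], R[j], d)
        expected[res.key] = max(0.0, area)
    return _model("sasa_toy", residues), expected


# ---------------------------------------------------------------------------
# Burial dimers with prescribed region labels

def _shell_points(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _probe_ala(chain: str, seq: int, origin: np.ndarray) -> ResidueRecord:
    o = origin
    return _res("ALA", chain, seq, [
        ("N", "N", tuple(o + [1.46, 0.0, 0.0])),
        ("CA", "C", tuple(o)),
        ("C", "C", tuple(o + [-0.8, 1.2, 0.0])),
        ("O", "O", tuple(o + [-0.8, 2.43, 0.0])),
        ("CB", "C", tuple(o + [-0.8, -1.2, 0.0])),
    ])


def _occluder_residues(points: np.ndarray, chain: str, start_seq: int,
                       max_atoms: int = 40) -> list[ResidueRecord]:
    """Chunk occluder carbons into incomplete GLY residues."""
    residues = []
    seq = start_seq
    for i0 in range(0, len(points), max_atoms):
        chunk = points[i0:i0 + max_atoms]
        atoms = [(f"C{k + 1}", "C", tuple(p)) for k, p in enumerate(chunk)]
        residues.append(_res("GLY", chain, seq, atoms))
        seq += 1
    return residues


#: Shell coverage fractions per requested label: (own-chain cap, partner cap).
#: Caps are fractions of the occluder sphere around the probe; the own-chain
#: cap opens toward +z and the partner cap closes that window.
_BURIAL_RECIPES: dict[str, tuple[float, float]] = {
    "surface": (0.0, 0.0),
    "interior": (1.0, 0.0),
    "core": (0.0, 1.0),
    "support": (0.70, 0.35),
    "rim_interacting": (0.0, 0.35),
    # rim_nis is handled by a distance search for a grazing occluder
}

_SHELL_RADIUS = 5.5
_SHELL_N = 160


def make_burial_dimer(
    labels: list[str],
    thresholds: RegionThresholds = RegionThresholds(),
    n_points: int = 960,
    verify: bool = True,
) -> tuple[StructureModel, dict]:
    """Two-chain dimer whose probe residues carry the requested region labels.

    Each probe is an alanine 80 Å from its neighbors, surrounded by occluder
    shells: own-chain occluders control the monomer rASA, partner-chain
    occluders the additional burial in the complex. Returns the model and
    the map probe residue key -> expected label; when ``verify`` is set the
    labels are recomputed with the package's own SASA and must match.
    """
    from .structure_io import split_complex, standardize_residues

    valid = set(_BURIAL_RECIPES) | {"rim_nis"}
    unknown = set(labels) - valid
    if unknown:
        raise ValueError(f"unachievable labels requested: {sorted(unknown)}")

    unit = _shell_points(_SHELL_N)
    residues_a: list[ResidueRecord] = []
    residues_b: list[ResidueRecord] = []
    expected: dict = {}
    seq_a, seq_b = 1, 1

    plan: list[tuple] = []  # (probe, own_pts, partner_pts) gathered first
    for i, label in enumerate(labels):
        origin = np.array([80.0 * i, 0.0, 0.0])
        probe = _probe_ala("A", seq_a, origin)
        seq_a += 1
        own_pts = np.empty((0, 3))
        partner_pts = np.empty((0, 3))
        if label == "rim_nis":
            partner_pts = None  # resolved by search below
        else:
            own_f, partner_f = _BURIAL_RECIPES[label]
            if own_f > 0:
                sel = unit[unit[:, 2] <= (2.0 * own_f - 1.0)]
                own_pts = origin + _SHELL_RADIUS * sel
            if partner_f > 0:
                sel = unit[unit[:, 2] > (1.0 - 2.0 * partner_f)]
                partner_pts = origin + _SHELL_RADIUS * sel
        plan.append((probe, origin, own_pts, partner_pts, label))
        expected[probe.key] = label

    # resolve grazing occluders for rim_nis probes by a deterministic search
    for idx, (probe, origin, own_pts, partner_pts, label) in enumerate(plan):
        if label != "rim_nis":
            continue
        chosen = None
        for dist in np.arange(8.5, 4.9, -0.1):
            candidate = origin + np.array([0.0, 0.0, dist])
            mono = compute_sasa(_model("m", [probe]), n_points=n_points)
            both = compute_sasa(
                _model("c", [probe, _res("GLY", "B", 999, [("C1", "C", tuple(candidate))])]),
                n_points=n_points,
            )
            regions = assign_regions(
                {probe.key: mono[probe.key]},
                {probe.key: both[probe.key]},
                {probe.key: "ALA"},
                thresholds=thresholds,
            )
            if regions[probe.key].region == "rim_nis":
                chosen = candidate
                break
        if chosen is None:
            raise ValueError("rim_nis band not achievable with a single occluder")
        plan[idx] = (probe, origin, own_pts, np.array([chosen]), label)

    for probe, origin, own_pts, partner_pts, label in plan:
        residues_a.append(probe)
        if len(own_pts):
            occ = _occluder_residues(own_pts, "A", seq_a)
            residues_a.extend(occ)
            seq_a += len(occ)
        if partner_pts is not None and len(partner_pts):
            occ = _occluder_residues(partner_pts, "B", seq_b)
            residues_b.extend(occ)
            seq_b += len(occ)

    if not residues_b:  # chain B must exist even for all-surface requests
        residues_b.append(_probe_ala("B", seq_b, np.array([-80.0, 0.0, 0.0])))

    model = _model("burial_dimer", residues_a + residues_b)

    if verify:
        std = standardize_residues(model)
        mono_a, mono_b, cplx = split_complex(std, {"A"}, {"B"})
        asa_mono = {**compute_sasa(mono_a, n_points=n_points),
                    **compute_sasa(mono_b, n_points=n_points)}
        asa_cplx = compute_sasa(cplx, n_points=n_points)
        names = {r.key: r.name for r in std.residues()}
        regions = assign_regions(asa_mono, asa_cplx, names, DEFAULT_SCALES, thresholds)
        for key, want in expected.items():
            got = regions[key].region
            if got != want:
                raise AssertionError(
                    f"burial fixture self-test failed: probe {key} labelled "
                    f"{got}, wanted {want}"
                )
    return model, expected


# ---------------------------------------------------------------------------
# Interaction geometries

#: Types with an angle criterion that the negative fixtures can violate.
ANGLE_VIOLATION_TYPES = frozenset(
    {"hbond", "n_pi_star", "c_bond", "chalcogen", "h_pi", "amino_pi",
     "salt_bridge", "arg_arg_stacking"}
)

_PHE_RING = [
    ("CG", "C", (1.39, 0.0, 0.0)),
    ("CD1", "C", (0.695, 1.204, 0.0)),
    ("CD2", "C", (0.695, -1.204, 0.0)),
    ("CE1", "C", (-0.695, 1.204, 0.0)),
    ("CE2", "C", (-0.695, -1.204, 0.0)),
    ("CZ", "C", (-1.39, 0.0, 0.0)),
]

_PHE_ARM = [
    ("CB", "C", (2.4, 0.0, 0.8)),
    ("CA", "C", (3.4, 0.0, 1.5)),
    ("N", "N", (4.3, 0.8, 1.5)),
    ("C", "C", (3.9, -1.4, 1.8)),
    ("O", "O", (4.6, -2.2, 2.2)),
]


def _phe(chain: str, seq: int, shift=(0.0, 0.0, 0.0)) -> ResidueRecord:
    s = np.asarray(shift)
    atoms = [(n, e, tuple(np.asarray(p) + s)) for n, e, p in _PHE_RING + _PHE_ARM]
    return _res("PHE", chain, seq, atoms)


def _lys_above(chain: str, seq: int, nz: tuple, ce_offset=(0.0, 0.0, 1.0)) -> ResidueRecord:
    nz = np.asarray(nz)
    ce = nz + np.asarray(ce_offset)
    return _res("LYS", chain, seq, [
        ("NZ", "N", tuple(nz)),
        ("CE", "C", tuple(ce)),
        ("CD", "C", tuple(ce + [1.2, 0.0, 0.7])),
        ("CG", "C", tuple(ce + [1.2, 0.0, 2.2])),
        ("CB", "C", tuple(ce + [2.4, 0.0, 2.8])),
        ("CA", "C", tuple(ce + [2.4, 0.0, 4.3])),
        ("N", "N", tuple(ce + [3.5, 0.6, 4.7])),
        ("C", "C", tuple(ce + [1.2, -0.7, 4.9])),
        ("O", "O", tuple(ce + [1.2, -1.93, 4.9])),
    ])


def _asp_along_x(chain: str, seq: int, od1: tuple) -> ResidueRecord:
    """ASP with OD1 at the given point, the rest of the residue extending +x."""
    o = np.asarray(od1)
    return _res("ASP", chain, seq, [
        ("OD1", "O", tuple(o)),
        ("CG", "C", tuple(o + [1.3, 0.0, 0.0])),
        ("OD2", "O", tuple(o + [1.95, 1.1, 0.0])),
        ("CB", "C", tuple(o + [2.0, -1.2, 0.0])),
        ("CA", "C", tuple(o + [3.0, -2.2, 0.0])),
        ("N", "N", tuple(o + [4.0, -1.7, 0.0])),
        ("C", "C", tuple(o + [3.2, -3.7, 0.0])),
        ("O", "O", tuple(o + [4.43, -3.7, 0.0])),
    ])


def _bd_direction(angle_deg: float) -> np.ndarray:
    """Unit vector at the given angle from (-1, 0, 0), in the xy-plane."""
    a = math.radians(angle_deg)
    return np.array([-math.cos(a), math.sin(a), 0.0])


def _clash_scaffold(resname_a: str, sc_a: list, resname_b: str, sc_b: list,
                    bb_sep: float, b_side: float) -> tuple[ResidueRecord, ResidueRecord]:
    """Two residues with backbones bb_sep apart; side chains extend toward
    -y (A) and toward b_side*y (B)."""
    res_a = _res(resname_a, "A", 1, [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.46, 0.0, 0.0)),
        ("C", "C", (2.0, 1.4, 0.0)),
        ("O", "O", (3.23, 1.4, 0.0)),
    ] + sc_a)
    shift = np.array([bb_sep, 0.0, 0.0])
    atoms_b = [
        ("N", "N", tuple(shift)),
        ("CA", "C", tuple(shift + [1.46, 0.0, 0.0])),
        ("C", "C", tuple(shift + [2.0, 1.4, 0.0])),
        ("O", "O", tuple(shift + [3.23, 1.4, 0.0])),
    ]
    for n, e, p in sc_b:
        p = np.asarray(p)
        atoms_b.append((n, e, tuple(shift + [p[0], b_side * p[1], p[2]])))
    return res_a, _res(resname_b, "B", 1, atoms_b)


_GLU_SC = [
    ("CB", "C", (0.5, -1.4, 0.0)),
    ("CG", "C", (0.5, -2.9, 0.0)),
    ("CD", "C", (0.5, -4.4, 0.0)),
    ("OE1", "O", (1.5, -5.2, 0.0)),
    ("OE2", "O", (-0.5, -5.2, 0.0)),
]
_ASP_SC = [
    ("CB", "C", (0.5, -1.4, 0.0)),
    ("CG", "C", (0.5, -2.9, 0.0)),
    ("OD1", "O", (1.5, -3.7, 0.0)),
    ("OD2", "O", (-0.5, -3.7, 0.0)),
]
_LEU_SC = [
    ("CB", "C", (0.5, -1.4, 0.0)),
    ("CG", "C", (0.5, -2.9, 0.0)),
    ("CD1", "C", (1.5, -3.7, 0.0)),
    ("CD2", "C", (-0.5, -3.7, 0.0)),
]
_ASN_SC = [
    ("CB", "C", (0.5, -1.4, 0.0)),
    ("CG", "C", (0.5, -2.9, 0.0)),
    ("OD1", "O", (1.5, -3.6, 0.0)),
    ("ND2", "N", (-0.5, -3.6, 0.0)),
]


def _arg(chain: str, seq: int, shift=(0.0, 0.0, 0.0), tilt_deg: float = 0.0) -> ResidueRecord:
    """Arginine with its guanidinium plane centered near the origin (+shift);
    tilt rotates the plane about the x-axis."""
    s = np.asarray(shift)
    local = {
        "CZ": (0.0, 0.0, 0.0), "NH1": (1.33, 0.0, 0.0),
        "NH2": (-0.665, 1.15, 0.0), "NE": (-0.665, -1.15, 0.0),
        "CD": (-1.865, -2.05, 0.0), "CG": (-2.6, -1.0, 0.0),
        "CB": (-3.6, -1.9, 0.0), "CA": (-3.8, -1.5, 1.2),
        "N": (-4.6, -0.5, 1.4), "C": (-4.3, -2.8, 1.6), "O": (-5.2, -3.0, 2.4),
    }
    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0],
                    [0, math.cos(t), -math.sin(t)],
                    [0, math.sin(t), math.cos(t)]])
    atoms = []
    for n, p in local.items():
        el = "N" if n.startswith(("N",)) else "C" if n != "O" else "O"
        atoms.append((n, el, tuple(rot @ np.asarray(p, dtype=float) + s)))
    return _res("ARG", chain, seq, atoms)


def make_interaction_geometry(
    itype: str,
    positive: bool = True,
    margin: float = 0.5,
    violate: str = "distance",
    cfg: GeometryConfig = DEFAULT_GEOMETRY,
    self_test: bool = True,
) -> StructureModel:
    """Two-residue model satisfying (or violating by ``margin``) one detector.

    Positive fixtures meet the detector's criteria with the given margin;
    negative fixtures break exactly one criterion — the distance by default,
    or the angle for ``violate="angle"`` where the type has one. The fixture
    is validated at build time against the detector itself.
    """
    if itype not in INTERACTION_TYPES:
        raise ValueError(f"unknown interaction type {itype!r}")
    if not positive and violate == "angle" and itype not in ANGLE_VIOLATION_TYPES:
        raise ValueError(f"{itype} has no angle criterion to violate")

    res_a: ResidueRecord
    res_b: ResidueRecord

    if itype == "hbond":
        d = cfg.d_hb - margin if positive else cfg.d_hb + margin
        res_a = _res("SER", "A", 1, [
            ("CB", "C", (0.0, 0.0, 0.0)), ("OG", "O", (1.42, 0.0, 0.0)),
            ("CA", "C", (-1.5, 0.0, 0.0)), ("N", "N", (-2.0, 1.3, 0.0)),
            ("C", "C", (-2.3, -1.2, 0.0)), ("O", "O", (-3.5, -1.2, 0.0)),
        ])
        if positive or violate == "distance":
            od1 = (1.42 + d, 0.0, 0.0)
        else:  # compliant distance, angle at the idealized H far below a_hb
            od1 = (1.42, cfg.d_hb - margin, 0.0)
        res_b = _asp_along_x("B", 1, od1)

    elif itype == "sse_hbond":
        d = cfg.d_sse_hb - margin if positive else cfg.d_sse_hb + margin
        res_a = _res("ALA", "A", 1, [
            ("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (0.0, -1.46, 0.0)),
            ("C", "C", (1.3, -2.26, 0.0)), ("O", "O", (2.53, -2.26, 0.0)),
            ("CB", "C", (-1.3, -2.26, 0.0)),
        ])
        res_b = _res("MET", "B", 1, [
            ("SD", "S", (0.0, d, 0.0)),
            ("CG", "C", (1.7, d + 0.5, 0.0)), ("CE", "C", (-1.7, d + 0.5, 0.0)),
            ("CB", "C", (2.5, d + 1.9, 0.0)),
            ("CA", "C", (1.5, d + 3.0, 0.0)), ("N", "N", (2.5, d + 3.5, 0.0)),
            ("C", "C", (0.8, d + 4.0, 0.0)), ("O", "O", (0.8, d + 5.23, 0.0)),
        ])

    elif itype == "h_pi":
        res_b = _phe("B", 1)
        if positive:
            h_dist = cfg.d_hpi - margin  # H sits h_dist above the centroid
            res_a = _lys_above("A", 1, (0.0, 0.0, h_dist + 1.0))
        elif violate == "distance":
            h_dist = cfg.d_hpi + margin
            res_a = _lys_above("A", 1, (0.0, 0.0, h_dist + 1.0))
        else:  # inside d_hpi but 60 deg off the ring normal
            ang = math.radians(cfg.a_hpi_cone + 15.0)
            h = (cfg.d_hpi - margin) * np.array([math.sin(ang), 0.0, math.cos(ang)])
            res_a = _lys_above("A", 1, tuple(h + [0.0, 0.0, 1.0]))

    elif itype == "n_pi_star":
        d = cfg.d_npi - 0.3 if positive else (
            cfg.d_npi + margin if violate == "distance" else cfg.d_npi - 0.3)
        approach = 105.0 if (positive or violate == "distance") else 60.0
        res_a = _res("GLY", "A", 1, [
            ("O", "O", (0.0, 0.0, 0.0)), ("C", "C", (0.0, -1.23, 0.0)),
            ("CA", "C", (-1.4, -1.9, 0.0)), ("N", "N", (-2.5, -1.2, 0.0)),
        ])
        u = _bd_direction(approach)
        o_j = np.array([d, 0.0, 0.0]) + 1.23 * u
        res_b = _res("GLY", "B", 1, [
            ("C", "C", (d, 0.0, 0.0)), ("O", "O", tuple(o_j)),
            ("CA", "C", (d + 0.6, -1.5, 0.0)), ("N", "N", (d + 1.8, -2.3, 0.0)),
        ])

    elif itype == "c_bond":
        d = cfg.d_cb - 0.3 if positive else (
            cfg.d_cb + margin if violate == "distance" else cfg.d_cb - 0.3)
        res_a = _res("GLY", "A", 1, [
            ("O", "O", (0.0, 0.0, 0.0)), ("C", "C", (0.0, -1.23, 0.0)),
            ("CA", "C", (-1.4, -1.9, 0.0)), ("N", "N", (-2.6, -1.2, 0.0)),
        ])
        if positive or violate == "distance":
            ca_b = (0.0, 0.0, d + 1.54)  # antecedent-C...O angle 180
        else:
            ca_b = (1.54, 0.0, d)  # 90 deg, below the sigma-hole window
        ca_b = np.asarray(ca_b)
        res_b = _res("ALA", "B", 1, [
            ("CB", "C", (0.0, 0.0, d)), ("CA", "C", tuple(ca_b)),
            ("N", "N", tuple(ca_b + [0.8, 1.2, 0.6])),
            ("C", "C", tuple(ca_b + [0.9, -1.2, 0.7])),
            ("O", "O", tuple(ca_b + [2.13, -1.2, 0.7])),
        ])

    elif itype == "chalcogen":
        d = cfg.d_ch - 0.3 if positive else (
            cfg.d_ch + margin if violate == "distance" else cfg.d_ch - 0.3)
        res_a = _res("MET", "A", 1, [
            ("CG", "C", (0.0, 0.0, 0.0)), ("SD", "S", (1.81, 0.0, 0.0)),
            ("CE", "C", (2.71, 1.55, 0.0)), ("CB", "C", (-0.8, 1.3, 0.0)),
            ("CA", "C", (-1.6, 2.5, 0.0)), ("N", "N", (-2.9, 2.2, 0.0)),
            ("C", "C", (-1.5, 3.6, 0.5)), ("O", "O", (-1.5, 4.8, 0.3)),
        ])
        if positive or violate == "distance":
            od1 = (1.81 + d, 0.0, 0.0)  # along the CG-SD extension
        else:
            od1 = (1.81, 0.0, d)  # out of plane: 90 deg off both sigma-hole axes
        res_b = _asp_along_x("B", 1, od1)

    elif itype == "aromatic_aromatic":
        res_a = _phe("A", 1)
        z = 3.8 if positive else cfg.d_aa + margin
        res_b = _phe("B", 1, shift=(0.0, 0.0, z))
        # push the second arm to the other side to keep backbones apart
        res_b = _res("PHE", "B", 1, [
            (n, e, (-p[0], p[1], p[2] + z)) for n, e, p in _PHE_RING + _PHE_ARM
        ])

    elif itype == "amino_pi":
        res_b = _phe("B", 1)
        if positive:
            nd2 = np.array([0.0, 0.0, cfg.d_ap - margin])
        elif violate == "distance":
            nd2 = np.array([0.0, 0.0, cfg.d_ap + margin])
        else:
            ang = math.radians(cfg.a_pi_cone + 15.0)
            nd2 = (cfg.d_ap - margin) * np.array([math.sin(ang), 0.0, math.cos(ang)])
        res_a = _res("ASN", "A", 1, [
            ("ND2", "N", tuple(nd2)),
            ("CG", "C", tuple(nd2 + [1.0, 0.9, 0.3])),
            ("OD1", "O", tuple(nd2 + [2.2, 0.9, 0.0])),
            ("CB", "C", tuple(nd2 + [1.2, 2.1, 1.1])),
            ("CA", "C", tuple(nd2 + [1.2, 3.0, 2.2])),
            ("N", "N", tuple(nd2 + [2.2, 3.7, 2.2])),
            ("C", "C", tuple(nd2 + [0.2, 3.9, 2.6])),
            ("O", "O", tuple(nd2 + [0.2, 5.1, 2.6])),
        ])

    elif itype == "aromatic_sse":
        res_b = _phe("B", 1)
        r = cfg.d_asse - margin if positive else cfg.d_asse + margin
        ang = math.radians(15.0)
        sg = r * np.array([math.sin(ang), 0.0, math.cos(ang)])
        res_a = _res("CYS", "A", 1, [
            ("SG", "S", tuple(sg)),
            ("CB", "C", tuple(sg + [1.8, 0.0, 0.2])),
            ("CA", "C", tuple(sg + [2.4, 1.2, 0.9])),
            ("N", "N", tuple(sg + [3.4, 1.8, 0.7])),
            ("C", "C", tuple(sg + [1.7, 1.5, 2.1])),
            ("O", "O", tuple(sg + [2.2, 1.0, 3.1])),
        ])

    elif itype in {"aromatic_cation", "aromatic_anion"}:
        res_b = _phe("B", 1)
        r = 4.0 if positive else cfg.d_ac + margin
        if itype == "aromatic_cation":
            res_a = _lys_above("A", 1, (0.0, 0.0, r))
        else:
            mid = np.array([0.0, 0.0, r])
            res_a = _res("GLU", "A", 1, [
                ("OE1", "O", tuple(mid + [1.09, 0.0, 0.0])),
                ("OE2", "O", tuple(mid + [-1.09, 0.0, 0.0])),
                ("CD", "C", tuple(mid + [0.0, 0.62, 0.0])),
                ("CG", "C", tuple(mid + [0.0, 2.14, 0.0])),
                ("CB", "C", tuple(mid + [1.2, 2.9, 0.0])),
                ("CA", "C", tuple(mid + [1.2, 4.4, 0.0])),
                ("N", "N", tuple(mid + [2.3, 5.0, 0.0])),
                ("C", "C", tuple(mid + [0.0, 5.2, 0.3])),
                ("O", "O", tuple(mid + [0.0, 6.43, 0.3])),
            ])

    elif itype == "salt_bridge":
        res_a = _arg("A", 1)
        if positive:
            # 0.1 off the plain H-bond cutoff so its record does not flicker
            od1 = (1.33 + cfg.d_sb - margin - 0.1, 0.0, 0.0)
        elif violate == "distance":
            od1 = (1.33 + cfg.d_sb + margin, 0.0, 0.0)
        else:  # N...O compliant but perpendicular to every reconstructed H
            od1 = (1.33, cfg.d_sb - margin, 0.0)
        res_b = _asp_along_x("B", 1, od1)

    elif itype == "vdw":
        cutoff = 2 * VDW_RADII["C"] + cfg.vdw_slack
        d = cutoff - margin if positive else cutoff + margin
        def ala(chain, z):
            return _res("ALA", chain, 1, [
                ("CB", "C", (0.0, 0.0, z)), ("CA", "C", (0.0, 1.5, z)),
                ("N", "N", (1.2, 2.2, z)), ("C", "C", (-1.2, 2.3, z)),
                ("O", "O", (-1.2, 3.5, z)),
            ])
        res_a, res_b = ala("A", 0.0), ala("B", d)

    elif itype == "hydrophobic":
        # keep clear of the C-C vdW cutoff so no secondary record flickers
        d = cfg.d_hp - margin - 0.7 if positive else cfg.d_hp + margin + 1.3
        res_a = _res("LEU", "A", 1, [
            ("CD1", "C", (0.0, 0.0, 0.0)), ("CG", "C", (0.0, 1.3, 0.8)),
            ("CD2", "C", (1.3, 1.6, 0.6)), ("CB", "C", (-1.2, 2.1, 1.2)),
            ("CA", "C", (-2.4, 3.0, 1.2)), ("N", "N", (-3.5, 2.5, 1.8)),
            ("C", "C", (-2.2, 4.4, 1.8)), ("O", "O", (-2.2, 5.4, 1.1)),
        ])
        res_b = _res("ILE", "B", 1, [
            ("CD1", "C", (0.0, 0.0, d)), ("CG1", "C", (0.0, -1.2, d + 0.9)),
            ("CG2", "C", (-1.5, -1.9, d + 1.0)), ("CB", "C", (0.0, -2.5, d + 1.8)),
            ("CA", "C", (1.2, -3.4, d + 2.3)), ("N", "N", (2.3, -2.9, d + 2.9)),
            ("C", "C", (0.8, -4.6, d + 3.1)), ("O", "O", (1.5, -5.6, d + 3.0)),
        ])

    elif itype == "arg_arg_stacking":
        res_a = _arg("A", 1)
        if positive:
            res_b = _arg("B", 2, shift=(0.0, 0.0, cfg.d_rr - margin - 1.0))
        elif violate == "distance":
            res_b = _arg("B", 2, shift=(cfg.d_rr + margin, 0.0, 0.0))
        else:
            res_b = _arg("B", 2, shift=(0.0, 0.0, cfg.d_rr - margin - 1.0),
                         tilt_deg=cfg.a_rr + 30.0)

    elif itype in {"charge_clash", "charge_repulsion"}:
        if itype == "charge_clash":
            bb_sep, b_side = (5.0, 1.0) if positive else (5.0, -1.0)
            if not positive:  # side chains pulled apart -> repulsion instead
                bb_sep = 6.5
        else:
            # backbone span is 3.23 Å, so the shift must exceed d_bb by that much
            bb_sep, b_side = (6.5, -1.0) if positive else (cfg.d_bb + margin + 3.3, -1.0)
        res_a, res_b = _clash_scaffold("GLU", _GLU_SC, "ASP", _ASP_SC, bb_sep, b_side)

    elif itype in {"hydrophobic_hydrophilic_clash", "hydrophobic_hydrophilic_repulsion"}:
        if itype.endswith("_clash"):
            bb_sep, b_side = (5.0, 1.0) if positive else (6.5, -1.0)
        else:
            bb_sep, b_side = (6.5, -1.0) if positive else (cfg.d_bb + margin + 3.3, -1.0)
        res_a, res_b = _clash_scaffold("LEU", _LEU_SC, "ASN", _ASN_SC, bb_sep, b_side)

    else:  # pragma: no cover
        raise ValueError(itype)

    model = _model(f"{itype}_{'pos' if positive else 'neg'}", [res_a, res_b])
    if self_test:
        types = {r.type for r in detect_pair(res_a, res_b, cfg)}
        if positive and itype not in types:
            raise AssertionError(f"positive {itype} fixture did not fire ({types})")
        if not positive and itype in types:
            raise AssertionError(f"negative {itype} fixture fired")
    return model


# ---------------------------------------------------------------------------
# Frequency tables with known H / J / PMI

@dataclass
class FrequencyFixture:
    """Pair- and residue-class counts plus their exact expected statistics."""

    pair_counts: dict[tuple[str, str], int]
    residue_counts: dict[str, int]
    class_dist: dict[str, float]
    pair_dist: dict[tuple[str, str], float]
    expected_H: float
    expected_J: float
    expected_pmi: dict[tuple[str, str], float]


def make_frequency_fixture(
    class_dist: dict[str, float] | None = None,
    coupling: dict[tuple[str, str], float] | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> FrequencyFixture:
    """Random pair draws with an enforced co-occurrence coupling.

    Residue classes are drawn independently from ``class_dist``; unordered
    pair classes from the independent-pairing baseline with selected cells
    multiplied by their coupling factor c. The probability mass added to a
    coupled cell is removed from cells sharing no class with any coupled
    pair, which keeps the residue-class frequencies at ``class_dist`` — so
    the expected PMI of a coupled cell is exactly log2(c).
    """
    p = dict(class_dist or {c: 0.25 for c in PAIR_CLASSES_4})
    if not math.isclose(sum(p.values()), 1.0, abs_tol=1e-9):
        raise ValueError("class distribution must sum to 1")
    coupling = dict(coupling or {})
    for c in coupling.values():
        if c <= 0:
            raise ValueError("coupling factors must be positive")

    base = {}
    for a, b in ALL_PAIR_CLASSES:
        base[(a, b)] = p[a] * p[a] if a == b else 2.0 * p[a] * p[b]

    q = dict(base)
    coupled = {tuple(sorted(k)) for k in coupling}
    touched_classes = {c for k in coupled for c in k}
    added = 0.0
    for key in coupled:
        c = coupling.get(key, coupling.get((key[1], key[0])))
        q[key] = base[key] * c
        added += (c - 1.0) * base[key]
    donors = [k for k in q if not (set(k) & touched_classes)]
    donor_mass = sum(q[k] for k in donors)
    if donor_mass < added:
        raise ValueError("coupling too strong: not enough free probability mass")
    shrink = 1.0 - added / donor_mass if donor_mass > 0 else 1.0
    for k in donors:
        q[k] *= shrink

    expected_pmi = {}
    for a, b in ALL_PAIR_CLASSES:
        denom = p[a] * p[b] if a == b else 2.0 * p[a] * p[b]
        expected_pmi[(a, b)] = math.log2(q[(a, b)] / denom) if q[(a, b)] > 0 else float("-inf")

    H = -sum(v * math.log2(v) for v in q.values() if v > 0)
    k = len(ALL_PAIR_CLASSES)

    rng = np.random.default_rng(seed)
    cells = list(q)
    pair_draws = rng.multinomial(n_draws, [q[c] for c in cells])
    res_draws = rng.multinomial(n_draws, [p[c] for c in PAIR_CLASSES_4])
    return FrequencyFixture(
        pair_counts={c: int(n) for c, n in zip(cells, pair_draws)},
        residue_counts={c: int(n) for c, n in zip(PAIR_CLASSES_4, res_draws)},
        class_dist=p,
        pair_dist=q,
        expected_H=H,
        expected_J=H / math.log2(k),
        expected_pmi=expected_pmi,
    )
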