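"""Geometric detection of non-bonded residue-residue interactions.

Candidate residue pairs are those with a Cα-Cα distance of 14 Å or less.
Each candidate pair is screened by a family of detectors covering 19
reporting types of non-bonded contacts:

directional     n_pi_star, c_bond, chalcogen, sse_hbond, hbond, h_pi
aromatic        aromatic_aromatic (stacked / t_shaped / oblique), amino_pi,
                aromatic_sse, aromatic_cation, aromatic_anion
electrostatic   salt_bridge, arg_arg_stacking
packing         vdw, hydrophobic
unfavourable    charge_clash, charge_repulsion,
                hydrophobic_hydrophilic_clash, hydrophobic_hydrophilic_repulsion

All criteria are internal distances and angles, so detector output is
invariant under rigid motions. Every numeric threshold lives in
:class:`GeometryConfig` with literature-informed defaults and can be
overridden from a flat key=value config file. Distance criteria use
"less-or-equal" semantics: a geometry exactly at the cutoff fires.

Two conventions from the analysis design are enforced here: an ARG-ARG pair
whose guanidinium groups stack is excluded from the charge-clash category,
and atom pairs already explaining a directional interaction are not counted
again as van der Waals contacts.

Structure files at typical X-ray resolution lack hydrogens, so donor
hydrogens are reconstructed at ideal covalent geometry (1.0 Å along the
direction pointing away from the donor's bonded heavy atoms) for the angle
tests; a heavy-atom-only mode skips angle checks entirely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueRecord, StructureModel
from .sasa_regions import VDW_RADII
from .interface_metrics import (
    DEFAULT_CLASS_TABLE,
    canonical_name,
)

logger = logging.getLogger("ppiface")

ResidueKey = tuple[str, int, str]

INTERACTION_TYPES = (
    "n_pi_star", "c_bond", "chalcogen", "sse_hbond", "hbond", "h_pi",
    "aromatic_aromatic", "amino_pi", "aromatic_sse", "aromatic_cation",
    "aromatic_anion", "salt_bridge", "vdw", "hydrophobic", "arg_arg_stacking",
    "charge_clash", "charge_repulsion", "hydrophobic_hydrophilic_clash",
    "hydrophobic_hydrophilic_repulsion",
)

#: Reporting groups: each detector already emits one of the 19 types; the
#: table documents which finer subtypes are folded into each type.
TYPE_GROUPING: dict[str, tuple[str, ...]] = {
    "aromatic_aromatic": ("stacked", "t_shaped", "oblique"),
    "aromatic_sse": ("pi", "quadrupole"),
    "aromatic_cation": ("pi", "quadrupole"),
    "aromatic_anion": ("pi", "quadrupole"),
    "hbond": ("sidechain", "backbone"),
    "sse_hbond": ("donor", "acceptor"),
}


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class GeometryConfig:
    """All geometric thresholds (Å for distances, degrees for angles)."""

    ca_cutoff: float = 14.0            # candidate-pair Cα-Cα cutoff
    min_seq_separation: int = 2        # intra-chain neighbor exclusion
    d_hb: float = 3.5                  # H-bond donor-acceptor heavy-atom cutoff
    a_hb: float = 120.0                # minimal donor-H...acceptor angle
    d_sse_hb: float = 4.0              # H-bond cutoff when S/Se is involved
    d_hpi: float = 3.5                 # H to aromatic ring centroid
    a_hpi_cone: float = 45.0           # H-π cone half-angle around ring normal
    d_npi: float = 3.2                 # n->pi* donor O ... acceptor C
    a_npi_low: float = 95.0            # Bürgi-Dunitz approach window
    a_npi_high: float = 125.0
    d_cb: float = 3.6                  # C-bond Csp3 ... carbonyl O
    a_cb: float = 140.0                # minimal antecedent-C...O angle (σ-hole)
    d_ch: float = 3.6                  # chalcogen S/Se ... electronegative atom
    a_ch: float = 140.0                # minimal antecedent-S...A angle (σ-hole axis)
    d_aa: float = 7.0                  # aromatic ring centroid-centroid
    a_stacked: float = 30.0            # plane angle below -> stacked
    a_tshaped: float = 60.0            # plane angle above -> T-shaped
    d_ap: float = 5.5                  # amide N to ring centroid
    a_pi_cone: float = 45.0            # π-face vs quadrupole-edge discriminator
    d_asse: float = 5.5                # S/Se to ring centroid
    d_ac: float = 6.0                  # charged-group centroid to ring centroid
    d_sb: float = 4.0                  # salt-bridge N...O
    d_rr: float = 5.0                  # ARG-ARG guanidinium centroid distance
    a_rr: float = 30.0                 # guanidinium plane parallelism
    vdw_slack: float = 0.5             # r_i + r_j + slack for vdW contacts
    d_hp: float = 5.0                  # hydrophobic closest side-chain C-C
    d_bb: float = 8.0                  # clash/repulsion backbone proximity
    d_sc: float = 5.0                  # clash/repulsion side-chain proximity
    his_as_cation: bool = True         # HIS counted as cation-capable
    heavy_atom_only: bool = False      # skip angle checks (no H reconstruction)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometryConfig":
        """Read overrides from a flat ``key = value`` config file."""
        overrides = {}
        valid = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise KeyError(f"unknown geometry config key {key!r}")
            value = value.strip()
            if key in {"his_as_cation", "heavy_atom_only"}:
                overrides[key] = value.lower() in {"1", "true", "yes", "on"}
            elif key == "min_seq_separation":
                overrides[key] = int(value)
            else:
                overrides[key] = float(value)
        return replace(cls(), **overrides)


DEFAULT_GEOMETRY = GeometryConfig()


# ---------------------------------------------------------------------------
# Records

@dataclass
class InteractionRecord:
    """One detected interaction instance between two residues."""

    type: str
    subtype: str
    pair: tuple[ResidueKey, ResidueKey]
    geometry: dict[str, float]
    inter_chain: bool
    atoms: tuple[tuple[ResidueKey, str], ...] = ()


@dataclass
class PairRecord:
    """A candidate (and possibly interacting) residue pair."""

    pair: tuple[ResidueKey, ResidueKey]
    resnames: tuple[str, str]
    ca_distance: float
    inter_chain: bool
    interactions: list[InteractionRecord] = field(default_factory=list)
    regions: tuple[str, str] = ("", "")

    @property
    def pair_type(self) -> tuple[str, str]:
        return tuple(sorted(self.resnames))

    @property
    def same_region(self) -> bool:
        return self.regions[0] == self.regions[1] and self.regions[0] != ""


# ---------------------------------------------------------------------------
# Chemistry tables used by the detectors

#: Side-chain connectivity (heavy atoms), used for hydrogen reconstruction,
#: σ-hole axes and sp3-carbon antecedents.
_SIDECHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "SEC": (("CA", "CB"), ("CB", "SE")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "MSE": (("CA", "CB"), ("CB", "CG"), ("CG", "SE"), ("SE", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")),
    "GLY": (),
}

_BACKBONE_BONDS = (("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"))

#: Aromatic ring atom sets (TRP contributes both rings).
RING_ATOMS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        ("CG", "CD1", "CD2", "NE1", "CE2"),
    ),
}

#: Side-chain hydrogen-bond donors (atom names); backbone N is a donor for
#: every residue except proline.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",), "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "SEC": ("SE",),
}

#: Side-chain hydrogen-bond acceptors; backbone O / OXT accepts everywhere.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",), "CYS": ("SG",),
    "MSE": ("SE",), "SEC": ("SE",),
}

#: S/Se atoms per residue (chalcogen donors / aromatic-S partners).
SSE_ATOMS: dict[str, tuple[str, ...]] = {
    "CYS": ("SG",), "MET": ("SD",), "MSE": ("SE",), "SEC": ("SE",),
}

#: Carbonyl-type oxygen acceptors for the C-bond detector.
CARBONYL_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",), "GLN": ("OE1",),
}

#: sp2 carbons excluded from the Csp3 donor set of the C-bond detector.
_SP2_CARBONS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "ARG": frozenset({"CZ"}),
    "ASP": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
}

CATION_GROUPS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
}
ANION_GROUPS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}


def _bonded_neighbors(res: ResidueRecord, atom_name: str) -> list[np.ndarray]:
    """Positions of heavy atoms covalently bonded to ``atom_name``."""
    bonds = _SIDECHAIN_BONDS.get(canonical_name(res.name), ()) + _BACKBONE_BONDS
    out = []
    for a, b in bonds:
        other = b if a == atom_name else a if b == atom_name else None
        if other is None:
            continue
        atom = res.atom(other)
        if atom is not None:
            out.append(atom.coords)
    return out


# ---------------------------------------------------------------------------
# Geometry helpers

def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees."""
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _vec_angle(u: np.ndarray, v: np.ndarray, fold: bool = False) -> float:
    """Angle between two vectors in degrees; fold=True maps to [0, 90]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    return min(ang, 180.0 - ang) if fold else ang


def _plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a set of (near-)coplanar points (SVD)."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _rings(res: ResidueRecord) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(ring id, centroid, normal) for each complete aromatic ring."""
    out = []
    for i, names in enumerate(RING_ATOMS.get(canonical_name(res.name), ())):
        atoms = [res.atom(n) for n in names]
        if any(a is None for a in atoms):
            continue
        coords = np.array([a.coords for a in atoms])
        centroid, normal = _plane_fit(coords)
        out.append((f"ring{i}", centroid, normal))
    return out


def _donor_hydrogen(res: ResidueRecord, donor: str) -> np.ndarray | None:
    """Idealized donor hydrogen: 1.0 Å from the donor, pointing away from
    the mean direction of its bonded heavy atoms. None if no neighbor known."""
    atom = res.atom(donor)
    if atom is None:
        return None
    neighbors = _bonded_neighbors(res, donor)
    if not neighbors:
        return None
    direction = atom.coords - np.mean(neighbors, axis=0)
    norm = np.linalg.norm(direction)
    if norm == 0:
        return None
    return atom.coords + direction / norm


def _donors(res: ResidueRecord, include_backbone: bool = True):
    """(atom name, position, is S/Se) for every available H-bond donor."""
    name = canonical_name(res.name)
    out = []
    if include_backbone and name != "PRO":
        a = res.atom("N")
        if a is not None:
            out.append(("N", a.coords, False))
    for dn in SIDECHAIN_DONORS.get(name, ()):
        a = res.atom(dn)
        if a is not None:
            out.append((dn, a.coords, a.element in {"S", "SE"}))
    return out


def _acceptors(res: ResidueRecord, include_backbone: bool = True):
    name = canonical_name(res.name)
    out = []
    if include_backbone:
        for an in ("O", "OXT"):
            a = res.atom(an)
            if a is not None:
                out.append((an, a.coords, False))
    for an in SIDECHAIN_ACCEPTORS.get(name, ()):
        a = res.atom(an)
        if a is not None:
            out.append((an, a.coords, a.element in {"S", "SE"}))
    return out


def _canonical_pair(res_a: ResidueRecord, res_b: ResidueRecord):
    """Order the two residues deterministically by (chain, resnum, icode)."""
    if res_a.key <= res_b.key:
        return res_a, res_b
    return res_b, res_a


# ---------------------------------------------------------------------------
# Candidate enumeration

def enumerate_candidate_pairs(
    model: StructureModel,
    ca_cutoff: float = 14.0,
    scope: str = "inter_chain",
    min_seq_separation: int = 2,
) -> list[PairRecord]:
    """All residue pairs with Cα-Cα distance ≤ ``ca_cutoff`` ("14 Å or less").

    scope selects inter-chain pairs, intra-chain pairs, or both; intra-chain
    pairs must additionally be ≥ ``min_seq_separation`` apart in sequence.
    Residues lacking a Cα are skipped with a warning. Output order is
    deterministic (sorted by residue keys).
    """
    if scope not in {"inter_chain", "intra_chain", "both"}:
        raise ValueError("scope must be inter_chain, intra_chain or both")
    residues = []
    for res in model.residues():
        ca = res.atom("CA")
        if ca is None:
            logger.warning("residue %s %s%d has no CA; skipped from pair search",
                           res.name, res.chain_id, res.seq_number)
            continue
        residues.append((res, ca.coords))
    if len(residues) < 2:
        return []
    coords = np.array([c for _, c in residues])
    tree = cKDTree(coords)
    pairs = []
    for i, j in sorted(tree.query_pairs(ca_cutoff)):
        ri, rj = residues[i][0], residues[j][0]
        inter = ri.chain_id != rj.chain_id
        if scope == "inter_chain" and not inter:
            continue
        if scope == "intra_chain" and inter:
            continue
        if not inter and abs(ri.seq_number - rj.seq_number) < min_seq_separation:
            continue
        ra, rb = _canonical_pair(ri, rj)
        pairs.append(
            PairRecord(
                pair=(ra.key, rb.key),
                resnames=(ra.name, rb.name),
                ca_distance=_dist(coords[i], coords[j]),
                inter_chain=inter,
            )
        )
    pairs.sort(key=lambda p: p.pair)
    return pairs


# ---------------------------------------------------------------------------
# Detector families. Each takes the two residues (any order) and the config
# and returns InteractionRecords with a canonical residue ordering.

def _mk_record(itype, subtype, res_a, res_b, geometry, atoms=()):
    ra, rb = _canonical_pair(res_a, res_b)
    return InteractionRecord(
        type=itype,
        subtype=subtype,
        pair=(ra.key, rb.key),
        geometry=geometry,
        inter_chain=ra.chain_id != rb.chain_id,
        atoms=tuple(sorted(atoms)),
    )


def detect_hbond_family(res_a: ResidueRecord, res_b: ResidueRecord,
                        cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Hydrogen bonds, S/Se-mediated hydrogen bonds and H-π contacts.

    hbond: donor-acceptor heavy-atom distance ≤ d_hb and donor-H...acceptor
    angle ≥ a_hb (H idealized). sse_hbond: same template with S/Se as donor
    or acceptor and the longer d_sse_hb cutoff. h_pi: donor H within d_hpi
    of an aromatic ring centroid, inside the a_hpi_cone around the normal.
    """
    records = []
    for don_res, acc_res in ((res_a, res_b), (res_b, res_a)):
        acceptors = _acceptors(acc_res)
        rings = _rings(acc_res)
        for dname, dpos, d_sse in _donors(don_res):
            hpos = _donor_hydrogen(don_res, dname)
            for aname, apos, a_sse in acceptors:
                sse = d_sse or a_sse
                cutoff = cfg.d_sse_hb if sse else cfg.d_hb
                d = _dist(dpos, apos)
                if d > cutoff:
                    continue
                if not cfg.heavy_atom_only and hpos is not None:
                    ang = _angle(dpos, hpos, apos)
                    if ang < cfg.a_hb:
                        continue
                else:
                    ang = float("nan")
                itype = "sse_hbond" if sse else "hbond"
                subtype = ("donor" if d_sse else "acceptor") if sse else (
                    "backbone" if dname == "N" and aname in {"O", "OXT"} else "sidechain"
                )
                records.append(
                    _mk_record(itype, subtype, don_res, acc_res,
                               {"distance": d, "angle": ang},
                               atoms=((don_res.key, dname), (acc_res.key, aname)))
                )
            # H-π: donor hydrogen over an aromatic ring of the partner
            if hpos is None:
                continue
            for ring_id, centroid, normal in rings:
                d = _dist(hpos, centroid)
                if d > cfg.d_hpi:
                    continue
                cone = _vec_angle(hpos - centroid, normal, fold=True)
                if cone > cfg.a_hpi_cone:
                    continue
                records.append(
                    _mk_record("h_pi", ring_id, don_res, acc_res,
                               {"distance": d, "cone_angle": cone},
                               atoms=((don_res.key, dname), (acc_res.key, ring_id)))
                )
    return records


def detect_carbonyl_family(res_a: ResidueRecord, res_b: ResidueRecord,
                           cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Backbone n→π* contacts and C-bonds (n→σ* to a carbonyl oxygen).

    n_pi_star: donor carbonyl O within d_npi of the acceptor carbonyl C, the
    O...C=O approach angle inside the Bürgi-Dunitz window. c_bond: sp3 carbon
    within d_cb of a carbonyl O, approaching along a σ-hole axis (the
    antecedent-C...O angle ≥ a_cb).
    """
    records = []
    for don_res, acc_res in ((res_a, res_b), (res_b, res_a)):
        # n->pi*
        o_i = don_res.atom("O")
        c_j, o_j = acc_res.atom("C"), acc_res.atom("O")
        if o_i is not None and c_j is not None and o_j is not None:
            d = _dist(o_i.coords, c_j.coords)
            if d <= cfg.d_npi:
                approach = _angle(o_i.coords, c_j.coords, o_j.coords)
                if cfg.a_npi_low <= approach <= cfg.a_npi_high:
                    records.append(
                        _mk_record("n_pi_star", "backbone", don_res, acc_res,
                                   {"distance": d, "approach_angle": approach},
                                   atoms=((don_res.key, "O"), (acc_res.key, "C")))
                    )
        # C-bond: sp3 carbons of don_res vs carbonyl oxygens of acc_res
        sp2 = _SP2_CARBONS.get(canonical_name(don_res.name), frozenset())
        acc_oxygens = [("O", acc_res.atom("O"))]
        for oname in CARBONYL_OXYGENS.get(canonical_name(acc_res.name), ()):
            acc_oxygens.append((oname, acc_res.atom(oname)))
        for atom in don_res.heavy_atoms():
            if atom.element != "C" or atom.name == "C" or atom.name in sp2:
                continue
            neighbors = _bonded_neighbors(don_res, atom.name)
            for oname, oatom in acc_oxygens:
                if oatom is None:
                    continue
                d = _dist(atom.coords, oatom.coords)
                if d > cfg.d_cb:
                    continue
                if not cfg.heavy_atom_only and neighbors:
                    best = max(_angle(nb, atom.coords, oatom.coords) for nb in neighbors)
                    if best < cfg.a_cb:
                        continue
                else:
                    best = float("nan")
                records.append(
                    _mk_record("c_bond", "sigma_hole", don_res, acc_res,
                               {"distance": d, "axis_angle": best},
                               atoms=((don_res.key, atom.name), (acc_res.key, oname)))
                )
    return records


def detect_sulfur_family(res_a: ResidueRecord, res_b: ResidueRecord,
                         cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Chalcogen bonds and aromatic-S/Se contacts.

    chalcogen: S/Se within d_ch of an electronegative atom (N/O), the contact
    aligned with the extension of a covalent bond to S/Se (σ-hole axis,
    antecedent-S...A angle ≥ a_ch). aromatic_sse: S/Se within d_asse of an
    aromatic ring centroid; subtype π (face) vs quadrupole (edge) from the
    angle between the centroid→S vector and the ring normal.
    """
    records = []
    for s_res, other in ((res_a, res_b), (res_b, res_a)):
        s_names = SSE_ATOMS.get(canonical_name(s_res.name), ())
        if not s_names:
            continue
        for s_name in s_names:
            s_atom = s_res.atom(s_name)
            if s_atom is None:
                continue
            neighbors = _bonded_neighbors(s_res, s_name)
            # chalcogen bond to electronegative atoms of the partner
            for atom in other.heavy_atoms():
                if atom.element not in {"N", "O"}:
                    continue
                d = _dist(s_atom.coords, atom.coords)
                if d > cfg.d_ch:
                    continue
                if not cfg.heavy_atom_only and neighbors:
                    best = max(_angle(nb, s_atom.coords, atom.coords) for nb in neighbors)
                    if best < cfg.a_ch:
                        continue
                else:
                    best = float("nan")
                records.append(
                    _mk_record("chalcogen", "sigma_hole", s_res, other,
                               {"distance": d, "axis_angle": best},
                               atoms=((s_res.key, s_name), (other.key, atom.name)))
                )
            # aromatic-S/Se
            for ring_id, centroid, normal in _rings(other):
                d = _dist(s_atom.coords, centroid)
                if d > cfg.d_asse:
                    continue
                cone = _vec_angle(s_atom.coords - centroid, normal, fold=True)
                subtype = "pi" if cone <= cfg.a_pi_cone else "quadrupole"
                records.append(
                    _mk_record("aromatic_sse", subtype, s_res, other,
                               {"distance": d, "cone_angle": cone},
                               atoms=((s_res.key, s_name), (other.key, ring_id)))
                )
    return records


def detect_aromatic_family(res_a: ResidueRecord, res_b: ResidueRecord,
                           cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Aromatic-aromatic, amino-π and aromatic-charge contacts.

    aromatic_aromatic: ring centroids within d_aa; subtype from the
    inter-plane angle (≤ a_stacked stacked, ≥ a_tshaped T-shaped, else
    oblique). amino_pi: ASN/GLN amide nitrogen within d_ap of a centroid and
    inside the normal cone. aromatic_cation / aromatic_anion: charged-group
    centroid (ARG CZ, LYS NZ, HIS ring when cation-capable; ASP/GLU
    carboxylate midpoint) within d_ac of a ring centroid; subtype π vs
    quadrupole from the normal angle.
    """
    records = []
    rings_a, rings_b = _rings(res_a), _rings(res_b)
    # aromatic-aromatic (each ring pair once; res_a/res_b order fixed)
    for ida, ca, na in rings_a:
        for idb, cb, nb in rings_b:
            d = _dist(ca, cb)
            if d > cfg.d_aa:
                continue
            plane_angle = _vec_angle(na, nb, fold=True)
            if plane_angle <= cfg.a_stacked:
                subtype = "stacked"
            elif plane_angle >= cfg.a_tshaped:
                subtype = "t_shaped"
            else:
                subtype = "oblique"
            records.append(
                _mk_record("aromatic_aromatic", subtype, res_a, res_b,
                           {"distance": d, "plane_angle": plane_angle},
                           atoms=((res_a.key, ida), (res_b.key, idb)))
            )
    for part_res, arom_res, rings in (
        (res_a, res_b, rings_b),
        (res_b, res_a, rings_a),
    ):
        name = canonical_name(part_res.name)
        # amino-π
        amide = {"ASN": "ND2", "GLN": "NE2"}.get(name)
        if amide is not None:
            atom = part_res.atom(amide)
            if atom is not None:
                for ring_id, centroid, normal in rings:
                    d = _dist(atom.coords, centroid)
                    if d > cfg.d_ap:
                        continue
                    cone = _vec_angle(atom.coords - centroid, normal, fold=True)
                    if cone > cfg.a_pi_cone:
                        continue
                    records.append(
                        _mk_record("amino_pi", "pi", part_res, arom_res,
                                   {"distance": d, "cone_angle": cone},
                                   atoms=((part_res.key, amide), (arom_res.key, ring_id)))
                    )
        # aromatic-cation / aromatic-anion
        charge_center = None
        itype = None
        if name == "ARG":
            a = part_res.atom("CZ")
            charge_center, itype = (a.coords if a else None), "aromatic_cation"
        elif name == "LYS":
            a = part_res.atom("NZ")
            charge_center, itype = (a.coords if a else None), "aromatic_cation"
        elif name == "HIS" and cfg.his_as_cation:
            his_rings = _rings(part_res)
            if his_rings:
                charge_center, itype = his_rings[0][1], "aromatic_cation"
        elif name in ANION_GROUPS:
            atoms = [part_res.atom(n) for n in ANION_GROUPS[name]]
            if all(a is not None for a in atoms):
                charge_center = np.mean([a.coords for a in atoms], axis=0)
                itype = "aromatic_anion"
        if charge_center is None:
            continue
        for ring_id, centroid, normal in rings:
            d = _dist(charge_center, centroid)
            if d > cfg.d_ac:
                continue
            cone = _vec_angle(charge_center - centroid, normal, fold=True)
            subtype = "pi" if cone <= cfg.a_pi_cone else "quadrupole"
            records.append(
                _mk_record(itype, subtype, part_res, arom_res,
                           {"distance": d, "cone_angle": cone},
                           atoms=((part_res.key, "charge_center"), (arom_res.key, ring_id)))
            )
    return records


def detect_arg_arg_stacking(res_a: ResidueRecord, res_b: ResidueRecord,
                            cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Parallel stacking of two arginine guanidinium planes.

    Fires when the guanidinium centroids (NE, CZ, NH1, NH2) are within d_rr
    and the planes are parallel within a_rr. A firing pair is excluded from
    the charge-clash category downstream.
    """
    if canonical_name(res_a.name) != "ARG" or canonical_name(res_b.name) != "ARG":
        return []
    planes = []
    for res in (res_a, res_b):
        atoms = [res.atom(n) for n in ("NE", "CZ", "NH1", "NH2")]
        if any(a is None for a in atoms):
            return []
        planes.append(_plane_fit(np.array([a.coords for a in atoms])))
    (ca, na), (cb, nb) = planes
    d = _dist(ca, cb)
    if d > cfg.d_rr:
        return []
    tilt = _vec_angle(na, nb, fold=True)
    if tilt > cfg.a_rr:
        return []
    return [
        _mk_record("arg_arg_stacking", "parallel", res_a, res_b,
                   {"distance": d, "plane_angle": tilt},
                   atoms=((res_a.key, "guanidinium"), (res_b.key, "guanidinium")))
    ]


def detect_salt_bridge(res_a: ResidueRecord, res_b: ResidueRecord,
                       cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Salt bridge: ionic bond plus hydrogen bond between opposite charges.

    Requires a cation-group nitrogen within d_sb of an anion-group oxygen
    AND a compliant hydrogen-bond geometry (idealized donor H, angle ≥ a_hb)
    between the same groups. Records the minimal N...O distance.
    """
    def groups(res):
        name = canonical_name(res.name)
        cations = CATION_GROUPS if cfg.his_as_cation else {
            k: v for k, v in CATION_GROUPS.items() if k != "HIS"
        }
        if name in cations:
            return "cation", CATION_GROUPS[name]
        if name in ANION_GROUPS:
            return "anion", ANION_GROUPS[name]
        return None, ()

    kind_a, atoms_a = groups(res_a)
    kind_b, atoms_b = groups(res_b)
    if {kind_a, kind_b} != {"cation", "anion"}:
        return []
    cat_res, cat_atoms = (res_a, atoms_a) if kind_a == "cation" else (res_b, atoms_b)
    an_res, an_atoms = (res_b, atoms_b) if kind_a == "cation" else (res_a, atoms_a)

    best = None
    for n_name in cat_atoms:
        n_atom = cat_res.atom(n_name)
        if n_atom is None:
            continue
        hpos = _donor_hydrogen(cat_res, n_name)
        for o_name in an_atoms:
            o_atom = an_res.atom(o_name)
            if o_atom is None:
                continue
            d = _dist(n_atom.coords, o_atom.coords)
            if d > cfg.d_sb:
                continue
            if not cfg.heavy_atom_only and hpos is not None:
                if _angle(n_atom.coords, hpos, o_atom.coords) < cfg.a_hb:
                    continue
            if best is None or d < best[0]:
                best = (d, n_name, o_name)
    if best is None:
        return []
    d, n_name, o_name = best
    return [
        _mk_record("salt_bridge", "nh_o", cat_res, an_res,
                   {"distance": d},
                   atoms=((cat_res.key, n_name), (an_res.key, o_name)))
    ]


def detect_packing_family(res_a: ResidueRecord, res_b: ResidueRecord,
                          cfg: GeometryConfig = DEFAULT_GEOMETRY,
                          used_atom_pairs: set | None = None) -> list[InteractionRecord]:
    """Van der Waals contacts and the hydrophobic contact flag.

    vdw: one record per heavy-atom pair with distance ≤ r_i + r_j + slack
    that is not already part of a directional interaction between the same
    atoms. hydrophobic: fires once when both residues are hydrophobic-class
    and their closest side-chain carbon-carbon distance ≤ d_hp.
    """
    used = used_atom_pairs or set()
    records = []
    for atom_i in res_a.heavy_atoms():
        ri = VDW_RADII.get(atom_i.element)
        if ri is None:
            continue
        for atom_j in res_b.heavy_atoms():
            rj = VDW_RADII.get(atom_j.element)
            if rj is None:
                continue
            pair_key = frozenset(((res_a.key, atom_i.name), (res_b.key, atom_j.name)))
            if pair_key in used:
                continue
            d = _dist(atom_i.coords, atom_j.coords)
            if d <= ri + rj + cfg.vdw_slack:
                records.append(
                    _mk_record("vdw", "dispersion", res_a, res_b, {"distance": d},
                               atoms=((res_a.key, atom_i.name), (res_b.key, atom_j.name)))
                )
    table = DEFAULT_CLASS_TABLE
    if (table.hydropathy.get(canonical_name(res_a.name)) == "hydrophobic"
            and table.hydropathy.get(canonical_name(res_b.name)) == "hydrophobic"):
        sc_a = [a.coords for a in res_a.heavy_atoms()
                if a.element == "C" and not a.is_backbone and a.name != "CA"]
        sc_b = [a.coords for a in res_b.heavy_atoms()
                if a.element == "C" and not a.is_backbone and a.name != "CA"]
        if sc_a and sc_b:
            dmin = min(_dist(x, y) for x in sc_a for y in sc_b)
            if dmin <= cfg.d_hp:
                records.append(
                    _mk_record("hydrophobic", "contact", res_a, res_b, {"distance": dmin})
                )
    return records


def detect_clash_repulsion(res_a: ResidueRecord, res_b: ResidueRecord,
                           cfg: GeometryConfig = DEFAULT_GEOMETRY,
                           arg_arg_stacked: bool = False) -> list[InteractionRecord]:
    """Like-charge and hydrophobe-hydrophile clash vs repulsion.

    A pair qualifies when both residues carry the same charge sign, or when
    one is hydrophobic-class and the other hydrophilic-class. With minimum
    backbone-atom distance ≤ d_bb: side chains within d_sc → clash; side
    chains farther → repulsion. Glycine (no side chain) is skipped with a
    warning. ARG-ARG pairs whose guanidinium groups stack are excluded from
    the charge categories.
    """
    table = DEFAULT_CLASS_TABLE
    name_a, name_b = canonical_name(res_a.name), canonical_name(res_b.name)
    cations = {"ARG", "LYS"} | ({"HIS"} if cfg.his_as_cation else set())
    anions = {"ASP", "GLU"}
    like_charge = (name_a in cations and name_b in cations) or (
        name_a in anions and name_b in anions
    )
    hh = {table.hydropathy.get(name_a), table.hydropathy.get(name_b)} == {
        "hydrophobic", "hydrophilic"
    }
    if not like_charge and not hh:
        return []
    if like_charge and arg_arg_stacked:
        like_charge = False
        if not hh:
            return []
    if "GLY" in (name_a, name_b):
        logger.warning("clash/repulsion skipped for glycine pair %s-%s",
                       res_a.key, res_b.key)
        return []
    bb_a = [a.coords for a in res_a.heavy_atoms() if a.is_backbone]
    bb_b = [a.coords for a in res_b.heavy_atoms() if a.is_backbone]
    sc_a = [a.coords for a in res_a.heavy_atoms() if not a.is_backbone]
    sc_b = [a.coords for a in res_b.heavy_atoms() if not a.is_backbone]
    if not (bb_a and bb_b and sc_a and sc_b):
        return []
    min_bb = min(_dist(x, y) for x in bb_a for y in bb_b)
    if min_bb > cfg.d_bb:
        return []
    min_sc = min(_dist(x, y) for x in sc_a for y in sc_b)
    flavor = "clash" if min_sc <= cfg.d_sc else "repulsion"
    base = "charge" if like_charge else "hydrophobic_hydrophilic"
    itype = f"{base}_{flavor}"
    return [
        _mk_record(itype, base, res_a, res_b,
                   {"backbone_distance": min_bb, "sidechain_distance": min_sc})
    ]


#: Directional types whose atom pairs are withheld from vdW double-counting.
_DIRECTIONAL = frozenset(
    {"hbond", "sse_hbond", "salt_bridge", "chalcogen", "c_bond", "n_pi_star"}
)


def detect_pair(res_a: ResidueRecord, res_b: ResidueRecord,
                cfg: GeometryConfig = DEFAULT_GEOMETRY) -> list[InteractionRecord]:
    """Run every detector on one residue pair; records carry canonical order."""
    records: list[InteractionRecord] = []
    records += detect_hbond_family(res_a, res_b, cfg)
    records += detect_carbonyl_family(res_a, res_b, cfg)
    records += detect_sulfur_family(res_a, res_b, cfg)
    records += detect_aromatic_family(res_a, res_b, cfg)
    stacking = detect_arg_arg_stacking(res_a, res_b, cfg)
    records += stacking
    records += detect_salt_bridge(res_a, res_b, cfg)
    used = {frozenset(r.atoms) for r in records if r.type in _DIRECTIONAL}
    records += detect_packing_family(res_a, res_b, cfg, used_atom_pairs=used)
    records += detect_clash_repulsion(res_a, res_b, cfg,
                                      arg_arg_stacked=bool(stacking))
    return records


@dataclass
class DetectionResult:
    records: list[InteractionRecord]
    pairs: list[PairRecord]          # pairs with >= 1 interaction
    candidates: list[PairRecord]     # every candidate pair (denominators)


def detect_all(
    model: StructureModel,
    regions: dict[ResidueKey, object] | None = None,
    cfg: GeometryConfig = DEFAULT_GEOMETRY,
    scope: str = "inter_chain",
) -> DetectionResult:
    """Detect every interaction over all candidate pairs of a model.

    ``regions`` (residue key -> RegionAssignment) annotates each pair with
    its region labels when provided. Interacting PairRecords materialize only
    pairs with at least one record.
    """
    res_map = model.residue_map()
    candidates = enumerate_candidate_pairs(
        model, ca_cutoff=cfg.ca_cutoff, scope=scope,
        min_seq_separation=cfg.min_seq_separation,
    )
    all_records: list[InteractionRecord] = []
    interacting: list[PairRecord] = []
    for pair in candidates:
        res_a, res_b = res_map[pair.pair[0]], res_map[pair.pair[1]]
        recs = detect_pair(res_a, res_b, cfg)
        if regions is not None:
            pair.regions = (
                regions[pair.pair[0]].region if pair.pair[0] in regions else "",
                regions[pair.pair[1]].region if pair.pair[1] in regions else "",
            )
        if recs:
            pair.interactions = recs
            all_records.extend(recs)
            interacting.append(pair)
    return DetectionResult(records=all_records, pairs=interacting, candidates=candidates)


def interaction_table(result: DetectionResult, structure_id: str = ""):
    """Detected interactions as a tidy DataFrame (TSV-ready)."""
    import pandas as pd

    region_of = {p.pair: p.regions for p in result.pairs}
    rows = []
    for rec in result.records:
        (ca, na, ia), (cb, nb, ib) = rec.pair
        ra, rb = region_of.get(rec.pair, ("", ""))
        row = {
            "structure_id": structure_id,
            "type": rec.type,
            "subtype": rec.subtype,
            "chainA": ca, "resA": na, "icodeA": ia,
            "chainB": cb, "resB": nb, "icodeB": ib,
            "regionA": ra, "regionB": rb,
            "same_region": ra == rb and ra != "",
            "inter_chain": rec.inter_chain,
        }
        for k, v in sorted(rec.geometry.items()):
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
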