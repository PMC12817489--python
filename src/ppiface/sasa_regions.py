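"""Solvent accessibility, interface regionalization and buried surface area.

Per-residue solvent-accessible surface area (SASA) is computed with
Shrake–Rupley sphere sampling (probe 1.4 Å, 960 quadrature points per atom by
default, Bondi van der Waals radii). Relative accessibility

    rASA = ASA / MaxASA,    ΔrASA = rASA(monomer) − rASA(complex)

drives the region assignment: a residue is part of the interface when its
accessibility drops on binding (ΔrASA > 0). Interface residues split into

* core     — exposed in the monomer (rASA > 25%), buried in the complex,
* support  — already buried in the monomer (rASA < 25%), buried further,
* rim      — exposed before and after; the rim subset with ΔrASA ≤ 5% is the
  non-interacting surface (rim-NIS), the rest is the interacting rim.

Non-interface residues are interior (buried) or surface (exposed). The final
label is a majority vote over several MaxASA normalization scales, with a
fixed priority order breaking ties (the more-buried label wins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel

ResidueKey = tuple[str, int, str]

# ---------------------------------------------------------------------------
# Radii and MaxASA scales

#: Bondi van der Waals radii (Å) by element.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "SE": 1.90, "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class MaxAsaScale:
    """Maximum attainable ASA per residue type (Å²), from Gly-X-Gly peptides."""

    scale_name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = {
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL",
        } - set(self.values)
        if missing:
            raise ValueError(f"scale {self.scale_name} missing residues: {sorted(missing)}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError(f"scale {self.scale_name} has non-positive values")

    def max_asa(self, resname: str) -> float:
        # Selenium variants normalized by their sulfur analogues.
        resname = {"MSE": "MET", "SEC": "CYS"}.get(resname, resname)
        if resname not in self.values:
            raise KeyError(f"residue {resname} not in MaxASA scale {self.scale_name}")
        return self.values[resname]


#: Theoretical maxima from systematic conformer enumeration.
TIEN_THEORETICAL = MaxAsaScale(
    "tien_theoretical",
    {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
        "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
        "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
        "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
)

#: Empirical maxima observed in folded structures (Tien et al. style).
TIEN_EMPIRICAL = MaxAsaScale(
    "tien_empirical",
    {
        "ALA": 121.0, "ARG": 265.0, "ASN": 187.0, "ASP": 187.0, "CYS": 148.0,
        "GLN": 214.0, "GLU": 214.0, "GLY": 97.0, "HIS": 216.0, "ILE": 195.0,
        "LEU": 191.0, "LYS": 230.0, "MET": 203.0, "PHE": 228.0, "PRO": 154.0,
        "SER": 143.0, "THR": 163.0, "TRP": 264.0, "TYR": 255.0, "VAL": 165.0,
    },
)

#: Classic empirical Gly-X-Gly values (Miller et al. style).
MILLER_EMPIRICAL = MaxAsaScale(
    "miller_empirical",
    {
        "ALA": 113.0, "ARG": 241.0, "ASN": 158.0, "ASP": 151.0, "CYS": 140.0,
        "GLN": 189.0, "GLU": 183.0, "GLY": 85.0, "HIS": 194.0, "ILE": 182.0,
        "LEU": 180.0, "LYS": 211.0, "MET": 204.0, "PHE": 218.0, "PRO": 143.0,
        "SER": 122.0, "THR": 146.0, "TRP": 259.0, "TYR": 229.0, "VAL": 160.0,
    },
)

DEFAULT_SCALES: tuple[MaxAsaScale, ...] = (
    TIEN_THEORETICAL,
    TIEN_EMPIRICAL,
    MILLER_EMPIRICAL,
)

# ---------------------------------------------------------------------------
# Region labels and thresholds

REGION_LABELS = ("interior", "surface", "core", "support", "rim_interacting", "rim_nis")
INTERFACE_REGIONS = ("core", "support", "rim_interacting", "rim_nis")

#: Tie-break priority for the consensus vote: the more-buried label wins.
REGION_PRIORITY = ("core", "support", "rim_interacting", "rim_nis", "surface", "interior")


@dataclass(frozen=True)
class RegionThresholds:
    """rASA thresholds for region assignment (fractions, not percent)."""

    rasa_cut: float = 0.25
    nis_cut: float = 0.05
    interface_eps: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.nis_cut < self.rasa_cut < 1.0:
            raise ValueError("require 0 < nis_cut < rasa_cut < 1")


@dataclass
class RegionAssignment:
    """Per-residue accessibility and region label under every scale."""

    key: ResidueKey
    resname: str
    asa_monomer: float
    asa_complex: float
    rasa_monomer: float
    rasa_complex: float
    delta_rasa: float
    region_by_scale: dict[str, str]
    region: str


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[ResidueKey, float]:
    """Per-residue SASA (Å²) by Shrake–Rupley sampling over heavy atoms.

    Deterministic for a fixed quadrature. Hydrogens present in the model are
    ignored (radii are for heavy atoms; X-ray inputs rarely carry H).
    """
    atoms: list[tuple[ResidueKey, np.ndarray, float]] = []
    for res in model.residues():
        for a in res.heavy_atoms():
            radius = VDW_RADII.get(a.element)
            if radius is None:
                raise ValueError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.name} in {res.name} {res.chain_id}{res.seq_number})"
                )
            atoms.append((res.key, a.coords, radius))
    if not atoms:
        return {}

    coords = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms]) + probe_radius
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    max_r = radii.max()

    per_res: dict[ResidueKey, float] = {res.key: 0.0 for res in model.residues()}
    for i, (key, center, _) in enumerate(atoms):
        ri = radii[i]
        neighbors = [j for j in tree.query_ball_point(center, ri + max_r) if j != i]
        pts = center + ri * unit
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r2 = radii[neighbors] ** 2
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= nb_r2[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_res[key] += 4.0 * math.pi * ri * ri * frac
    return per_res


# ---------------------------------------------------------------------------
# rASA and region rules

def compute_rasa(asa: float, residue_name: str, scale: MaxAsaScale) -> float:
    """Relative accessibility ASA / MaxASA. Values > 1 are kept unclamped."""
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return asa / scale.max_asa(residue_name)


def assign_region(
    rasa_monomer: float,
    rasa_complex: float,
    thresholds: RegionThresholds = RegionThresholds(),
) -> str:
    """Region label from monomer/complex rASA.

    Residues whose accessibility does not drop on binding are interior or
    surface; interface residues are split into support / core / rim by the
    25% rule, and the rim into NIS vs interacting by the 5% ΔrASA rule.
    A residue sitting exactly at the 25% cut on both sides falls into rim.
    """
    if rasa_monomer < 0 or rasa_complex < 0:
        raise ValueError("rASA values must be non-negative")
    t = thresholds
    delta = rasa_monomer - rasa_complex
    if delta <= t.interface_eps:
        return "interior" if rasa_monomer < t.rasa_cut else "surface"
    if rasa_monomer < t.rasa_cut:
        return "support"
    if rasa_monomer > t.rasa_cut and rasa_complex < t.rasa_cut:
        return "core"
    return "rim_nis" if delta <= t.nis_cut + t.interface_eps else "rim_interacting"


def assign_region_consensus(region_by_scale: dict[str, str]) -> str:
    """Majority vote over scales; ties broken by the fixed priority order."""
    if not region_by_scale:
        raise ValueError("no region labels to vote over")
    counts = Counter(region_by_scale.values())
    best = max(counts.values())
    tied = [label for label, c in counts.items() if c == best]
    return min(tied, key=REGION_PRIORITY.index)


def assign_regions(
    asa_monomer: dict[ResidueKey, float],
    asa_complex: dict[ResidueKey, float],
    residue_names: dict[ResidueKey, str],
    scales: tuple[MaxAsaScale, ...] = DEFAULT_SCALES,
    thresholds: RegionThresholds = RegionThresholds(),
) -> dict[ResidueKey, RegionAssignment]:
    """Full per-residue region table over a set of MaxASA scales.

    The reported rASA / ΔrASA values use the first scale in ``scales``; the
    consensus label votes over all of them.
    """
    if set(asa_monomer) != set(asa_complex):
        raise ValueError("monomer/complex ASA maps must share residue keys")
    out: dict[ResidueKey, RegionAssignment] = {}
    primary = scales[0]
    for key in asa_monomer:
        name = residue_names[key]
        by_scale: dict[str, str] = {}
        for scale in scales:
            rm = compute_rasa(asa_monomer[key], name, scale)
            rc = compute_rasa(asa_complex[key], name, scale)
            by_scale[scale.scale_name] = assign_region(rm, rc, thresholds)
        rm0 = compute_rasa(asa_monomer[key], name, primary)
        rc0 = compute_rasa(asa_complex[key], name, primary)
        out[key] = RegionAssignment(
            key=key,
            resname=name,
            asa_monomer=asa_monomer[key],
            asa_complex=asa_complex[key],
            rasa_monomer=rm0,
            rasa_complex=rc0,
            delta_rasa=rm0 - rc0,
            region_by_scale=by_scale,
            region=assign_region_consensus(by_scale),
        )
    return out


# ---------------------------------------------------------------------------
# Buried surface area

@dataclass
class BsaResult:
    """Total and per-region buried surface area (Å²)."""

    total: float
    per_region: dict[str, float]
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        interface_total = sum(self.per_region.get(r, 0.0) for r in INTERFACE_REGIONS)
        if interface_total > 0:
            self.fractions = {
                r: self.per_region.get(r, 0.0) / interface_total for r in INTERFACE_REGIONS
            }


def buried_surface_area(
    asa_monomer: dict[ResidueKey, float],
    asa_complex: dict[ResidueKey, float],
    regions: dict[ResidueKey, RegionAssignment],
) -> BsaResult:
    """Per-residue buried area (monomer − complex, clamped at 0) summed per region.

    The residue keys of the two ASA maps must match; the total sums over the
    residues of both chains, so it equals ASA_a + ASA_b − ASA_complex.
    """
    if set(asa_monomer) != set(asa_complex):
        raise ValueError("monomer/complex ASA maps must share residue keys")
    per_region: dict[str, float] = {r: 0.0 for r in REGION_LABELS}
    total = 0.0
    for key, asa_m in asa_monomer.items():
        buried = max(0.0, asa_m - asa_complex[key])
        total += buried
        per_region[regions[key].region] += buried
    return BsaResult(total=total, per_region=per_region)


def region_table(regions: dict[ResidueKey, RegionAssignment]):
    """Region assignments as a tidy DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for key in sorted(regions):
        r = regions[key]
        row = {
            "chain": key[0],
            "resnum": key[1],
            "icode": key[2],
            "resname": r.resname,
            "asa_mono": r.asa_monomer,
            "asa_cplx": r.asa_complex,
            "rasa_mono": r.rasa_monomer,
            "rasa_cplx": r.rasa_complex,
            "delta_rasa": r.delta_rasa,
        }
        for scale, label in r.region_by_scale.items():
            row[f"region_{scale}"] = label
        row["region"] = r.region
        rows.append(row)
    return pd.DataFrame(rows)
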