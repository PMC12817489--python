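"""Region-resolved interface statistics.

Composition and partitioning of physicochemical residue classes per region,
stickiness (log-propensity of an amino acid for interface vs exposed surface
area), interaction counting by region, the mean interaction count per capable
residue pair, and the scaling of interacting-pair counts with buried surface
area.

The residue classification follows the IMGT physicochemical scheme: charge
(positive/negative/neutral), polarity (polar/apolar), hydropathy
(hydrophobic/neutral/hydrophilic), aromatic/aliphatic flags and a side-chain
hydrogen-bonding capability flag. Tyrosine is polar with neutral hydropathy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Physicochemical residue classification (IMGT scheme)

_CANON = {"MSE": "MET", "SEC": "CYS"}


def canonical_name(resname: str) -> str:
    """Map selenium variants onto their sulfur analogues for classification."""
    return _CANON.get(resname, resname)


@dataclass(frozen=True)
class ResidueClassTable:
    """Per-residue physicochemical labels in several dimensions."""

    charge: dict[str, str]
    polarity: dict[str, str]
    hydropathy: dict[str, str]
    aromatic: frozenset[str]
    aliphatic: frozenset[str]
    sidechain_hbond: frozenset[str]

    def label(self, resname: str, dimension: str) -> str:
        name = canonical_name(resname)
        if dimension == "charge":
            return self.charge[name]
        if dimension == "polarity":
            return self.polarity[name]
        if dimension == "hydropathy":
            return self.hydropathy[name]
        if dimension == "aromatic":
            return "aromatic" if name in self.aromatic else "non_aromatic"
        if dimension == "aliphatic":
            return "aliphatic" if name in self.aliphatic else "non_aliphatic"
        if dimension == "sidechain_hbond":
            return "hbond_capable" if name in self.sidechain_hbond else "hbond_incapable"
        raise KeyError(f"unknown class dimension {dimension!r}")

    def classes(self, dimension: str) -> tuple[str, ...]:
        if dimension == "charge":
            return ("positive", "negative", "neutral")
        if dimension == "polarity":
            return ("polar", "apolar")
        if dimension == "hydropathy":
            return ("hydrophobic", "neutral", "hydrophilic")
        if dimension == "aromatic":
            return ("aromatic", "non_aromatic")
        if dimension == "aliphatic":
            return ("aliphatic", "non_aliphatic")
        if dimension == "sidechain_hbond":
            return ("hbond_capable", "hbond_incapable")
        raise KeyError(f"unknown class dimension {dimension!r}")


_POSITIVE = ("ARG", "LYS", "HIS")
_NEGATIVE = ("ASP", "GLU")
_POLAR = ("ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "LYS", "SER", "THR", "TYR")
_HYDROPHOBIC = ("ALA", "CYS", "ILE", "LEU", "MET", "PHE", "TRP", "VAL")
_HYDROPHILIC = ("ARG", "ASN", "ASP", "GLN", "GLU", "LYS")
_ALL20 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

DEFAULT_CLASS_TABLE = ResidueClassTable(
    charge={r: ("positive" if r in _POSITIVE else "negative" if r in _NEGATIVE else "neutral")
            for r in _ALL20},
    polarity={r: ("polar" if r in _POLAR else "apolar") for r in _ALL20},
    hydropathy={r: ("hydrophobic" if r in _HYDROPHOBIC
                    else "hydrophilic" if r in _HYDROPHILIC else "neutral")
                for r in _ALL20},
    aromatic=frozenset({"HIS", "PHE", "TRP", "TYR"}),
    aliphatic=frozenset({"ALA", "ILE", "LEU", "VAL"}),
    sidechain_hbond=frozenset(
        {"ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "LYS", "SER", "THR", "TRP", "TYR"}
    ),
)

# ---------------------------------------------------------------------------
# Capability table: which residue-name pairs can chemically form each type

AROMATIC_RES = frozenset({"HIS", "PHE", "TRP", "TYR"})
CATION_RES = frozenset({"ARG", "LYS", "HIS"})
ANION_RES = frozenset({"ASP", "GLU"})
SSE_RES = frozenset({"CYS", "MET"})  # after canonicalization MSE->MET, SEC->CYS
AMIDE_RES = frozenset({"ASN", "GLN"})
HYDROPHOBIC_RES = frozenset(_HYDROPHOBIC)
HYDROPHILIC_RES = frozenset(_HYDROPHILIC)


@dataclass(frozen=True)
class CapabilityTable:
    """Predicate per interaction type on unordered residue-name pairs."""

    his_as_cation: bool = True

    def _cations(self) -> frozenset[str]:
        return CATION_RES if self.his_as_cation else frozenset({"ARG", "LYS"})

    def capable(self, itype: str, resname_a: str, resname_b: str) -> bool:
        a, b = canonical_name(resname_a), canonical_name(resname_b)
        pair = {a, b}
        cations = self._cations()
        if itype in {"hbond", "n_pi_star", "c_bond", "vdw"}:
            return True  # backbone suffices
        if itype in {"sse_hbond", "chalcogen"}:
            return bool(pair & SSE_RES)
        if itype == "h_pi":
            return bool(pair & AROMATIC_RES)
        if itype == "aromatic_aromatic":
            return a in AROMATIC_RES and b in AROMATIC_RES
        if itype == "amino_pi":
            return (a in AMIDE_RES and b in AROMATIC_RES) or (b in AMIDE_RES and a in AROMATIC_RES)
        if itype == "aromatic_sse":
            return (a in SSE_RES and b in AROMATIC_RES) or (b in SSE_RES and a in AROMATIC_RES)
        if itype == "aromatic_cation":
            return (a in cations and b in AROMATIC_RES) or (b in cations and a in AROMATIC_RES)
        if itype == "aromatic_anion":
            return (a in ANION_RES and b in AROMATIC_RES) or (b in ANION_RES and a in AROMATIC_RES)
        if itype == "salt_bridge":
            return (a in cations and b in ANION_RES) or (b in cations and a in ANION_RES)
        if itype == "hydrophobic":
            return a in HYDROPHOBIC_RES and b in HYDROPHOBIC_RES
        if itype == "arg_arg_stacking":
            return a == "ARG" and b == "ARG"
        if itype in {"charge_clash", "charge_repulsion"}:
            if a == "ARG" and b == "ARG" and itype == "charge_clash":
                return True  # capable, though stacking pairs are excluded at detection
            return (a in cations and b in cations) or (a in ANION_RES and b in ANION_RES)
        if itype in {"hydrophobic_hydrophilic_clash", "hydrophobic_hydrophilic_repulsion"}:
            return (a in HYDROPHOBIC_RES and b in HYDROPHILIC_RES) or (
                b in HYDROPHOBIC_RES and a in HYDROPHILIC_RES
            )
        raise KeyError(f"unknown interaction type {itype!r}")


DEFAULT_CAPABILITY = CapabilityTable()

#: Interaction types whose per-pair count is 0/1 by construction; their mean
#: per capable pair is a proportion and gets a Wilson interval.
BINARY_TYPES = frozenset(
    {
        "hydrophobic", "arg_arg_stacking", "salt_bridge",
        "charge_clash", "charge_repulsion",
        "hydrophobic_hydrophilic_clash", "hydrophobic_hydrophilic_repulsion",
    }
)

# ---------------------------------------------------------------------------
# Composition and partitioning

@dataclass
class RegionCompositionResult:
    """Per-region class frequency vectors (percent) and residue counts."""

    dimension: str
    percentages: dict[str, dict[str, float]]
    counts: dict[str, int]


def region_composition(
    regions: dict,
    class_table: ResidueClassTable = DEFAULT_CLASS_TABLE,
    dimension: str = "charge",
    region_labels: tuple[str, ...] | None = None,
) -> RegionCompositionResult:
    """Percentage of residues in each class of ``dimension``, per region.

    ``regions`` maps residue key -> RegionAssignment. Empty regions yield an
    empty vector (flagged by a zero count), never NaN.
    """
    from .sasa_regions import REGION_LABELS

    labels = region_labels or REGION_LABELS
    classes = class_table.classes(dimension)
    percentages: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    for region in labels:
        members = [r for r in regions.values() if r.region == region]
        counts[region] = len(members)
        if not members:
            percentages[region] = {}
            continue
        vec = {c: 0 for c in classes}
        for r in members:
            try:
                vec[class_table.label(r.resname, dimension)] += 1
            except KeyError:
                continue
        n = sum(vec.values())
        percentages[region] = {c: 100.0 * v / n for c, v in vec.items()} if n else {}
    return RegionCompositionResult(dimension=dimension, percentages=percentages, counts=counts)


def partition_by_region(
    residue_class: str,
    regions: dict,
    class_table: ResidueClassTable = DEFAULT_CLASS_TABLE,
    dimension: str = "charge",
) -> dict[str, float] | None:
    """Fraction of residues of one class found in each interface region.

    Returns None (missing) when the class is absent from the interface.
    """
    from .sasa_regions import INTERFACE_REGIONS

    tallies = {r: 0 for r in INTERFACE_REGIONS}
    for assignment in regions.values():
        if assignment.region not in tallies:
            continue
        try:
            if class_table.label(assignment.resname, dimension) == residue_class:
                tallies[assignment.region] += 1
        except KeyError:
            continue
    total = sum(tallies.values())
    if total == 0:
        return None
    return {r: v / total for r, v in tallies.items()}


# ---------------------------------------------------------------------------
# Stickiness

def stickiness(
    interface_area_by_restype: dict[str, float],
    surface_area_by_restype: dict[str, float],
    epsilon: float = 1e-6,
) -> dict[str, float | None]:
    """Log-propensity ln(f_interface / f_surface) per residue type.

    The fractional contribution of each residue type to the interface area is
    compared with its contribution to the solvent-exposed surface area. A
    pseudo-share ``epsilon`` is added to both fractions; a type absent from
    both areas is reported as missing (None), never 0.
    """
    ti = sum(interface_area_by_restype.values())
    ts = sum(surface_area_by_restype.values())
    if ti <= 0 or ts <= 0:
        raise ValueError("total interface and surface areas must be positive")
    out: dict[str, float | None] = {}
    for res in sorted(set(interface_area_by_restype) | set(surface_area_by_restype)):
        ai = interface_area_by_restype.get(res, 0.0)
        asurf = surface_area_by_restype.get(res, 0.0)
        if ai == 0.0 and asurf == 0.0:
            out[res] = None
            continue
        fi = ai / ti + epsilon
        fs = asurf / ts + epsilon
        out[res] = math.log(fi / fs)
    return out


# ---------------------------------------------------------------------------
# Interaction counting

def count_interactions_by_region(
    records: list,
    pairs: list,
    scope: str = "same_region",
) -> dict:
    """Count interaction records per type, per region or region pair.

    scope="same_region": counts only records whose two residues share the
    same consensus region, keyed by that region. scope="cross_region": counts
    records whose residues sit in different regions, keyed by the sorted
    region pair.
    """
    if scope not in {"same_region", "cross_region"}:
        raise ValueError("scope must be same_region or cross_region")
    region_of = {}
    for p in pairs:
        region_of[p.pair] = p.regions
    out: dict = {}
    for rec in records:
        pair_key = rec.pair
        regions = region_of.get(pair_key)
        if regions is None:
            continue
        ra, rb = regions
        if scope == "same_region":
            if ra != rb:
                continue
            key = ra
        else:
            if ra == rb:
                continue
            key = tuple(sorted((ra, rb)))
        out.setdefault(key, {}).setdefault(rec.type, 0)
        out[key][rec.type] += 1
    return out


# ---------------------------------------------------------------------------
# Mean count per capable pair

@dataclass
class MeanCountResult:
    mean: float
    ci_low: float
    ci_high: float
    n_capable: int
    binary: bool


def mean_count_per_pair(
    records: list,
    candidate_pairs: list,
    itype: str,
    region: str,
    regions: dict,
    capability: CapabilityTable = DEFAULT_CAPABILITY,
    confidence: float = 0.95,
) -> MeanCountResult | None:
    """Average count of one interaction type over capable candidate pairs.

    The denominator is every candidate residue pair (Cα within the cutoff)
    whose residue names are capable of the type and whose residues both carry
    the requested consensus region label — including pairs that formed no
    interaction. Binary types yield a proportion with a Wilson interval;
    counted types a mean with a Student-t interval. Returns None when no
    capable pair exists.
    """
    from .diversity_stats import wilson_interval

    per_pair_counts: dict[tuple, int] = {}
    for rec in records:
        if rec.type == itype:
            per_pair_counts[rec.pair] = per_pair_counts.get(rec.pair, 0) + 1

    counts = []
    for pair in candidate_pairs:
        key_a, key_b = pair.pair
        if regions[key_a].region != region or regions[key_b].region != region:
            continue
        if not capability.capable(itype, regions[key_a].resname, regions[key_b].resname):
            continue
        counts.append(per_pair_counts.get(pair.pair, 0))
    n = len(counts)
    if n == 0:
        return None
    binary = itype in BINARY_TYPES
    if binary:
        successes = sum(1 for c in counts if c > 0)
        mean = successes / n
        lo, hi = wilson_interval(successes, n, confidence)
        return MeanCountResult(mean, lo, hi, n, True)
    arr = np.asarray(counts, dtype=float)
    mean = float(arr.mean())
    if n > 1 and arr.std(ddof=1) > 0:
        from scipy import stats

        sem = arr.std(ddof=1) / math.sqrt(n)
        tval = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
        lo, hi = mean - tval * sem, mean + tval * sem
    else:
        lo = hi = mean
    return MeanCountResult(mean, float(lo), float(hi), n, False)


# ---------------------------------------------------------------------------
# Pair count vs BSA scaling

@dataclass
class ScalingFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    points: list[tuple[float, float]] = field(default_factory=list)


def weighted_same_region_pair_count(pairs: list, region: str) -> float:
    """Same-region interacting pairs, counted twice (once per chain side).

    Rim and rim-NIS are merged for this accounting: a pair is in region
    "rim" when both residues carry either rim label.
    """
    def norm(label: str) -> str:
        return "rim" if label in {"rim_interacting", "rim_nis"} else label

    n = sum(1 for p in pairs if norm(p.regions[0]) == norm(p.regions[1]) == region)
    return 2.0 * n


def pair_bsa_scaling(
    per_complex: list[tuple[float, float]],
) -> ScalingFit | None:
    """OLS fit of weighted same-region pair count against region BSA.

    ``per_complex`` holds (bsa, weighted_pair_count) points, one per complex.
    Returns None when fewer than 2 points are available.
    """
    if len(per_complex) < 2:
        return None
    import statsmodels.api as sm

    x = np.array([p[0] for p in per_complex])
    y = np.array([p[1] for p in per_complex])
    X = sm.add_constant(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = sm.OLS(y, X).fit()
        return ScalingFit(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]) if len(fit.pvalues) > 1 else float("nan"),
            points=list(per_complex),
        )
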