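"""Reading and normalizing protein complex structures.

Parses PDB / mmCIF files (via gemmi), reduces them to a light internal model
of protein residues and heavy/hydrogen atoms, resolves alternate conformers
to a single deterministic conformer, flags incomplete residues, and splits a
complex into its two monomer contexts plus the bound complex.

The monomer contexts are the chains exactly as found in the complex: no
re-minimization or repair is performed, so a residue's coordinates are
bit-identical between its monomer and the complex.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

try:
    import gemmi
except ImportError as _exc:  # pragma: no cover
    raise ImportError("ppiface.structure_io requires gemmi") from _exc

logger = logging.getLogger("ppiface")

# ---------------------------------------------------------------------------
# Residue chemistry tables

#: The 20 standard residues plus selenium variants (selenomethionine MSE,
#: selenocysteine SEC), which are retained with their Se atoms.
STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "MSE", "SEC",
    }
)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Heavy atoms expected for each residue type (used for the `complete` flag).
RESIDUE_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": ("N", "CA", "C", "O"),
    "ALA": ("N", "CA", "C", "O", "CB"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "SEC": ("N", "CA", "C", "O", "CB", "SE"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "MSE": ("N", "CA", "C", "O", "CB", "CG", "SE", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}


class StructureError(ValueError):
    """Raised for unreadable files, empty structures or bad chain groupings."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class AtomRecord:
    """One atom: label, element, position (Å), occupancy and altloc flag."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        self.is_backbone = self.name in BACKBONE_ATOMS or (
            self.element == "H" and self.name in {"H", "HA", "H1", "H2", "H3"}
        )


@dataclass
class ResidueRecord:
    """One residue with its atoms and identity within a chain."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord]
    complete: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class StructureModel:
    """A parsed structure: ordered residue lists per chain, plus provenance."""

    structure_id: str
    chains: dict[str, list[ResidueRecord]]
    provenance: dict = field(default_factory=dict)

    def residues(self) -> Iterator[ResidueRecord]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def residue_map(self) -> dict[tuple[str, int, str], ResidueRecord]:
        return {r.key: r for r in self.residues()}

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


# ---------------------------------------------------------------------------
# Loading

def load_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model (e.g. NMR) files is used; the model
    count is recorded in provenance. Heteroatoms that are not amino acids
    (waters, ligands, ions) are excluded from the residue lists but counted
    in ``provenance["excluded_residues"]``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in {"mmcif", "cif"}:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc

    n_models = len(st)
    if n_models == 0:
        raise StructureError(f"{path}: no models in file")
    model = st[0]

    chains: dict[str, list[ResidueRecord]] = {}
    excluded = 0
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            if res.name not in STANDARD_RESIDUES:
                excluded += 1
                continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            if not atoms:
                excluded += 1
                continue
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                )
            )
        if residues:
            if chain.name in chains:
                chains[chain.name].extend(residues)
            else:
                chains[chain.name] = residues
    if not chains:
        raise StructureError(f"{path}: no protein chains found")

    return StructureModel(
        structure_id=st.name or path.stem,
        chains=chains,
        provenance={
            "path": str(path),
            "format": fmt,
            "n_models": n_models,
            "model_index": 0,
            "excluded_residues": excluded,
        },
    )


# ---------------------------------------------------------------------------
# Standardization

def standardize_residues(model: StructureModel) -> StructureModel:
    """Resolve alternate conformers and flag incomplete residues.

    For each atom name with several altloc conformers, the highest-occupancy
    conformer is kept; ties are broken by altloc character order. Residues
    missing expected heavy atoms are flagged ``complete=False`` but retained.
    The fraction of complete residues per chain is reported in provenance.
    Idempotent.
    """
    out_chains: dict[str, list[ResidueRecord]] = {}
    completeness: dict[str, float] = {}
    for chain_id, residues in model.chains.items():
        out_res: list[ResidueRecord] = []
        n_complete = 0
        for res in residues:
            by_name: dict[str, list[AtomRecord]] = {}
            order: list[str] = []
            for a in res.atoms:
                if a.name not in by_name:
                    order.append(a.name)
                by_name.setdefault(a.name, []).append(a)
            atoms: list[AtomRecord] = []
            for name in order:
                group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
                kept = copy.copy(group[0])
                kept.altloc = ""
                atoms.append(kept)
            expected = RESIDUE_HEAVY_ATOMS.get(res.name, ())
            present = {a.name for a in atoms}
            complete = all(n in present for n in expected)
            if complete:
                n_complete += 1
            else:
                logger.debug("residue %s %s%d incomplete", res.name, chain_id, res.seq_number)
            out_res.append(
                ResidueRecord(
                    chain_id=res.chain_id,
                    seq_number=res.seq_number,
                    insertion_code=res.insertion_code,
                    name=res.name,
                    atoms=atoms,
                    complete=complete,
                )
            )
        out_chains[chain_id] = out_res
        completeness[chain_id] = n_complete / len(residues) if residues else 1.0
    prov = dict(model.provenance)
    prov["completeness"] = completeness
    return StructureModel(model.structure_id, out_chains, prov)


# ---------------------------------------------------------------------------
# Splitting

def split_complex(
    model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> tuple[StructureModel, StructureModel, StructureModel]:
    """Split a complex into two monomer contexts and the bound complex.

    The monomers contain exactly the coordinates of their chains as found in
    the complex; the returned complex is restricted to the union of the two
    groups.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise StructureError("chain groups must be non-empty")
    overlap = ga & gb
    if overlap:
        raise StructureError(f"chain groups overlap: {sorted(overlap)}")
    unknown = (ga | gb) - set(model.chains)
    if unknown:
        raise StructureError(f"unknown chain ids: {sorted(unknown)}")

    def subset(group: set[str], tag: str) -> StructureModel:
        chains = {cid: model.chains[cid] for cid in model.chains if cid in group}
        prov = dict(model.provenance)
        prov["context"] = tag
        return StructureModel(f"{model.structure_id}:{tag}", chains, prov)

    return subset(ga, "monomer_a"), subset(gb, "monomer_b"), subset(ga | gb, "complex")


# ---------------------------------------------------------------------------
# Audit table

def write_residue_table(model: StructureModel, path: str | Path) -> None:
    """Write a normalized residue/atom table (TSV) for auditability."""
    import pandas as pd

    rows = []
    for res in model.residues():
        for a in res.atoms:
            rows.append(
                {
                    "chain": res.chain_id,
                    "resnum": res.seq_number,
                    "icode": res.insertion_code,
                    "resname": res.name,
                    "atom": a.name,
                    "element": a.element,
                    "x": a.coords[0],
                    "y": a.coords[1],
                    "z": a.coords[2],
                    "occupancy": a.occupancy,
                    "complete": res.complete,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")
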