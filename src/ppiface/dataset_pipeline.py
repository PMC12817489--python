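"""Per-complex orchestration, affinity-based classification and aggregation.

A manifest table (TSV) lists one complex per row: structure path/ID, the two
chain groups, and the binding affinity (KD, IC50 or Ki, in molar units or
with an explicit unit column). Complexes are classified by
log10(affinity): above −6 transient, below −9 stable, in between (and at
the boundaries) intermediate.

``run_complex`` executes the full per-complex pipeline — load, standardize,
split, SASA on both monomers and the complex, region assignment, interaction
detection, per-complex metrics — and ``aggregate`` builds dataset-level
tables: compositions, partitioning, interaction counts, pair-vs-BSA scaling
fits, affinity regressions, diversity and PMI. A thin click CLI exposes the
pipeline as the ``ppiface`` command.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import load_structure, split_complex, standardize_residues
from .sasa_regions import (
    BsaResult,
    DEFAULT_SCALES,
    INTERFACE_REGIONS,
    RegionThresholds,
    assign_regions,
    buried_surface_area,
    compute_sasa,
    region_table,
)
from .interactions import (
    DEFAULT_GEOMETRY,
    DetectionResult,
    GeometryConfig,
    detect_all,
    interaction_table,
)
from .interface_metrics import (
    DEFAULT_CLASS_TABLE,
    count_interactions_by_region,
    region_composition,
    weighted_same_region_pair_count,
    pair_bsa_scaling,
)
from .diversity_stats import (
    DEFAULT_PAIR_CLASS_MAP,
    diversity,
    pair_class,
    region_pmi_analysis,
)

logger = logging.getLogger("ppiface")

STABILITY_LABELS = ("stable", "intermediate", "transient")

#: log10(affinity in M) cuts: above the first -> transient, below the second
#: -> stable; boundary values fall into the intermediate band.
DEFAULT_STABILITY_CUTS = (-6.0, -9.0)

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def classify_stability(
    log10_affinity: float,
    cuts: tuple[float, float] = DEFAULT_STABILITY_CUTS,
) -> str:
    """Stability class from log10 affinity (KD/IC50/Ki in molar units)."""
    if not math.isfinite(log10_affinity):
        raise ValueError("log10 affinity must be finite")
    transient_cut, stable_cut = cuts
    if transient_cut <= stable_cut:
        raise ValueError("transient cut must exceed stable cut")
    if log10_affinity > transient_cut:
        return "transient"
    if log10_affinity < stable_cut:
        return "stable"
    return "intermediate"


@dataclass
class ComplexAnnotation:
    """One manifest row."""

    structure_id: str
    path: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    affinity_value: float
    affinity_kind: str = "KD"
    affinity_units: str = "M"

    @property
    def log10_affinity(self) -> float:
        factor = _UNIT_FACTORS.get(self.affinity_units)
        if factor is None:
            raise ValueError(f"unknown affinity unit {self.affinity_units!r}")
        return math.log10(self.affinity_value * factor)


@dataclass
class RunConfig:
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)
    geometry: GeometryConfig = field(default_factory=lambda: DEFAULT_GEOMETRY)
    stability_cuts: tuple[float, float] = DEFAULT_STABILITY_CUTS
    scales: tuple = DEFAULT_SCALES
    sasa_points: int = 960
    seed: int = 0


@dataclass
class ComplexSummary:
    """Everything the aggregation step needs from one complex."""

    structure_id: str
    log10_affinity: float
    stability: str
    regions: dict
    bsa: BsaResult
    detection: DetectionResult
    n_residues_by_region: dict[str, int]
    pair_class_counts: dict[str, Counter]
    residue_class_counts: dict[str, Counter]
    region_df: pd.DataFrame
    interaction_df: pd.DataFrame


def run_complex(annotation: ComplexAnnotation, config: RunConfig = RunConfig()) -> ComplexSummary:
    """Full per-complex pipeline: load → regions → detect → summarize."""
    model = standardize_residues(load_structure(annotation.path))
    mono_a, mono_b, cplx = split_complex(model, annotation.group_a, annotation.group_b)
    asa_mono = {
        **compute_sasa(mono_a, n_points=config.sasa_points),
        **compute_sasa(mono_b, n_points=config.sasa_points),
    }
    asa_cplx = compute_sasa(cplx, n_points=config.sasa_points)
    names = {r.key: r.name for r in cplx.residues()}
    regions = assign_regions(asa_mono, asa_cplx, names, config.scales, config.thresholds)
    bsa = buried_surface_area(asa_mono, asa_cplx, regions)
    detection = detect_all(cplx, regions, config.geometry, scope="inter_chain")
    # interior pairs come from the intra-chain contact network
    interior_detection = detect_all(cplx, regions, config.geometry, scope="intra_chain")

    n_by_region = Counter(r.region for r in regions.values())
    pair_class_counts: dict[str, Counter] = {}
    residue_class_counts: dict[str, Counter] = {}
    for r in regions.values():
        residue_class_counts.setdefault(r.region, Counter())[
            DEFAULT_PAIR_CLASS_MAP.get(_canon(r.resname), "polar")
        ] += 1
    for pair in detection.pairs + [
        p for p in interior_detection.pairs
        if p.regions[0] == p.regions[1] == "interior"
    ]:
        ra, rb = pair.regions
        if ra != rb or ra == "":
            continue
        pair_class_counts.setdefault(ra, Counter())[
            pair_class(*pair.resnames)
        ] += 1

    return ComplexSummary(
        structure_id=annotation.structure_id,
        log10_affinity=annotation.log10_affinity,
        stability=classify_stability(annotation.log10_affinity, config.stability_cuts),
        regions=regions,
        bsa=bsa,
        detection=detection,
        n_residues_by_region=dict(n_by_region),
        pair_class_counts=pair_class_counts,
        residue_class_counts=residue_class_counts,
        region_df=region_table(regions),
        interaction_df=interaction_table(detection, annotation.structure_id),
    )


def _canon(name: str) -> str:
    from .interface_metrics import canonical_name

    return canonical_name(name)


# ---------------------------------------------------------------------------
# Aggregation

def aggregate(
    summaries: list[ComplexSummary],
    groups: tuple[str, ...] = ("stable", "intermediate", "transient"),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Dataset-level tables grouped by stability class.

    Produces composition means with t-based confidence intervals, region-size
    regressions of affinity against residue counts, pair-count-vs-BSA scaling
    fits, same-region interaction counts, diversity indices and PMI tables.
    Raises for a requested group with no complexes.
    """
    if not summaries:
        raise ValueError("no complex summaries to aggregate")
    by_group: dict[str, list[ComplexSummary]] = {g: [] for g in groups}
    for s in summaries:
        if s.stability in by_group:
            by_group[s.stability].append(s)
    present_groups = [g for g in groups if by_group[g]]
    if not present_groups:
        raise ValueError(f"no complexes in any requested group {groups}")

    tables: dict[str, pd.DataFrame] = {}

    # --- composition means per group/region/dimension
    comp_rows = []
    for g in present_groups:
        for dimension in ("charge", "polarity", "hydropathy", "aromatic", "aliphatic",
                          "sidechain_hbond"):
            per_complex = [
                region_composition(s.regions, DEFAULT_CLASS_TABLE, dimension)
                for s in by_group[g]
            ]
            for region in INTERFACE_REGIONS:
                classes = DEFAULT_CLASS_TABLE.classes(dimension)
                for cls in classes:
                    vals = [
                        c.percentages[region][cls]
                        for c in per_complex
                        if c.percentages.get(region)
                    ]
                    if not vals:
                        continue
                    mean, lo, hi = _t_ci(vals)
                    comp_rows.append({
                        "group": g, "dimension": dimension, "region": region,
                        "class": cls, "mean_pct": mean, "ci_low": lo, "ci_high": hi,
                        "n_complexes": len(vals),
                    })
    tables["composition"] = pd.DataFrame(comp_rows)

    # --- affinity vs region size regressions (all complexes pooled)
    import statsmodels.api as sm

    reg_rows = []
    for region in ("support", "core", "rim"):
        x, y = [], []
        for s in summaries:
            if region == "rim":
                n = (s.n_residues_by_region.get("rim_interacting", 0)
                     + s.n_residues_by_region.get("rim_nis", 0))
            else:
                n = s.n_residues_by_region.get(region, 0)
            x.append(n)
            y.append(s.log10_affinity)
        if len(set(x)) > 1:
            fit = sm.OLS(np.array(y), sm.add_constant(np.array(x, dtype=float))).fit()
            reg_rows.append({
                "region": region, "slope": fit.params[1], "intercept": fit.params[0],
                "r_squared": fit.rsquared, "p_value": fit.pvalues[1], "n": len(x),
            })
    tables["affinity_regression"] = pd.DataFrame(reg_rows)

    # --- pair count vs BSA scaling (rim merged, same-region pairs doubled)
    scaling_rows = []
    for region in ("core", "support", "rim"):
        points = []
        for s in summaries:
            if region == "rim":
                bsa = (s.bsa.per_region.get("rim_interacting", 0.0)
                       + s.bsa.per_region.get("rim_nis", 0.0))
            else:
                bsa = s.bsa.per_region.get(region, 0.0)
            y = weighted_same_region_pair_count(s.detection.pairs, region)
            points.append((bsa, y))
        fit = pair_bsa_scaling(points)
        if fit is not None:
            scaling_rows.append({
                "region": region, "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "p_value": fit.p_value, "n": len(points),
            })
    tables["pair_bsa_scaling"] = pd.DataFrame(scaling_rows)

    # --- same-region interaction counts per group
    count_rows = []
    for g in present_groups:
        totals: dict[str, Counter] = {}
        for s in by_group[g]:
            counts = count_interactions_by_region(s.detection.records, s.detection.pairs,
                                                  scope="same_region")
            for region, per_type in counts.items():
                totals.setdefault(region, Counter()).update(per_type)
        for region, per_type in sorted(totals.items()):
            for itype, n in sorted(per_type.items()):
                count_rows.append({"group": g, "region": region, "type": itype, "count": n})
    tables["interaction_counts"] = pd.DataFrame(count_rows)

    # --- diversity of pair classes per group/region (mean of frequencies)
    div_rows = []
    for g in present_groups:
        region_names = sorted({r for s in by_group[g] for r in s.pair_class_counts})
        for region in region_names:
            freq_vectors = []
            for s in by_group[g]:
                counts = s.pair_class_counts.get(region)
                if not counts:
                    continue
                total = sum(counts.values())
                freq_vectors.append({k: v / total for k, v in counts.items()})
            if not freq_vectors:
                continue
            mean_freq: dict = {}
            for f in freq_vectors:
                for k, v in f.items():
                    mean_freq[k] = mean_freq.get(k, 0.0) + v / len(freq_vectors)
            total = sum(mean_freq.values())
            mean_freq = {k: v / total for k, v in mean_freq.items()}
            d = diversity(mean_freq)
            div_rows.append({
                "group": g, "region": region, "H": d.H, "H_max": d.H_max,
                "J": d.J, "k": d.k, "n_complexes": len(freq_vectors),
            })
    tables["diversity"] = pd.DataFrame(div_rows)

    # --- PMI per (region, group)
    complexes = [
        {
            "stability": s.stability,
            "regions": {
                region: {
                    "pairs": s.pair_class_counts.get(region, Counter()),
                    "residues": s.residue_class_counts.get(region, Counter()),
                }
                for region in set(s.pair_class_counts) | set(s.residue_class_counts)
            },
        }
        for s in summaries
    ]
    group_idx = {
        g: [i for i, s in enumerate(summaries) if s.stability == g]
        for g in present_groups
    }
    pmi_tables = region_pmi_analysis(complexes, groups=group_idx)
    pmi_rows = []
    for (region, g), cells in sorted(pmi_tables.items()):
        for cell in cells:
            pmi_rows.append({
                "region": region, "group": g,
                "pair_class": "-".join(cell.pair),
                "pair_freq": cell.pair_freq, "f1": cell.f1, "f2": cell.f2,
                "pmi": cell.pmi if cell.pmi is not None else np.nan,
                "tfidf": cell.tfidf, "retained": cell.retained,
            })
    tables["pmi"] = pd.DataFrame(pmi_rows)

    # --- stability group sizes
    tables["stability_counts"] = pd.DataFrame(
        [{"group": g, "n": len(by_group.get(g, []))} for g in groups]
    )
    return tables


def _t_ci(values: list[float], confidence: float = 0.95) -> tuple[float, float, float]:
    from scipy import stats

    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2 or arr.std(ddof=1) == 0:
        return mean, mean, mean
    sem = arr.std(ddof=1) / math.sqrt(len(arr))
    t = stats.t.ppf(0.5 + confidence / 2.0, len(arr) - 1)
    return mean, mean - t * sem, mean + t * sem


# ---------------------------------------------------------------------------
# Manifest handling and CLI

def read_manifest(path: str | Path) -> list[ComplexAnnotation]:
    """Manifest TSV columns: structure_id, path, group_a, group_b, affinity,
    affinity_kind, affinity_units. Chain groups are '+'-separated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"structure_id", "path", "group_a", "group_b", "affinity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(ComplexAnnotation(
            structure_id=row["structure_id"],
            path=row["path"],
            group_a=tuple(str(row["group_a"]).split("+")),
            group_b=tuple(str(row["group_b"]).split("+")),
            affinity_value=float(row["affinity"]),
            affinity_kind=row.get("affinity_kind", "KD") or "KD",
            affinity_units=row.get("affinity_units", "M") or "M",
        ))
    return out


def run_manifest(
    annotations: list[ComplexAnnotation],
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> tuple[list[ComplexSummary], dict[str, pd.DataFrame], list[tuple[str, str]]]:
    """Process every manifest row; failures quarantine the complex."""
    summaries: list[ComplexSummary] = []
    failures: list[tuple[str, str]] = []
    for ann in annotations:
        try:
            summaries.append(run_complex(ann, config))
            logger.info("processed %s", ann.structure_id)
        except Exception as exc:  # deliberate: keep going over the manifest
            logger.error("complex %s failed: %s", ann.structure_id, exc)
            failures.append((ann.structure_id, str(exc)))
    groups = tuple(g for g in STABILITY_LABELS
                   if any(s.stability == g for s in summaries))
    tables = aggregate(summaries, groups=groups, seed=config.seed) if summaries else {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in summaries:
            s.region_df.to_csv(out_dir / f"{s.structure_id}_regions.tsv",
                               sep="\t", index=False, float_format="%.4f")
            s.interaction_df.to_csv(out_dir / f"{s.structure_id}_interactions.tsv",
                                    sep="\t", index=False, float_format="%.4f")
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.6f")
        if failures:
            pd.DataFrame(failures, columns=["structure_id", "error"]).to_csv(
                out_dir / "failures.tsv", sep="\t", index=False)
    return summaries, tables, failures


# ---------------------------------------------------------------------------
# CLI

import click


@click.group()
def cli() -> None:
    """Region-resolved interface interaction analysis."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@cli.command("run")
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="Flat key=value geometry config overrides.")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--sasa-points", default=960, show_default=True)
def cli_run(manifest, config_path, out_dir, sasa_points) -> None:
    """Process a manifest of complexes and write all per-complex and
    aggregate tables."""
    geometry = GeometryConfig.from_file(config_path) if config_path else DEFAULT_GEOMETRY
    config = RunConfig(geometry=geometry, sasa_points=sasa_points)
    summaries, _, failures = run_manifest(read_manifest(manifest), config, out_dir)
    click.echo(f"processed {len(summaries)} complexes, {len(failures)} failures")


@cli.command("regions")
@click.argument("structure", type=click.Path(exists=True))
@click.option("--group-a", required=True, help="'+'-separated chain ids")
@click.option("--group-b", required=True)
@click.option("--out", type=click.Path(), default=None)
@click.option("--sasa-points", default=960, show_default=True)
def cli_regions(structure, group_a, group_b, out, sasa_points) -> None:
    """Per-residue rASA and interface region table for one complex."""
    model = standardize_residues(load_structure(structure))
    mono_a, mono_b, cplx = split_complex(model, group_a.split("+"), group_b.split("+"))
    asa_mono = {**compute_sasa(mono_a, n_points=sasa_points),
                **compute_sasa(mono_b, n_points=sasa_points)}
    asa_cplx = compute_sasa(cplx, n_points=sasa_points)
    names = {r.key: r.name for r in cplx.residues()}
    regions = assign_regions(asa_mono, asa_cplx, names)
    df = region_table(regions)
    if out:
        df.to_csv(out, sep="\t", index=False, float_format="%.4f")
    else:
        click.echo(df.to_string(index=False))


@cli.command("interactions")
@click.argument("structure", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--scope", default="inter_chain",
              type=click.Choice(["inter_chain", "intra_chain", "both"]))
@click.option("--out", type=click.Path(), default=None)
def cli_interactions(structure, config_path, scope, out) -> None:
    """Detect all non-bonded interactions in one structure."""
    geometry = GeometryConfig.from_file(config_path) if config_path else DEFAULT_GEOMETRY
    model = standardize_residues(load_structure(structure))
    result = detect_all(model, None, geometry, scope=scope)
    df = interaction_table(result, model.structure_id)
    if out:
        df.to_csv(out, sep="\t", index=False, float_format="%.4f")
    else:
        click.echo(df.to_string(index=False))


@cli.command("diversity")
@click.argument("counts_tsv", type=click.Path(exists=True))
@click.option("--k", default=None, type=int,
              help="Number of possible classes (default: 10 pair classes).")
def cli_diversity(counts_tsv, k) -> None:
    """Entropy and evenness of a class,count table (TSV)."""
    df = pd.read_csv(counts_tsv, sep="\t")
    counts = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    total = sum(counts.values())
    d = diversity({c: v / total for c, v in counts.items()}, k=k)
    click.echo(f"H = {d.H:.4f} bits (Hmax = {d.H_max:.4f}), J = {d.J:.4f}, k = {d.k}")
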