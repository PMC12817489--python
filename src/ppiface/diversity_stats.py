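"""Pair-class diversity and co-occurrence statistics.

Interacting residue pairs are reduced to a simplified class alphabet based
on charge and polarity (positive / negative / polar / apolar), giving 10
unordered pair classes. Per region the module computes:

* Shannon entropy H = −Σ f log2 f of the pair-class frequencies and the
  evenness J = H / Hmax (Hmax = log2 k),
* a tf-idf filter that drops pair types confined to few structures
  (tf = total count across the dataset, idf = ln(N / df), threshold 1),
* pointwise mutual information of a pair class against the independence
  baseline of its residue-class frequencies — the heterogeneous branch
  carries a factor 2 in the denominator because an unordered heterogeneous
  pair can arise in two ways:

      PMI = log2( f_pair / (f1 · f2) )        homogeneous pair
      PMI = log2( f_pair / (2 · f1 · f2) )    heterogeneous pair

plus the generic estimators used throughout the analysis: the Wilson score
interval for proportions, the probability of superiority P(X>Y) + ½P(X=Y),
and percentile bootstrap confidence intervals resampled over complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from itertools import combinations_with_replacement
from typing import Callable, Iterable, Sequence

import numpy as np

from .interface_metrics import DEFAULT_CLASS_TABLE, canonical_name

# ---------------------------------------------------------------------------
# Simplified pair classes

PAIR_CLASSES_4 = ("positive", "negative", "polar", "apolar")


def default_pair_class_map() -> dict[str, str]:
    """Residue name -> simplified class: charged residues by their charge,
    remaining residues split by polarity."""
    out = {}
    for res in DEFAULT_CLASS_TABLE.charge:
        charge = DEFAULT_CLASS_TABLE.charge[res]
        if charge in {"positive", "negative"}:
            out[res] = charge
        else:
            out[res] = DEFAULT_CLASS_TABLE.polarity[res]
    return out


DEFAULT_PAIR_CLASS_MAP = default_pair_class_map()

#: The 10 unordered pair classes over the 4-class alphabet.
ALL_PAIR_CLASSES: tuple[tuple[str, str], ...] = tuple(
    tuple(sorted(c)) for c in combinations_with_replacement(PAIR_CLASSES_4, 2)
)


def pair_class(resname_a: str, resname_b: str,
               class_map: dict[str, str] = DEFAULT_PAIR_CLASS_MAP) -> tuple[str, str]:
    """Unordered simplified class pair of two residues."""
    a = class_map[canonical_name(resname_a)]
    b = class_map[canonical_name(resname_b)]
    return tuple(sorted((a, b)))


# ---------------------------------------------------------------------------
# Entropy and evenness

def shannon_entropy(freqs: Sequence[float]) -> float:
    """H = −Σ f log2 f in bits; zero entries contribute nothing."""
    arr = np.asarray(list(freqs), dtype=float)
    if np.any(arr < 0):
        raise ValueError("frequencies must be non-negative")
    total = arr.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    nz = arr[arr > 0]
    return float(-(nz * np.log2(nz)).sum())


def evenness(H: float, k: int) -> float:
    """Pielou evenness J = H / log2(k); defined as 1 for the degenerate k=1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if H < 0:
        raise ValueError("entropy must be non-negative")
    if k == 1:
        if H > 1e-9:
            raise ValueError("H > 0 impossible with a single class")
        return 1.0
    h_max = math.log2(k)
    if H > h_max + 1e-9:
        raise ValueError(f"H={H} exceeds log2({k})")
    return min(H / h_max, 1.0)


@dataclass
class DiversityResult:
    H: float
    H_max: float
    J: float
    k: int


def diversity(freqs: dict, k: int | None = None) -> DiversityResult:
    """Entropy and evenness of a frequency table.

    ``k`` defaults to the number of possible pair classes (10 for the
    4-class alphabet); pass len(freqs) for "observed" mode.
    """
    k = k if k is not None else len(ALL_PAIR_CLASSES)
    values = list(freqs.values())
    H = shannon_entropy(values)
    return DiversityResult(H=H, H_max=math.log2(k) if k > 1 else 0.0,
                           J=evenness(H, k), k=k)


# ---------------------------------------------------------------------------
# tf-idf filtering

def tfidf_filter(
    pair_type_counts: dict[object, dict[str, int]],
    threshold: float = 1.0,
) -> dict[object, dict[str, float]]:
    """tf-idf weight per pair type over a dataset of structures.

    ``pair_type_counts`` maps pair type -> {structure id: count}. The weight
    is tf(t) · ln(N / df(t)) with tf the total count of the type across the
    dataset, N the number of structures and df the number of structures
    containing the type. A type present in every structure has idf = 0 and
    is always removed for any positive threshold.
    """
    if not pair_type_counts:
        return {}
    structures = set()
    for per_struct in pair_type_counts.values():
        structures.update(per_struct)
    n_structures = len(structures)
    out = {}
    for ptype, per_struct in pair_type_counts.items():
        tf = sum(per_struct.values())
        df = sum(1 for c in per_struct.values() if c > 0)
        idf = math.log(n_structures / df) if df > 0 else 0.0
        score = tf * idf
        out[ptype] = {"tf": float(tf), "df": float(df), "tfidf": score,
                      "retained": score >= threshold}
    return out


# ---------------------------------------------------------------------------
# Pointwise mutual information

def pmi(pair_freq: float, f1: float, f2: float, homogeneous: bool) -> float | None:
    """PMI of one pair class against its independence baseline.

    Returns None (missing) for zero frequencies rather than −∞.
    """
    for f in (pair_freq, f1, f2):
        if f < 0 or f > 1:
            raise ValueError("frequencies must lie in [0, 1]")
    if pair_freq == 0 or f1 == 0 or f2 == 0:
        return None
    denom = f1 * f2 if homogeneous else 2.0 * f1 * f2
    return math.log2(pair_freq / denom)


@dataclass
class PmiCell:
    pair: tuple[str, str]
    pair_freq: float
    f1: float
    f2: float
    pmi: float | None
    tfidf: float
    retained: bool


def region_pmi_analysis(
    complexes: list[dict],
    groups: dict[str, list[int]] | None = None,
    tfidf_threshold: float = 1.0,
    merge_core_support: bool = True,
    class_alphabet: Sequence[str] = PAIR_CLASSES_4,
) -> dict[tuple[str, str], list[PmiCell]]:
    """PMI tables per (region, group) from per-complex class counts.

    Each entry of ``complexes`` is a dict with keys ``"stability"`` and
    ``"regions"``, the latter mapping region name to
    ``{"pairs": Counter[pair class], "residues": Counter[class]}``. Core and
    support are pooled into "core_support" when requested (interior stays
    its own region). ``groups`` maps group name -> complex indices; default
    groups are the stable and transient complexes, with the interior always
    pooled from the whole dataset.

    Per-complex pair-class and residue-class frequencies are averaged across
    the complexes of a group (mean of frequencies, not pooled counts) before
    the PMI formula is applied; the tf-idf filter over the group's complexes
    flags removed cells.
    """
    if not complexes:
        raise ValueError("no complexes provided")

    def norm_region(region: str) -> str:
        if merge_core_support and region in {"core", "support"}:
            return "core_support"
        return region

    if groups is None:
        groups = {
            "stable": [i for i, c in enumerate(complexes) if c["stability"] == "stable"],
            "transient": [i for i, c in enumerate(complexes) if c["stability"] == "transient"],
        }
    for name, idx in groups.items():
        if not idx:
            raise ValueError(f"group {name!r} contains zero complexes")

    regions_present = sorted(
        {norm_region(r) for c in complexes for r in c["regions"]}
    )
    out: dict[tuple[str, str], list[PmiCell]] = {}
    for gname, idx in groups.items():
        for region in regions_present:
            # interior pools the whole dataset regardless of group
            members = range(len(complexes)) if region == "interior" else idx
            pair_freqs: list[dict] = []
            res_freqs: list[dict] = []
            tf_counts: dict[tuple[str, str], dict[str, int]] = {}
            for i in members:
                cx = complexes[i]
                pooled_pairs: Counter = Counter()
                pooled_res: Counter = Counter()
                for raw_region, tables in cx["regions"].items():
                    if norm_region(raw_region) != region:
                        continue
                    pooled_pairs.update(tables["pairs"])
                    pooled_res.update(tables["residues"])
                tot_p, tot_r = sum(pooled_pairs.values()), sum(pooled_res.values())
                if tot_p == 0 or tot_r == 0:
                    continue
                pair_freqs.append({k: v / tot_p for k, v in pooled_pairs.items()})
                res_freqs.append({k: v / tot_r for k, v in pooled_res.items()})
                for ptype, count in pooled_pairs.items():
                    tf_counts.setdefault(ptype, {})[str(i)] = count
            if not pair_freqs:
                continue
            tfidf = tfidf_filter(tf_counts, threshold=tfidf_threshold)
            cells = []
            n = len(pair_freqs)
            for pclass in ALL_PAIR_CLASSES:
                mean_pair = sum(f.get(pclass, 0.0) for f in pair_freqs) / n
                c1, c2 = pclass
                mean_f1 = sum(f.get(c1, 0.0) for f in res_freqs) / n
                mean_f2 = sum(f.get(c2, 0.0) for f in res_freqs) / n
                score = tfidf.get(pclass, {"tfidf": 0.0, "retained": False})
                value = (
                    pmi(mean_pair, mean_f1, mean_f2, homogeneous=(c1 == c2))
                    if score["retained"] else None
                )
                cells.append(
                    PmiCell(pair=pclass, pair_freq=mean_pair, f1=mean_f1, f2=mean_f2,
                            pmi=value, tfidf=score["tfidf"], retained=score["retained"])
                )
            out[(region, gname)] = cells
    return out


# ---------------------------------------------------------------------------
# Generic estimators

def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a proportion, clipped to [0,1]."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("require 0 <= successes <= n and n >= 1")
    from scipy import stats

    z = stats.norm.ppf(0.5 + confidence / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == n else min(1.0, center + half)
    return (lo, hi)


def probability_of_superiority(xs: Sequence[float], ys: Sequence[float]) -> float:
    """P(X > Y) + ½ P(X = Y) over all cross pairs of the two samples."""
    xs, ys = list(xs), list(ys)
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    wins = ties = 0
    for x in xs:
        for y in ys:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    return (wins + 0.5 * ties) / (len(xs) * len(ys))


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    dataset: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap over complexes (the resampling unit).

    Deterministic for a fixed seed; a constant statistic yields a zero-width
    interval.
    """
    data = list(dataset)
    if len(data) < 2:
        raise ValueError("dataset must contain at least 2 elements")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[b] = statistic([data[i] for i in idx])
    alpha = 1.0 - confidence
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))
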