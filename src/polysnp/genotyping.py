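"""Dosage-based co-dominant genotype calling from two-channel intensities.

A two-colour SNP assay reports, per sample and locus, the fraction theta of
signal from the B allele. In a hexaploid the expected theta under dosage d
of 2k amplified allele copies is d/(2k), so cluster centres carry dosage
meaning and are fixed by scenario rather than fitted freely:

* single sub-genome amplified (effective diploid): {0, 1/2, 1} -> AA/AB/BB;
* all sub-genomes amplified, one polymorphic: {0, 1/6, 2/6} ->
  AAAAAA/ABAAAA/BBAAAA;
* all sub-genomes amplified, two polymorphic: {0 .. 4/6} ->
  AAAAAA/AAABAA/AABBAA/ABBBAA/BBBBAA.

Samples are assigned to the nearest admissible centre (with an optional
single re-fit round of per-cluster means to absorb channel skew). Locus
cluster patterns are categorised by occupied-centre counts and a
silhouette-like separation score; cross-assay concordance collapses
co-dominant calls to the allele set each assay detects and ignores missing
data entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GenotypingError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    name: str
    centres: tuple[float, ...]
    labels: tuple[str, ...]
    total_copies: int


SCENARIOS: dict[str, Scenario] = {
    "single_subgenome": Scenario(
        "single_subgenome", (0.0, 0.5, 1.0), ("AA", "AB", "BB"), 2
    ),
    "all_subgenomes_one": Scenario(
        "all_subgenomes_one", (0.0, 1 / 6, 2 / 6), ("AAAAAA", "ABAAAA", "BBAAAA"), 6
    ),
    "all_subgenomes_two": Scenario(
        "all_subgenomes_two", (0.0, 1 / 6, 2 / 6, 3 / 6, 4 / 6),
        ("AAAAAA", "AAABAA", "AABBAA", "ABBBAA", "BBBBAA"), 6
    ),
}

PATTERN_CATEGORIES = (
    "THREE_CLUSTER_SINGLE_SUBGENOME", "THREE_CLUSTER_ALL_SUBGENOMES",
    "TWO_CLUSTER", "FIVE_CLUSTER", "DISPERSED", "MONOMORPHIC", "FAILED",
)


def call_dosage(
    thetas: pd.Series,
    scenario: str,
    refit: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign each sample's theta to the nearest scenario centre.

    thetas is a Series indexed by sample id; NaN entries yield missing calls.
    With refit, occupied clusters' centres are replaced once by their member
    means (per-locus shift for skewed channel ratios) and samples reassigned.
    Returns (calls, fitted centres); calls carry the dosage-class label, the
    cluster index and the residual to the assigned centre.
    """
    if scenario not in SCENARIOS:
        raise GenotypingError(f"unknown scenario {scenario!r}")
    sc = SCENARIOS[scenario]
    values = thetas.to_numpy(dtype=float)
    if values.size == 0 or np.all(np.isnan(values)):
        raise GenotypingError("no intensity values for this locus")
    centres = np.asarray(sc.centres, dtype=float)

    def assign(cn: np.ndarray) -> np.ndarray:
        return np.abs(values[:, None] - cn[None, :]).argmin(axis=1)

    idx = assign(centres)
    if refit:
        fitted = centres.copy()
        for k in range(len(centres)):
            members = values[(idx == k) & ~np.isnan(values)]
            if members.size:
                fitted[k] = members.mean()
        centres = fitted
        idx = assign(centres)
    rows = []
    for sample, theta, k in zip(thetas.index, values, idx):
        missing = bool(np.isnan(theta))
        rows.append({
            "sample_id": sample,
            "theta": theta,
            "class": "" if missing else sc.labels[int(k)],
            "cluster": -1 if missing else int(k),
            "residual": np.nan if missing else float(abs(theta - centres[int(k)])),
        })
    return pd.DataFrame(rows), centres


def _separation(values: np.ndarray, centres: np.ndarray, idx: np.ndarray) -> float:
    """Cluster tightness relative to centre spacing, in [0, 1].

    1 - mean|residual| / (spacing / 4): tight clusters score near 1; values
    spread uniformly over the theta range score near 0, since the mean
    distance to the nearest of evenly spaced centres is spacing / 4.
    """
    if len(centres) < 2:
        return 1.0
    spacing = float(np.min(np.diff(np.sort(centres))))
    resid = float(np.mean(np.abs(values - centres[idx])))
    return 1.0 - resid / (spacing / 4.0)


def classify_locus_pattern(
    thetas: pd.Series,
    min_samples: int = 8,
    min_cluster_size: int = 2,
    separation_threshold: float = 0.3,
    max_missing: float = 0.5,
) -> str:
    """Cluster-pattern category of one locus across the genotyping panel."""
    values = thetas.to_numpy(dtype=float)
    if values.size == 0:
        return "FAILED"
    missing_frac = float(np.isnan(values).mean())
    if missing_frac > max_missing:
        return "FAILED"
    values = values[~np.isnan(values)]
    if values.size < min_samples:
        return "FAILED"

    best = None  # (mean residual, scenario order, scenario, idx)
    for order, sc in enumerate(SCENARIOS.values()):
        centres = np.asarray(sc.centres)
        idx = np.abs(values[:, None] - centres[None, :]).argmin(axis=1)
        resid = float(np.mean(np.abs(values - centres[idx])))
        if best is None or (resid, order) < (best[0], best[1]):
            best = (resid, order, sc, idx)
    _, _, sc, idx = best
    centres = np.asarray(sc.centres)
    occupied = [k for k in range(len(centres)) if (idx == k).sum() >= min_cluster_size]
    if len(occupied) <= 1:
        return "MONOMORPHIC"
    if _separation(values, centres, idx) < separation_threshold:
        return "DISPERSED"
    n_occ = len(occupied)
    if sc.name == "single_subgenome" and n_occ == 3:
        return "THREE_CLUSTER_SINGLE_SUBGENOME"
    if sc.name == "all_subgenomes_one" and n_occ == 3:
        return "THREE_CLUSTER_ALL_SUBGENOMES"
    if sc.name == "all_subgenomes_two" and n_occ >= 4:
        return "FIVE_CLUSTER"
    if n_occ == 2:
        return "TWO_CLUSTER"
    return "DISPERSED"


def allele_set(call: str | float | None) -> frozenset[str] | None:
    """Allele presence of a dosage-class label; None for missing calls."""
    if call is None or (isinstance(call, float) and np.isnan(call)) or call == "":
        return None
    return frozenset(str(call))


def concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Percent of (sample, locus) pairs with identical detected allele sets.

    Calls are compared co-dominantly: each call collapses to the set of
    alleles it detects, so e.g. an effective-diploid AB call agrees with a
    hexaploid ABAAAA call. Pairs missing on either side are excluded from
    both numerator and denominator; loci with no comparable pairs are
    flagged undefined (NaN).
    """
    a = calls_a.set_index(["sample_id", "locus_id"])["class"]
    b = calls_b.set_index(["sample_id", "locus_id"])["class"]
    shared = a.index.intersection(b.index)
    per_locus: dict[str, list[int]] = {}
    for key in shared:
        sa, sb = allele_set(a.loc[key]), allele_set(b.loc[key])
        if sa is None or sb is None:
            continue
        per_locus.setdefault(key[1], []).append(int(sa == sb))
    rows = []
    total_match = total_n = 0
    for locus in sorted({k[1] for k in shared}):
        matches = per_locus.get(locus, [])
        pct = 100.0 * sum(matches) / len(matches) if matches else np.nan
        rows.append({"locus_id": locus, "n_compared": len(matches),
                     "pct_concordant": pct})
        total_match += sum(matches)
        total_n += len(matches)
    overall = 100.0 * total_match / total_n if total_n else np.nan
    return pd.DataFrame(rows, columns=["locus_id", "n_compared", "pct_concordant"]), overall
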