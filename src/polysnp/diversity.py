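"""SNP-based genetic similarity: binary allele scoring, Dice, UPGMA phenogram.

Allele calls are converted to a binary presence matrix (one column per
observed allele per SNP locus), pairwise similarity uses the Dice
coefficient D = 2a / (2a + b + c) over columns scored in both genotypes
(pairwise deletion of missing data), and the phenogram is built by UPGMA on
the dissimilarity 1 - D, producing an ultrametric tree whose merge height is
half the inter-cluster average distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.tree import TreeNode


class DiversityError(ValueError):
    pass


def binary_encode(calls: pd.DataFrame) -> pd.DataFrame:
    """Binary allele-presence matrix from per-genotype allele calls.

    ``calls`` has columns genotype, locus, alleles — ``alleles`` being the
    string of alleles the genotype carries at that locus (e.g. "AB", "A"),
    or empty/NaN for a missing call. Each locus contributes one column per
    allele observed anywhere in the panel; missing calls propagate as NaN
    across all of the locus's columns.
    """
    locus_alleles: dict[str, list[str]] = {}
    for r in calls.itertuples():
        if isinstance(r.alleles, str) and r.alleles:
            locus_alleles.setdefault(str(r.locus), [])
            for al in r.alleles:
                if al not in locus_alleles[str(r.locus)]:
                    locus_alleles[str(r.locus)].append(al)
    genotypes = sorted(calls["genotype"].unique())
    columns = [f"{locus}:{al}" for locus in sorted(locus_alleles)
               for al in sorted(locus_alleles[locus])]
    mat = pd.DataFrame(np.nan, index=genotypes, columns=columns)
    for r in calls.itertuples():
        locus = str(r.locus)
        if locus not in locus_alleles:
            continue
        missing = not (isinstance(r.alleles, str) and r.alleles)
        for al in sorted(locus_alleles[locus]):
            col = f"{locus}:{al}"
            mat.loc[r.genotype, col] = np.nan if missing else float(al in r.alleles)
    return mat


def dice_matrix(binary: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Dice similarity with pairwise deletion of missing columns.

    For two genotypes, a counts columns scored 1 in both, b and c columns
    scored 1 in exactly one; D = 2a / (2a + b + c). Pairs with no mutually
    scored column — or only mutual absences, where the coefficient is
    undefined — are NaN.
    """
    if len(binary) < 2:
        raise DiversityError("similarity needs >= 2 genotypes")
    names = list(binary.index)
    x = binary.to_numpy(dtype=float)
    n = len(names)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not both.any():
                sim[i, j] = sim[j, i] = np.nan
                continue
            xi, xj = x[i, both], x[j, both]
            a = float(np.sum((xi == 1) & (xj == 1)))
            b = float(np.sum((xi == 1) & (xj == 0)))
            c = float(np.sum((xi == 0) & (xj == 1)))
            denom = 2 * a + b + c
            sim[i, j] = sim[j, i] = (2 * a / denom) if denom > 0 else np.nan
    return pd.DataFrame(sim, index=names, columns=names)


def upgma(dissimilarity: pd.DataFrame) -> TreeNode:
    """Ultrametric phenogram by unweighted pair-group averaging.

    Iteratively merges the closest pair (ties: lexicographically smallest
    pair of cluster labels, a label being the smallest member name); the
    merge height is half the inter-cluster distance and inter-cluster
    distances are size-weighted averages, so the result is the standard
    UPGMA tree. NaN dissimilarities are an error.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise DiversityError("dissimilarity matrix contains NaN entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise DiversityError("dissimilarity matrix is not symmetric")
    names = [str(n) for n in dissimilarity.index]
    clusters: dict[str, tuple[TreeNode, int, float]] = {}
    for name in names:
        clusters[name] = (TreeNode(name=name), 1, 0.0)
    dist: dict[frozenset, float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            dist[frozenset((names[i], names[j]))] = float(d[i, j])

    while len(clusters) > 1:
        best = None
        for pair, dv in dist.items():
            a, b = sorted(pair)
            key = (dv, a, b)
            if best is None or key < best:
                best = key
        dv, a, b = best
        (na, sa, ha), (nb, sb, hb) = clusters[a], clusters[b]
        height = dv / 2.0
        na.length = height - ha
        nb.length = height - hb
        parent = TreeNode(children=[na, nb])
        label = min(a, b)
        del clusters[a], clusters[b]
        for other in list(clusters):
            d_ao = dist.pop(frozenset((a, other)))
            d_bo = dist.pop(frozenset((b, other)))
            dist[frozenset((label, other))] = (sa * d_ao + sb * d_bo) / (sa + sb)
        dist.pop(frozenset((a, b)), None)
        clusters[label] = (parent, sa + sb, height)

    root, _, _ = next(iter(clusters.values()))
    root.length = None
    return root


def to_newick(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def root_tip_depths(tree: TreeNode) -> dict[str, float]:
    depths = {}
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        depths[tip.name] = depth
    return depths


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = list(root_tip_depths(tree).values())
    return (max(depths) - min(depths)) <= tol


def top_bipartition(tree: TreeNode) -> tuple[set[str], set[str]]:
    """Leaf sets of the two clades below the root (the deepest split)."""
    kids = tree.children
    if len(kids) != 2:
        raise DiversityError("phenogram root is not a bifurcation")
    return ({t.name for t in kids[0].tips()} or {kids[0].name},
            {t.name for t in kids[1].tips()} or {kids[1].name})
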