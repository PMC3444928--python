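"""Distance-based phylogenetics for progenitor sub-genome attribution.

A putative sub-genome haplotype from the allohexaploid is attributed to the
meadow-fescue-derived P sub-genome or a *glaucescens*-derived G sub-genome
by its position in a neighbour-joining tree built together with orthologous
progenitor sequences. Distances use selectable closed-form models
(p-distance, JC69, K2P) computed over pairwise-comparable columns of a
common-span alignment block. The attribution rule is explicit: the query is
assigned to the progenitor class whose nearest labelled leaf is patristically
closer by a relative margin (default 10%); when only one progenitor class is
present in the tree, the query is assigned to it only as its sister leaf.
Everything else is AMBIGUOUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio.tree import TreeNode

from polysnp.align import Scoring, local_align

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_VALID = set("ACGT")


class PhyloError(ValueError):
    pass


@dataclass
class AlignedBlock:
    """Equal-length aligned sequences over a shared column frame."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise PhyloError("an aligned block needs >= 2 taxa")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise PhyloError(f"aligned sequences of unequal length: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


def align_to_frame(
    frame_name: str,
    frame_seq: str,
    others: dict[str, str],
    scoring: Scoring = Scoring(),
) -> dict[str, str]:
    """Project sequences onto the coordinate frame of one reference sequence.

    Each sequence is overlap-aligned to the frame; its bases are written into
    frame columns, deletions become gaps, and insertions relative to the
    frame are dropped (frame coordinates are preserved). Unaligned overhang
    stays gap. Suitable for closely related orthologs, the regime in which
    sub-genome attribution operates.
    """
    out = {frame_name: frame_seq}
    for name in sorted(others):
        seq = others[name]
        row = ["-"] * len(frame_seq)
        res = local_align(seq, frame_seq, scoring, mode="overlap")
        if res is None:
            out[name] = "".join(row)
            continue
        t = res.target_span[0]
        q = res.query_span[0]
        import re
        for n, op in re.findall(r"(\d+)([=XID])", res.cigar):
            n = int(n)
            if op in "=X":
                row[t: t + n] = seq[q: q + n]
                t += n
                q += n
            elif op == "D":  # frame-only columns -> gap in this row
                t += n
            else:  # 'I': sequence-only bases dropped
                q += n
        out[name] = "".join(row)
    return out


def trim_to_common_span(aligned: dict[str, str]) -> AlignedBlock:
    """Columns covered by every taxon (leading/trailing overhang removed)."""
    taxa = sorted(aligned)
    if len(taxa) < 2:
        raise PhyloError("need >= 2 aligned sequences")
    lo, hi = 0, None
    for name in taxa:
        s = aligned[name]
        nz = [i for i, c in enumerate(s) if c != "-"]
        if not nz:
            raise PhyloError(f"taxon {name!r} has no aligned columns")
        lo = max(lo, nz[0])
        hi = min(hi, nz[-1] + 1) if hi is not None else nz[-1] + 1
    if hi is None or hi <= lo:
        raise PhyloError("empty common span")
    return AlignedBlock(taxa, [aligned[n][lo:hi] for n in taxa])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pair_props(a: str, b: str) -> tuple[float, float, int]:
    """(p_transition, p_transversion, comparable_sites) over gap/N-free columns."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise PhyloError("no pairwise comparable sites")
    return ts / n, tv / n, n


def pairwise_distance(a: str, b: str, model: str = "JC69") -> float:
    P, Q, _ = _pair_props(a, b)
    p = P + Q
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise PhyloError(f"JC69 distance undefined at p = {p:.3f} >= 3/4")
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    if model == "K2P":
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise PhyloError("K2P distance undefined for these proportions")
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    raise PhyloError(f"unknown substitution model {model!r}")


def distance_matrix(block: AlignedBlock, model: str = "JC69") -> tuple[list[str], np.ndarray]:
    n = len(block.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                block.sequences[i], block.sequences[j], model
            )
    return list(block.taxa), d


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(taxa: list[str], dm: np.ndarray) -> TreeNode:
    """Saitou-Nei agglomeration with the standard Q criterion.

    Ties in Q resolve to the lowest index pair, so the construction is
    deterministic. Negative branch-length estimates are clamped to zero and
    the raw value recorded on the node (``raw_length``). The returned tree is
    the usual unrooted representation: a trifurcating root for n >= 3, a
    bifurcating root (each child at d/2) for n = 2.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(taxa)
    if n < 2:
        raise PhyloError("neighbour joining needs >= 2 taxa")
    if dm.shape != (n, n):
        raise PhyloError("distance matrix shape does not match taxa")
    if not np.all(np.isfinite(dm)):
        raise PhyloError("distance matrix has non-finite entries")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise PhyloError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-12):
        raise PhyloError("distance matrix diagonal is not zero")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    D = dm.copy()
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = _clamp(D[0, 1] / 2.0, node)
            root.append(node)
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        nodes[i].length = _clamp(li, nodes[i])
        nodes[j].length = _clamp(lj, nodes[j])
        parent.append(nodes[i])
        parent.append(nodes[j])
        # reuse slot i for the merged node
        newD = D.copy()
        for k in active:
            if k in (i, j):
                continue
            newD[i, k] = newD[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = newD
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = TreeNode()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamp(ln, nodes[idx])
        root.append(nodes[idx])
    return root


def _clamp(length: float, node: TreeNode) -> float:
    if length < 0:
        node.raw_length = float(length)  # negative estimate retained for audit
        return 0.0
    return float(length)


def patristic_distances(tree: TreeNode):
    """Tip-to-tip path-length matrix as (names, ndarray)."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)


# ---------------------------------------------------------------------------
# sub-genome assignment
# ---------------------------------------------------------------------------

@dataclass
class SubgenomeAssignment:
    haplotype: str
    assignment: str  # "P" | "G" | "AMBIGUOUS"
    d_p: float | None
    d_g: float | None
    margin: float


def assign_subgenome(
    tree: TreeNode,
    query: str,
    progenitor_labels: dict[str, list[str]],
    margin: float = 0.10,
) -> SubgenomeAssignment:
    """Nearest-progenitor patristic rule with a relative margin.

    The query is assigned to class P (or G) when its patristic distance to
    the nearest P-labelled (G-labelled) leaf is smaller than the distance to
    the other class by more than the relative margin; with only one class in
    the tree the query must be that progenitor's sister leaf. All other
    configurations are AMBIGUOUS.
    """
    if margin < 0:
        raise PhyloError("margin must be >= 0")
    names, dm = patristic_distances(tree)
    if query not in names:
        raise PhyloError(f"query {query!r} not present in tree")
    qi = names.index(query)

    def nearest(cls: str) -> float | None:
        taxa = [t for t in progenitor_labels.get(cls, []) if t in names]
        if not taxa:
            return None
        return min(dm[qi, names.index(t)] for t in taxa)

    d_p, d_g = nearest("P"), nearest("G")
    if d_p is None and d_g is None:
        raise PhyloError("tree contains no labelled progenitor taxa")
    if d_p is not None and d_g is not None:
        if d_p < (1.0 - margin) * d_g:
            call = "P"
        elif d_g < (1.0 - margin) * d_p:
            call = "G"
        else:
            call = "AMBIGUOUS"
        return SubgenomeAssignment(query, call, d_p, d_g, margin)
    cls = "P" if d_p is not None else "G"
    call = cls if _is_sister_to_class(tree, query, progenitor_labels.get(cls, [])) \
        else "AMBIGUOUS"
    return SubgenomeAssignment(query, call, d_p, d_g, margin)


def _is_sister_to_class(tree: TreeNode, query: str, class_taxa: list[str]) -> bool:
    node = next((t for t in tree.tips() if t.name == query), None)
    if node is None or node.parent is None:
        return False
    siblings = [c for c in node.parent.children if c is not node]
    return any(s.is_tip() and s.name in class_taxa for s in siblings)
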