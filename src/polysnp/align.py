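"""Pairwise alignment primitives and threshold-based read mapping.

Two engines back this module. An affine-gap local aligner
(Bio.Align.PairwiseAligner) provides the optimal-alignment primitive
:func:`local_align`. A unit-cost edit-distance aligner (edlib, infix mode)
provides the fast path used to screen and place reads against references;
its edit path is re-scored with the configured affine scheme, which is exact
for the reported path though that path itself minimises edit distance rather
than affine score. Mapping applies the stringency thresholds of the
discovery pipeline: a placement is accepted only with >= min_overlap aligned
columns at >= min_identity, identity being matches / aligned columns with
gap columns counted.

Template assignment approximates a BLASTN-style search: the best-scoring
template is accepted when its Karlin-Altschul expectation value
E = K * m * n * exp(-lambda * S) falls below a threshold (0.001 by default).
The constants are configuration, not fitted values; only clear accept/reject
regimes are relied upon.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
from Bio import Align

from polysnp.util import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap of length k scores gap_open + k * gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class MappingParams:
    min_overlap: int = 50
    min_identity: float = 0.80
    scoring: Scoring = field(default_factory=Scoring)
    strict_gt: bool = False  # True: thresholds are exclusive (">50 bp" read strictly)
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise AlignmentError("min_overlap must be >= 1")
        if not (0.0 < self.min_identity <= 1.0):
            raise AlignmentError("min_identity must be in (0, 1]")

    def passes(self, overlap: int, identity: float) -> bool:
        if self.strict_gt:
            return overlap > self.min_overlap and identity > self.min_identity
        return overlap >= self.min_overlap and identity >= self.min_identity


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    score: float
    identity: float
    overlap: int  # aligned columns, gap columns included
    query_span: tuple[int, int]  # 0-based half-open
    target_span: tuple[int, int]
    strand: str = "+"
    cigar: str = ""  # extended cigar over =, X, I (query-only), D (target-only)


def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global" if mode == "overlap" else mode
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score on the first gap base; our convention
    # charges gap_open + gap_extend for a length-1 gap.
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    if mode == "overlap":
        a.mode = "global"
        a.end_gap_score = 0.0
    return a


def _walk_alignment(alignment, query: str, target: str):
    """Columns/matches/cigar/spans from a Bio.Align alignment (target, query order)."""
    tblocks, qblocks = alignment.aligned
    if len(tblocks) == 0:
        return 0, 0, "", (0, 0), (0, 0)
    matches = 0
    columns = 0
    cigar_parts: list[str] = []
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            dgap = ts - prev_t  # unaligned target bases -> D columns
            igap = qs - prev_q  # unaligned query bases -> I columns
            if dgap:
                cigar_parts.append(f"{dgap}D")
            if igap:
                cigar_parts.append(f"{igap}I")
            columns += dgap + igap
        run_eq = 0
        run_x = 0
        for t, q in zip(target[ts:te], query[qs:qe]):
            if t == q:
                if run_x:
                    cigar_parts.append(f"{run_x}X")
                    run_x = 0
                run_eq += 1
            else:
                if run_eq:
                    cigar_parts.append(f"{run_eq}=")
                    run_eq = 0
                run_x += 1
        if run_eq:
            cigar_parts.append(f"{run_eq}=")
        if run_x:
            cigar_parts.append(f"{run_x}X")
        matches += sum(1 for t, q in zip(target[ts:te], query[qs:qe]) if t == q)
        columns += te - ts
        prev_t, prev_q = te, qe
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    return columns, matches, "".join(cigar_parts), qspan, tspan


def local_align(
    a: str,
    b: str,
    scoring: Scoring = Scoring(),
    both_strands: bool = False,
    query_id: str = "query",
    target_id: str = "target",
    mode: str = "local",
) -> AlignmentResult | None:
    """Optimal affine-gap alignment of query ``a`` against target ``b``.

    mode "local" is Smith-Waterman-style; mode "overlap" is global with free
    end gaps (used for contig-versus-contig comparison). Returns None when no
    positive-scoring local alignment exists. With both_strands, the reverse
    complement of the query is also tried and the better strand reported;
    query_span is then on the reverse-complemented sequence.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequences")
    aligner = _aligner(scoring, mode)

    def best_for(query: str, strand: str) -> AlignmentResult | None:
        alns = aligner.align(b, query)
        if len(alns) == 0:
            return None
        aln = alns[0]
        columns, matches, cigar, qspan, tspan = _walk_alignment(aln, query, b)
        if columns == 0:
            return None
        return AlignmentResult(
            query_id=query_id, target_id=target_id, score=float(aln.score),
            identity=matches / columns, overlap=columns,
            query_span=qspan, target_span=tspan, strand=strand, cigar=cigar,
        )

    fwd = best_for(a, "+")
    if not both_strands:
        return _none_if_nonpositive(fwd, mode)
    rev = best_for(revcomp(a), "-")
    cands = [r for r in (fwd, rev) if r is not None]
    if not cands:
        return None
    best = max(cands, key=lambda r: (r.score, r.strand == "+"))
    return _none_if_nonpositive(best, mode)


def _none_if_nonpositive(res: AlignmentResult | None, mode: str) -> AlignmentResult | None:
    if res is None:
        return None
    if mode == "local" and res.score <= 0:
        return None
    return res


# ---------------------------------------------------------------------------
# edlib fast path
# ---------------------------------------------------------------------------

def cigar_stats(cigar: str) -> tuple[int, int, int, list[int]]:
    """(columns, matches, mismatches, gap_run_lengths) from an extended cigar."""
    columns = matches = mismatches = 0
    gaps: list[int] = []
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        elif op in "ID":
            gaps.append(n)
        else:  # 'M': edlib never emits it with task="path"
            matches += n
    return columns, matches, mismatches, gaps


def affine_score(cigar: str, scoring: Scoring = Scoring()) -> float:
    """Affine score of an explicit edit path under the configured scheme."""
    _, matches, mismatches, gaps = cigar_stats(cigar)
    score = matches * scoring.match + mismatches * scoring.mismatch
    for g in gaps:
        score += scoring.gap_open + g * scoring.gap_extend
    return score


def edit_align(
    query: str,
    target: str,
    mode: str = "HW",
    scoring: Scoring = Scoring(),
    query_id: str = "query",
    target_id: str = "target",
    strand: str = "+",
) -> AlignmentResult | None:
    """Unit-cost edit alignment (edlib); HW = query infix of target.

    Identity and overlap are computed over the full edit path; the score is
    the affine re-scoring of that path.
    """
    if not query or not target:
        raise AlignmentError("cannot align empty sequences")
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    cigar = res["cigar"] or ""
    columns, matches, _, _ = cigar_stats(cigar)
    if columns == 0:
        return None
    start, end = res["locations"][0]
    return AlignmentResult(
        query_id=query_id, target_id=target_id,
        score=affine_score(cigar, scoring),
        identity=matches / columns, overlap=columns,
        query_span=(0, len(query)), target_span=(int(start), int(end) + 1),
        strand=strand, cigar=cigar,
    )


def map_read(
    read: str,
    references: Mapping[str, str],
    params: MappingParams = MappingParams(),
    read_id: str = "read",
) -> AlignmentResult | None:
    """Best placement of a read on a reference set, or None (unmapped).

    The highest affine score among placements passing the overlap and
    identity thresholds wins; ties break to higher identity, then to the
    lexicographically smaller reference id, so the result is invariant to
    reference ordering.
    """
    if not references:
        raise AlignmentError("empty reference set")
    best: AlignmentResult | None = None
    for ref_id in sorted(references):
        ref = references[ref_id]
        if not ref:
            continue
        candidates = [edit_align(read, ref, "HW", params.scoring, read_id, ref_id, "+")]
        if params.both_strands:
            candidates.append(
                edit_align(revcomp(read), ref, "HW", params.scoring, read_id, ref_id, "-")
            )
        for cand in candidates:
            if cand is None or not params.passes(cand.overlap, cand.identity):
                continue
            if best is None or (cand.score, cand.identity, _neg_id(cand)) > (
                best.score, best.identity, _neg_id(best)
            ):
                best = cand
    return best


def _neg_id(res: AlignmentResult):
    # sortable stand-in for "lexicographically smaller id wins"
    return tuple(-ord(c) for c in res.target_id)


# ---------------------------------------------------------------------------
# BLAST-like template assignment and coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KarlinAltschul:
    """Extreme-value constants for the e-value approximation (+2/-3 defaults)."""

    lam: float = 0.624
    k: float = 0.41


def evalue(score: float, query_len: int, db_len: int, ka: KarlinAltschul = KarlinAltschul()) -> float:
    return ka.k * query_len * db_len * math.exp(-ka.lam * score)


def assign_to_template(
    read: str,
    templates: Mapping[str, str],
    max_evalue: float = 0.001,
    scoring: Scoring = Scoring(),
    ka: KarlinAltschul = KarlinAltschul(),
    min_screen_identity: float = 0.75,
) -> tuple[str, float] | None:
    """Assign a read to the best-scoring template with E <= max_evalue.

    All templates are screened with the unit-cost infix aligner (both
    strands); the best candidate — smallest edit distance, ties to the
    lexicographically smaller id — is then scored. When the candidate's
    screen identity reaches min_screen_identity the affine re-score of its
    edit path is used directly; otherwise the optimal local aligner decides,
    so weakly similar reads are judged by their true best local score.
    """
    if not templates:
        raise AlignmentError("empty template set")
    db_len = sum(len(t) for t in templates.values())
    rc = revcomp(read)
    best = None  # (distance, template_id, oriented_query)
    for tid in sorted(templates):
        tseq = templates[tid]
        for q in (read, rc):
            dist = edlib.align(q, tseq, mode="HW", task="distance")["editDistance"]
            if dist < 0:
                continue
            if best is None or (dist, tid) < (best[0], best[1]):
                best = (dist, tid, q)
    if best is None:
        return None
    _, best_id, q = best
    hit = edit_align(q, templates[best_id], "HW", scoring)
    if hit is not None and hit.identity >= min_screen_identity:
        best_score = hit.score
    else:
        loc = local_align(q, templates[best_id], scoring)
        if loc is None:
            return None
        best_score = loc.score
    e = evalue(best_score, len(read), db_len, ka)
    if e > max_evalue:
        return None
    return best_id, e


def coverage_summary(
    assignments: Mapping[str, Sequence[str]],
    templates: Mapping[str, str],
    genotypes: Sequence[str],
):
    """Per-genotype amplicon coverage: templates hit, % hit, mean reads per hit.

    assignments maps genotype -> list of assigned template ids (one entry per
    assigned read). Genotypes with no reads report 0 covered and a no_reads
    flag rather than an undefined mean.
    """
    import pandas as pd

    n_templates = len(templates)
    rows = []
    for g in genotypes:
        hits = list(assignments.get(g, []))
        covered = len(set(hits))
        rows.append(
            {
                "genotype": g,
                "templates_covered": covered,
                "pct_covered": round(100.0 * covered / n_templates, 2) if n_templates else 0.0,
                "mean_reads_per_template": round(len(hits) / covered, 3) if covered else 0.0,
                "no_reads": len(hits) == 0,
            }
        )
    return pd.DataFrame(rows)
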