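"""Stringent greedy decomposition of amplicon reads into sub-genome contigs.

Homoeologous sub-genomes of an allopolyploid differ at fixed positions
(HSVs), so clustering reads at an identity stringency *below* the
inter-sub-genome identity and *above* the within-sub-genome identity yields
one contig per sub-genome haplotype. The defaults mirror the discovery
pipeline's stringent settings: reads join a cluster only on >= 100
overlapping bases at >= 97% identity, contigs need >= 5 member reads, and
singleton/under-populated clusters are saved as unassembled reads rather
than contigs. The clustering is a greedy centroid scheme standing in for a
full overlap-layout assembler: the parameterisation, not the assembler
internals, is what the pipeline's behaviour depends on.

Consensus calling is per-column majority over the member layout, with ties
encoded as IUPAC ambiguity codes and low-depth (< 2) terminal columns
trimmed. Heterozygous alleles within one sub-genome are *not* merged: if
they diverge beyond the identity threshold they form separate contigs, as
observed in real stringent assemblies (up to nine contigs per amplicon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polysnp.align import AlignmentResult, Scoring, _aligner, local_align
from polysnp.seqio import TaggedRead
from polysnp.util import GAP, iupac_code

import edlib

UNATTRIBUTED = "UNATTRIBUTED"
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, GAP: 4}
_IDX_BASE = "ACGT-"


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class AssemblyParams:
    min_identity: float = 0.97
    min_overlap: int = 100
    min_reads_per_contig: int = 5
    keep_singletons: bool = True
    scoring: Scoring = field(default_factory=Scoring)
    recompute_growth: float = 0.25  # recompute consensus when membership grows by this fraction
    end_trim_min_depth: int = 2


@dataclass
class SubgenomeContig:
    """Assembled putative sub-genome haplotype consensus."""

    contig_id: str
    genotype_id: str
    consensus: str
    member_read_ids: list[str]
    depth: np.ndarray  # per-consensus-position read depth
    amplicon_id: str = UNATTRIBUTED

    @property
    def n_reads(self) -> int:
        return len(self.member_read_ids)


class _Cluster:
    """Running consensus + per-column base counts in consensus coordinates."""

    def __init__(self, read_id: str, seq: str) -> None:
        self.members: list[str] = [read_id]
        self.counts = np.zeros((5, len(seq)), dtype=np.int32)
        for i, b in enumerate(seq):
            self.counts[_BASE_IDX.get(b, 0), i] += 1
        self.consensus = seq
        self._last_recompute = 1

    def add(self, read_id: str, seq: str, aln) -> None:
        """Fold a read into the counts using its overlap alignment to the consensus."""
        tblocks, qblocks = aln.aligned
        self.members.append(read_id)
        cons_len = len(self.consensus)
        prev_t = None
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if prev_t is not None and ts > prev_t:
                self.counts[4, prev_t:ts] += 1  # deletion in read -> gap evidence
            for t, q in zip(range(ts, te), range(qs, qe)):
                self.counts[_BASE_IDX.get(seq[q], 0), t] += 1
            prev_t = te
        # read insertions relative to the consensus are not columned; they are
        # rare pyrosequencing noise and would otherwise shift coordinates
        first_t, last_t = int(tblocks[0][0]), int(tblocks[-1][1])
        first_q, last_q = int(qblocks[0][0]), int(qblocks[-1][1])
        # extend the consensus frame where the read overhangs an end
        if last_t == cons_len and last_q < len(seq):
            tail = seq[last_q:]
            ext = np.zeros((5, len(tail)), dtype=np.int32)
            for i, b in enumerate(tail):
                ext[_BASE_IDX.get(b, 0), i] += 1
            self.counts = np.concatenate([self.counts, ext], axis=1)
            self.consensus = self.consensus + tail
        if first_t == 0 and first_q > 0:
            head = seq[:first_q]
            ext = np.zeros((5, len(head)), dtype=np.int32)
            for i, b in enumerate(head):
                ext[_BASE_IDX.get(b, 0), i] += 1
            self.counts = np.concatenate([ext, self.counts], axis=1)
            self.consensus = head + self.consensus
        if len(self.members) >= self._last_recompute * (1 + 0.25):
            self.recompute_consensus()
            self._last_recompute = len(self.members)

    def recompute_consensus(self) -> None:
        """Majority base per column; ties -> IUPAC; gap-majority columns dropped."""
        keep: list[int] = []
        chars: list[str] = []
        counts = self.counts
        for i in range(counts.shape[1]):
            col = counts[:, i]
            top = int(col.max())
            if top == 0:
                continue
            winners = [j for j in range(5) if col[j] == top]
            if winners == [4]:
                continue  # gap strictly wins: column removed
            bases = [_IDX_BASE[j] for j in winners if j != 4]
            keep.append(i)
            chars.append(bases[0] if len(bases) == 1 else iupac_code(bases))
        self.counts = counts[:, keep]
        self.consensus = "".join(chars)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _overlap_alignment(aligner, consensus: str, seq: str):
    alns = aligner.align(consensus, seq)
    if len(alns) == 0:
        return None, 0, 0.0
    aln = alns[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None, 0, 0.0
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        matches += sum(1 for t, q in zip(consensus[ts:te], seq[qs:qe]) if t == q)
        columns += te - ts
        prev_t, prev_q = te, qe
    return aln, columns, (matches / columns if columns else 0.0)


def cluster_reads(
    reads: list[TaggedRead],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[list[_Cluster], list[TaggedRead]]:
    """Greedy agglomerative clustering of one genotype's (or one bin's) reads.

    Reads are processed longest-first (ties by read id); a read joins the
    first cluster whose running consensus it matches with >= min_overlap
    aligned columns at >= min_identity, else seeds a new cluster. Clusters
    below min_reads_per_contig are dissolved back to unassembled reads.
    Every input read ends up in exactly one cluster or in the unassembled
    set.
    """
    aligner = _aligner(params.scoring, "overlap")
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))
    clusters: list[_Cluster] = []
    membership: dict[int, list[TaggedRead]] = {}
    for read in ordered:
        if not read.sequence:
            continue
        placed = False
        for ci, cluster in enumerate(clusters):
            # cheap screen rejecting unrelated (cross-amplicon) candidates only;
            # the bound is loose because offset overhangs inflate infix distance
            k = int(0.4 * len(read.sequence)
                    + abs(len(cluster.consensus) - len(read.sequence)))
            scr = edlib.align(read.sequence, cluster.consensus, mode="HW",
                              task="distance", k=k)
            if scr["editDistance"] < 0:
                continue
            aln, overlap, identity = _overlap_alignment(
                aligner, cluster.consensus, read.sequence
            )
            if aln is None:
                continue
            if overlap >= params.min_overlap and identity >= params.min_identity:
                cluster.add(read.read_id, read.sequence, aln)
                membership[ci].append(read)
                placed = True
                break
        if not placed:
            clusters.append(_Cluster(read.read_id, read.sequence))
            membership[len(clusters) - 1] = [read]
    kept: list[_Cluster] = []
    unassembled: list[TaggedRead] = []
    for ci, cluster in enumerate(clusters):
        if len(cluster.members) >= params.min_reads_per_contig:
            kept.append(cluster)
        else:
            unassembled.extend(membership[ci])
    return kept, unassembled


def consensus(
    cluster: _Cluster,
    contig_id: str,
    genotype_id: str,
    params: AssemblyParams = AssemblyParams(),
) -> SubgenomeContig | None:
    """Final consensus call: majority/IUPAC per column, low-depth termini trimmed.

    Returns None when trimming leaves fewer than min_overlap columns (the
    contig would be unusable for downstream mapping).
    """
    if not cluster.members:
        raise AssemblyError("cannot call a consensus for an empty cluster")
    cluster.recompute_consensus()
    depth = cluster.depth
    lo, hi = 0, len(depth)
    while lo < hi and depth[lo] < params.end_trim_min_depth:
        lo += 1
    while hi > lo and depth[hi - 1] < params.end_trim_min_depth:
        hi -= 1
    if hi - lo < params.min_overlap:
        return None
    return SubgenomeContig(
        contig_id=contig_id,
        genotype_id=genotype_id,
        consensus=cluster.consensus[lo:hi],
        member_read_ids=list(cluster.members),
        depth=depth[lo:hi].copy(),
    )


def assemble_genotype(
    reads: list[TaggedRead],
    genotype_id: str,
    params: AssemblyParams = AssemblyParams(),
    contig_prefix: str | None = None,
) -> tuple[list[SubgenomeContig], list[TaggedRead]]:
    """Cluster + consensus for one read set; contig ids are deterministic."""
    clusters, unassembled = cluster_reads(reads, params)
    prefix = contig_prefix or genotype_id
    contigs: list[SubgenomeContig] = []
    for i, cluster in enumerate(clusters):
        contig = consensus(cluster, f"{prefix}_c{i + 1:03d}", genotype_id, params)
        if contig is None:
            unassembled.extend(
                TaggedRead(read_id=rid, sequence="") for rid in cluster.members
            )
        else:
            contigs.append(contig)
    return contigs, unassembled


# ---------------------------------------------------------------------------
# contig-to-amplicon attribution
# ---------------------------------------------------------------------------

def _best_reference_hit(
    contig_seq: str,
    references: dict[str, tuple[str, str]],  # ref_name -> (amplicon_id, seq)
    min_identity: float,
    min_overlap: int,
    scoring: Scoring,
    top_k: int = 3,
) -> tuple[str, float] | None:
    """Best passing (amplicon, identity) via edlib screen + affine overlap refine."""
    screened: list[tuple[float, str]] = []
    for name in sorted(references):
        _, seq = references[name]
        res = edlib.align(contig_seq, seq, mode="HW", task="distance")
        dist = res["editDistance"]
        rough = 1.0 - dist / max(len(contig_seq), 1)
        screened.append((rough, name))
    screened.sort(key=lambda t: (-t[0], t[1]))
    best: tuple[float, str] | None = None
    for _, name in screened[:top_k]:
        amp, seq = references[name]
        res = local_align(contig_seq, seq, scoring, mode="overlap")
        if res is None:
            continue
        if res.overlap >= min_overlap and res.identity >= min_identity:
            if best is None or (res.identity, _lex(amp)) > (best[0], _lex(best[1])):
                best = (res.identity, amp)
    if best is None:
        return None
    return best[1], best[0]


def _lex(s: str):
    return tuple(-ord(c) for c in s)


def attribute_contigs(
    contigs: list[SubgenomeContig],
    progenitor_refs: dict[str, dict[str, str]],  # amplicon -> {ref name -> seq}
    fallback_templates: dict[str, str],          # amplicon -> seq
    min_identity: float = 0.80,
    min_overlap: int = 10,
    scoring: Scoring = Scoring(),
) -> list[SubgenomeContig]:
    """Attach each contig to an amplicon via its best progenitor-reference match.

    Contigs are first compared with the progenitor ortholog sequences at the
    relaxed stringency (80% identity, >= 10 bp overlap); contigs without a
    passing progenitor hit are tried against the fallback template set (the
    sequences the amplicons were designed from); the rest stay UNATTRIBUTED.
    """
    primary = {
        f"{amp}|{name}": (amp, seq)
        for amp, refs in progenitor_refs.items()
        for name, seq in refs.items()
    }
    fallback = {f"{amp}|tmpl": (amp, seq) for amp, seq in fallback_templates.items()}
    for contig in contigs:
        hit = _best_reference_hit(
            contig.consensus, primary, min_identity, min_overlap, scoring
        ) if primary else None
        if hit is None and fallback:
            hit = _best_reference_hit(
                contig.consensus, fallback, min_identity, min_overlap, scoring
            )
        contig.amplicon_id = hit[0] if hit else UNATTRIBUTED
    return contigs


def assembly_summary(
    contigs: list[SubgenomeContig],
    n_hsvs: int | None = None,
    morphotype: str = "",
) -> dict:
    """Reference-assembly characteristics: contig counts, lengths, HSV frequency.

    HSV frequency is expressed as one HSV per floor(total consensus bp /
    HSV count) bp, the convention of amplicon reference assemblies; with no
    HSVs it is reported as absent (None).
    """
    n = len(contigs)
    attributed = [c for c in contigs if c.amplicon_id != UNATTRIBUTED]
    amplicons = {c.amplicon_id for c in attributed}
    total_bp = sum(len(c.consensus) for c in contigs)
    out = {
        "morphotype": morphotype,
        "n_contigs": n,
        "mean_contig_length": round(total_bp / n, 1) if n else 0.0,
        "mean_reads_per_contig": round(sum(c.n_reads for c in contigs) / n, 1) if n else 0.0,
        "contigs_per_amplicon": round(len(attributed) / len(amplicons), 2) if amplicons else 0.0,
        "hsvs_per_amplicon": None,
        "hsv_frequency_bp": None,
    }
    if n_hsvs is not None:
        out["hsvs_per_amplicon"] = round(n_hsvs / len(amplicons), 2) if amplicons else 0.0
        out["hsv_frequency_bp"] = (total_bp // n_hsvs) if n_hsvs > 0 else None
    return out
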