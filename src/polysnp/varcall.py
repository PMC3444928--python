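"""Variant tabulation, HSV detection, and rule-based SNP qualification.

The discovery rules are deliberately simple and auditable, matching a
rule-based amplicon pipeline rather than a statistical caller:

* every nucleotide variant observed against the morphotype's reference
  contigs is recorded per genotype (substitutions, insertions, deletions)
  once it clears a support threshold;
* HSV positions — columns at which co-attributed putative sub-genome
  consensuses differ when aligned at relaxed stringency (80% identity,
  >= 10 bp overlap) — are masked;
* a variant qualifies as a SNP only if it is a substitution, is carried by
  more than one but not all panel genotypes, and does not co-locate with an
  HSV; indels are never SNPs. Rejected variants keep a reason code.
* positions fixed between the two morphotypes' reference consensuses and
  monomorphic within every sequenced genotype of each morphotype are
  classified as diagnostic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from polysnp.align import AlignmentResult, Scoring, local_align
from polysnp.assembly import SubgenomeContig

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_IDX_BASE = "ACGT-"

CLASSES = (
    "HSV", "SNP", "DIAGNOSTIC",
    "REJECT_INDEL", "REJECT_SINGLETON", "REJECT_UBIQUITOUS", "REJECT_HSV_COLOCATED",
)

OBSERVATION_COLUMNS = [
    "genotype", "amplicon", "contig", "position", "ref", "alt",
    "type", "depth", "alt_support",
]


class VarcallError(ValueError):
    pass


@dataclass(frozen=True)
class SupportParams:
    """Allele-support thresholds standing in for a mapper's caller internals."""

    min_reads: int = 2
    min_frac: float = 0.05   # fraction of site depth; must sit below the
                             # binomial sampling noise of a one-in-six allele
                             # at typical depth (a true 1/6 signal is often
                             # 2/25 = 8%) and above the error floor, which the
                             # min_reads rule already suppresses
    end_exclude: int = 10    # contig terminal bases excluded from qualification
    same_allele: bool = True # carriers must share the same alternate allele


class ContigCounts:
    """Per-contig base/gap counts accumulated from read placements."""

    def __init__(self, contig_id: str, consensus: str) -> None:
        self.contig_id = contig_id
        self.consensus = consensus
        self.counts = np.zeros((5, len(consensus)), dtype=np.int32)
        self.insertions: dict[int, int] = {}

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def accumulate_placement(counts: ContigCounts, oriented_read: str, placement: AlignmentResult) -> None:
    """Walk an extended cigar (=X consume both; I consumes read; D consumes contig)."""
    t = placement.target_span[0]
    q = 0
    arr = counts.counts
    for n, op in _CIGAR_RE.findall(placement.cigar):
        n = int(n)
        if op in "=X":
            for i in range(n):
                b = _BASE_IDX.get(oriented_read[q + i])
                if b is not None:
                    arr[b, t + i] += 1
            t += n
            q += n
        elif op == "D":  # contig bases absent from the read: deletion evidence
            arr[4, t: t + n] += 1
            t += n
        else:  # 'I': read bases absent from the contig
            counts.insertions[t] = counts.insertions.get(t, 0) + 1
            q += n


def tabulate_variants(
    genotype_id: str,
    placements: list[tuple[str, AlignmentResult]],
    contigs: dict[str, SubgenomeContig],
    support: SupportParams = SupportParams(),
) -> tuple[pd.DataFrame, dict[str, ContigCounts]]:
    """One genotype's variant observations against the reference contigs.

    placements are (oriented read sequence, mapping result) pairs from
    :func:`polysnp.align.map_read`; an observation is emitted for every
    (contig, position, allele) whose support reaches both min_reads and
    min_frac of the site depth. Positions are reported 1-based.
    """
    table: dict[str, ContigCounts] = {}
    for seq, placement in placements:
        contig = contigs.get(placement.target_id)
        if contig is None:
            raise VarcallError(
                f"placement references unknown contig {placement.target_id!r}"
            )
        cc = table.get(placement.target_id)
        if cc is None:
            cc = table[placement.target_id] = ContigCounts(
                placement.target_id, contig.consensus
            )
        accumulate_placement(cc, seq, placement)

    rows = []
    for contig_id in sorted(table):
        cc = table[contig_id]
        contig = contigs[contig_id]
        depth = cc.depth
        cons = cc.consensus
        alt_any = [i for i in range(len(cons))
                   if depth[i] > 0 and cc.counts[_BASE_IDX.get(cons[i], 0), i] != depth[i]]
        for pos in alt_any:
            d = int(depth[pos])
            ref = cons[pos]
            for bi in range(5):
                base = _IDX_BASE[bi]
                if base == ref:
                    continue
                n = int(cc.counts[bi, pos])
                if n >= support.min_reads and n >= support.min_frac * d:
                    rows.append({
                        "genotype": genotype_id, "amplicon": contig.amplicon_id,
                        "contig": contig_id, "position": pos + 1, "ref": ref,
                        "alt": base if base != "-" else "-",
                        "type": "SUB" if base != "-" else "DEL",
                        "depth": d, "alt_support": n,
                    })
        for pos, n in sorted(cc.insertions.items()):
            d = int(depth[pos]) if pos < len(depth) else 0
            if n >= support.min_reads and d and n >= support.min_frac * d:
                rows.append({
                    "genotype": genotype_id, "amplicon": contigs[contig_id].amplicon_id,
                    "contig": contig_id, "position": pos + 1,
                    "ref": cons[pos] if pos < len(cons) else "",
                    "alt": "INS", "type": "INS", "depth": d, "alt_support": n,
                })
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS), table


# ---------------------------------------------------------------------------
# HSV detection between co-attributed contigs
# ---------------------------------------------------------------------------

def detect_hsvs(
    contigs: list[SubgenomeContig],
    min_identity: float = 0.80,
    min_overlap: int = 10,
    scoring: Scoring = Scoring(),
) -> tuple[pd.DataFrame, dict[str, set[int]]]:
    """Differences between co-attributed sub-genome consensuses.

    Every pair of contigs attributed to the same amplicon is aligned with
    free end gaps; pairs overlapping fewer than min_overlap columns or below
    min_identity are not compared. Substitution columns become single-base
    HSVs; indel columns are recorded as HSV spans. Positions are projected
    onto each contig's own coordinates (0-based in the returned mask,
    1-based in the table).
    """
    by_amplicon: dict[str, list[SubgenomeContig]] = {}
    for c in contigs:
        if c.amplicon_id != "UNATTRIBUTED":
            by_amplicon.setdefault(c.amplicon_id, []).append(c)

    rows = []
    mask: dict[str, set[int]] = {c.contig_id: set() for c in contigs}
    for amp in sorted(by_amplicon):
        group = sorted(by_amplicon[amp], key=lambda c: c.contig_id)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                res = local_align(a.consensus, b.consensus, scoring, mode="overlap",
                                  query_id=a.contig_id, target_id=b.contig_id)
                if res is None or res.overlap < min_overlap or res.identity < min_identity:
                    continue
                _project_differences(a, b, res, amp, rows, mask)
    cols = ["amplicon", "contig", "position", "partner_contig", "allele",
            "partner_allele", "kind"]
    return pd.DataFrame(rows, columns=cols), mask


def _project_differences(a, b, res: AlignmentResult, amp, rows, mask) -> None:
    """Mismatch and gap columns of an a-vs-b overlap alignment, per contig."""
    # res was computed as local_align(a.consensus, b.consensus): query = a,
    # target = b; cigar ops: =X both, I consumes a (query), D consumes b.
    qa = res.query_span[0]
    tb = res.target_span[0]
    for n, op in _CIGAR_RE.findall(res.cigar):
        n = int(n)
        if op == "=":
            qa += n
            tb += n
        elif op == "X":
            for k in range(n):
                _add_hsv(rows, mask, amp, a, qa + k, b, tb + k, "SUB")
            qa += n
            tb += n
        elif op == "I":  # bases present in a only
            for k in range(n):
                _add_hsv(rows, mask, amp, a, qa + k, b, min(tb, len(b.consensus) - 1), "INDEL")
            qa += n
        else:  # 'D': bases present in b only
            for k in range(n):
                _add_hsv(rows, mask, amp, a, min(qa, len(a.consensus) - 1), b, tb + k, "INDEL")
            tb += n


def _add_hsv(rows, mask, amp, a, pa, b, pb, kind) -> None:
    allele_a = a.consensus[pa] if pa < len(a.consensus) else "-"
    allele_b = b.consensus[pb] if pb < len(b.consensus) else "-"
    rows.append({"amplicon": amp, "contig": a.contig_id, "position": pa + 1,
                 "partner_contig": b.contig_id, "allele": allele_a,
                 "partner_allele": allele_b, "kind": kind})
    rows.append({"amplicon": amp, "contig": b.contig_id, "position": pb + 1,
                 "partner_contig": a.contig_id, "allele": allele_b,
                 "partner_allele": allele_a, "kind": kind})
    mask[a.contig_id].add(pa)
    mask[b.contig_id].add(pb)


# ---------------------------------------------------------------------------
# SNP qualification
# ---------------------------------------------------------------------------

def qualify_snps(
    observations: pd.DataFrame,
    hsv_mask: dict[str, set[int]],
    panel_size: int,
    contig_lengths: dict[str, int],
    support: SupportParams = SupportParams(),
    morphotype: str = "",
) -> pd.DataFrame:
    """Classify pooled panel observations into SNPs and coded rejects.

    Class per (contig, position, allele): indels are rejected outright; then
    HSV co-location, then ubiquity (carried by every panel genotype), then
    singleton status; what remains is a qualified SNP (carried by >= 2 but
    < panel_size genotypes at a non-HSV site). Contig terminal positions
    (support.end_exclude) are excluded before qualification to avoid
    misalignment artefacts at contig ends.
    """
    if panel_size < 3:
        raise VarcallError("SNP qualification needs a panel of >= 3 genotypes")
    obs = observations.copy()
    if len(obs):
        ends = obs.apply(
            lambda r: r["position"] <= support.end_exclude
            or r["position"] > contig_lengths.get(r["contig"], 10 ** 9) - support.end_exclude,
            axis=1,
        )
        obs = obs[~ends]
    group_cols = ["contig", "position", "alt", "type"] if support.same_allele \
        else ["contig", "position", "type"]
    rows = []
    if len(obs):
        for key, grp in obs.groupby(group_cols, sort=True):
            key = dict(zip(group_cols, key))
            contig = key["contig"]
            pos1 = int(key["position"])
            carriers = sorted(grp["genotype"].unique())
            if key["type"] in ("INS", "DEL"):
                cls = "REJECT_INDEL"
            elif (pos1 - 1) in hsv_mask.get(contig, ()):
                cls = "REJECT_HSV_COLOCATED"
            elif len(carriers) >= panel_size:
                cls = "REJECT_UBIQUITOUS"
            elif len(carriers) == 1:
                cls = "REJECT_SINGLETON"
            else:
                cls = "SNP"
            rows.append({
                "morphotype": morphotype,
                "amplicon": grp["amplicon"].iloc[0],
                "contig": contig, "position": pos1,
                "ref": grp["ref"].iloc[0],
                "alt": key.get("alt", "/".join(sorted(grp["alt"].unique()))),
                "type": key["type"], "class": cls,
                "n_carriers": len(carriers), "carriers": ",".join(carriers),
            })
    cols = ["morphotype", "amplicon", "contig", "position", "ref", "alt", "type",
            "class", "n_carriers", "carriers"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# diagnostic variants between morphotype reference sets
# ---------------------------------------------------------------------------

def classify_diagnostic(
    contigs_a: list[SubgenomeContig],
    contigs_b: list[SubgenomeContig],
    observations_a: pd.DataFrame,
    observations_b: pd.DataFrame,
    depths_a: dict[str, dict[str, np.ndarray]],
    depths_b: dict[str, dict[str, np.ndarray]],
    min_observed: int = 2,
    min_identity: float = 0.80,
    min_overlap: int = 10,
    scoring: Scoring = Scoring(),
    group_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Fixed differences between two groups' reference consensuses.

    A position is diagnostic when the two groups' co-attributed reference
    contigs carry different bases there, no sequenced genotype of either
    group shows a variant at it, and at least min_observed genotypes per
    group actually cover it (the low-coverage guard).
    """
    amp_a = {c.amplicon_id for c in contigs_a if c.amplicon_id != "UNATTRIBUTED"}
    amp_b = {c.amplicon_id for c in contigs_b if c.amplicon_id != "UNATTRIBUTED"}
    shared = sorted(amp_a & amp_b)
    cols = ["amplicon", "contig_a", "position_a", "allele_a",
            "contig_b", "position_b", "allele_b", "class"]
    if not shared:
        warnings.warn("no shared amplicons between the two groups; no diagnostics")
        return pd.DataFrame(columns=cols)

    poly_a = _polymorphic_positions(observations_a)
    poly_b = _polymorphic_positions(observations_b)
    rows = []
    for amp in shared:
        group_a = sorted((c for c in contigs_a if c.amplicon_id == amp),
                         key=lambda c: c.contig_id)
        group_b = sorted((c for c in contigs_b if c.amplicon_id == amp),
                         key=lambda c: c.contig_id)
        for ca in group_a:
            for cb in group_b:
                res = local_align(ca.consensus, cb.consensus, scoring, mode="overlap")
                if res is None or res.overlap < min_overlap or res.identity < min_identity:
                    continue
                pa, pb = res.query_span[0], res.target_span[0]
                for n, op in _CIGAR_RE.findall(res.cigar):
                    n = int(n)
                    if op == "X":
                        for k in range(n):
                            ia, ib = pa + k, pb + k
                            if (ca.contig_id, ia + 1) in poly_a:
                                continue
                            if (cb.contig_id, ib + 1) in poly_b:
                                continue
                            if _n_covering(depths_a, ca.contig_id, ia) < min_observed:
                                continue
                            if _n_covering(depths_b, cb.contig_id, ib) < min_observed:
                                continue
                            rows.append({
                                "amplicon": amp,
                                "contig_a": ca.contig_id, "position_a": ia + 1,
                                "allele_a": ca.consensus[ia],
                                "contig_b": cb.contig_id, "position_b": ib + 1,
                                "allele_b": cb.consensus[ib],
                                "class": "DIAGNOSTIC",
                            })
                    if op in ("=", "X"):
                        pa += n
                        pb += n
                    elif op == "I":
                        pa += n
                    else:
                        pb += n
    return pd.DataFrame(rows, columns=cols)


def _polymorphic_positions(observations: pd.DataFrame) -> set[tuple[str, int]]:
    if not len(observations):
        return set()
    return set(zip(observations["contig"], observations["position"]))


def _n_covering(depths: dict[str, dict[str, np.ndarray]], contig: str, pos: int) -> int:
    n = 0
    for per_contig in depths.values():
        d = per_contig.get(contig)
        if d is not None and pos < len(d) and d[pos] > 0:
            n += 1
    return n


def snp_summary(
    classified: pd.DataFrame,
    n_amplicons: int,
    n_contigs: int,
    morphotype: str = "",
) -> pd.DataFrame:
    """Counts by class plus mean qualified SNPs per amplicon and per contig."""
    rows = []
    counts = classified["class"].value_counts() if len(classified) else {}
    for cls in CLASSES:
        c = int(counts.get(cls, 0))
        rows.append({
            "morphotype": morphotype, "class": cls, "count": c,
            "per_amplicon": round(c / n_amplicons, 2) if (cls == "SNP" and n_amplicons) else "",
            "per_contig": round(c / n_contigs, 2) if (cls == "SNP" and n_contigs) else "",
        })
    return pd.DataFrame(rows, columns=["morphotype", "class", "count",
                                       "per_amplicon", "per_contig"])


# ---------------------------------------------------------------------------
# minimal VCF emission
# ---------------------------------------------------------------------------

def write_vcf(classified: pd.DataFrame, path, reference_name: str = "contigs") -> None:
    """One record per classified substitution site; class and carriers in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference_name}",
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=NCARRIER,Number=1,Type=Integer,Description="Carrier genotypes">',
        '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Carrier genotype ids">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    sub = classified[classified["type"] == "SUB"] if len(classified) else classified
    if len(sub):
        sub = sub.sort_values(["contig", "position", "alt"], kind="mergesort")
        for r in sub.to_dict("records"):
            filt = "PASS" if r["class"] == "SNP" else "REJECT"
            info = (f"CLASS={r['class']};NCARRIER={r['n_carriers']};"
                    f"CARRIERS={r['carriers'] or '.'}")
            lines.append(
                f"{r['contig']}\t{r['position']}\t.\t{r['ref']}\t{r['alt']}\t.\t{filt}\t{info}"
            )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
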