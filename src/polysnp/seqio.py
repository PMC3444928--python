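"""Sequence and table I/O plus barcode demultiplexing.

Reads enter the pipeline as 8 bp barcode-tagged FASTQ/FASTA; demultiplexing
sorts them by genotype and trims the barcode (and an optional ligation
adaptor) from the 5' end, mirroring the read-sorting step that precedes
assembly. All emitted reports use 1-based inclusive coordinates and a
deterministic column order and row sort; internal coordinates everywhere in
the package are 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from polysnp.util import hamming

UNASSIGNED = "UNASSIGNED"


class ParseError(ValueError):
    """Malformed sequence file; message carries the record index / line hint."""


class ConfigError(ValueError):
    """Invalid table or configuration input."""


@dataclass
class TaggedRead:
    """One sequencing read with (after demultiplexing) genotype provenance."""

    read_id: str
    sequence: str
    quality: str | None = None
    genotype_id: str = UNASSIGNED
    barcode: str = ""


@dataclass
class BarcodeTable:
    """Mapping barcode -> (genotype_id, morphotype); barcodes unique, equal length."""

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mapping:
            return
        lengths = {len(b) for b in self.mapping}
        if len(lengths) != 1:
            raise ConfigError(f"barcodes of unequal length: {sorted(lengths)}")
        genotypes = [g for g, _ in self.mapping.values()]
        if len(set(genotypes)) != len(genotypes):
            raise ConfigError("duplicate genotype ids in barcode table")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.mapping)))

    @property
    def genotypes(self) -> list[str]:
        return [g for g, _ in self.mapping.values()]

    def morphotype_of(self, genotype_id: str) -> str:
        for g, m in self.mapping.values():
            if g == genotype_id:
                return m
        raise KeyError(genotype_id)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"barcode", "genotype_id", "morphotype"}
        if not required.issubset(df.columns):
            raise ConfigError(f"barcode table must have columns {sorted(required)}")
        if df["barcode"].duplicated().any():
            raise ConfigError("duplicate barcodes in barcode table")
        return cls({r.barcode: (r.genotype_id, r.morphotype) for r in df.itertuples()})

    def to_tsv(self, path) -> None:
        rows = [
            {"barcode": b, "genotype_id": g, "morphotype": m}
            for b, (g, m) in sorted(self.mapping.items(), key=lambda kv: kv[1][0])
        ]
        write_tsv(pd.DataFrame(rows, columns=["barcode", "genotype_id", "morphotype"]), path)


def demultiplex(
    reads: Iterable[TaggedRead],
    table: BarcodeTable,
    policy: str = "exact",
    adaptor: str = "",
) -> tuple[dict[str, list[TaggedRead]], list[TaggedRead]]:
    """Partition reads by 5' barcode; trim barcode (+ adaptor) from assigned reads.

    policy "exact" requires a perfect barcode prefix; "max-1-mismatch" accepts
    Hamming distance <= 1 but sends a read within distance 1 of two different
    barcodes to the unassigned set. Every input read lands in exactly one
    output set.
    """
    if policy not in ("exact", "max-1-mismatch"):
        raise ConfigError(f"unknown demultiplex policy {policy!r}")
    blen = table.barcode_length
    trim = blen + len(adaptor)
    assigned: dict[str, list[TaggedRead]] = {g: [] for g in table.genotypes}
    unassigned: list[TaggedRead] = []
    for read in reads:
        prefix = read.sequence[:blen]
        hit = table.mapping.get(prefix)
        if hit is None and policy == "max-1-mismatch" and len(prefix) == blen:
            near = [b for b in table.mapping if hamming(prefix, b) <= 1]
            if len(near) == 1:
                hit = table.mapping[near[0]]
        if hit is None:
            unassigned.append(read)
            continue
        genotype, _ = hit
        assigned[genotype].append(
            TaggedRead(
                read_id=read.read_id,
                sequence=read.sequence[trim:],
                quality=read.quality[trim:] if read.quality else None,
                genotype_id=genotype,
                barcode=prefix,
            )
        )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# FASTA / FASTQ round-trip
# ---------------------------------------------------------------------------

def read_sequences(path, fmt: str | None = None) -> list[TaggedRead]:
    """Parse FASTA/FASTQ into TaggedReads (format inferred from suffix)."""
    path = Path(path)
    fmt = fmt or _guess_format(path)
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(TaggedRead(read_id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    except ValueError as exc:
        # Biopython fails at the offending record; report its position
        approx_line = len(records) * (4 if fmt == "fastq" else 2) + 1
        raise ParseError(f"{path}: malformed {fmt} near record {len(records) + 1} "
                         f"(approx. line {approx_line}): {exc}") from exc
    return records


def write_sequences(records: Iterable[TaggedRead], path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _guess_format(path)
    seqrecords = []
    for r in records:
        sr = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            qual = r.quality or "I" * len(r.sequence)
            sr.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seqrecords.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, fmt)


def read_fasta_dict(path) -> dict[str, str]:
    return {r.read_id: r.sequence for r in read_sequences(path, "fasta")}


def write_fasta_dict(seqs: dict[str, str], path) -> None:
    write_sequences(
        [TaggedRead(read_id=k, sequence=v) for k, v in seqs.items()], path, "fasta"
    )


def _guess_format(path: Path) -> str:
    if path.suffix.lower() in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


# ---------------------------------------------------------------------------
# TSV report schemas
# ---------------------------------------------------------------------------

VARIANT_REPORT_COLUMNS = [
    "genotype", "amplicon", "contig", "position", "ref", "alt",
    "type", "depth", "alt_support", "class",
]
COVERAGE_REPORT_COLUMNS = [
    "genotype", "templates_covered", "pct_covered", "mean_reads_per_template", "no_reads",
]
ASSEMBLY_SUMMARY_COLUMNS = [
    "morphotype", "n_contigs", "mean_contig_length", "mean_reads_per_contig",
    "contigs_per_amplicon", "hsvs_per_amplicon", "hsv_frequency_bp",
]
SNP_SUMMARY_COLUMNS = [
    "morphotype", "class", "count", "per_amplicon", "per_contig",
]


def write_tsv(df: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Deterministic TSV emission: fixed column order, sorted rows, '\\n' endings."""
    out = df.copy()
    keys = sort_by if sort_by is not None else [c for c in out.columns]
    if len(out):
        out = out.sort_values(keys, kind="mergesort").reset_index(drop=True)
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def write_reports(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named report tables to <out_dir>/<name>.tsv; returns paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(tables):
        p = out_dir / f"{name}.tsv"
        write_tsv(tables[name], p)
        paths.append(p)
    return paths
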