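"""Small shared helpers: DNA alphabet, IUPAC codes, deterministic hashing."""

from __future__ import annotations

import hashlib

BASES = "ACGT"
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTNRYKMSWacgtn", "TGCANYRMKSWtgcan")

# canonical IUPAC code for each sorted base combination
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code(bases) -> str:
    """IUPAC ambiguity code for a set of bases (gap excluded by caller)."""
    return IUPAC[frozenset(bases)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
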