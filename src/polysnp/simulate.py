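"""Synthetic allohexaploid amplicon populations with full planted truth.

The generator emulates the data a sub-genome-aware SNP discovery pipeline
faces in an outbreeding allohexaploid: each genotype carries six haplotypes
per amplicon (three sub-genomes P, G1, G2 x two alleles). Three variant
classes are planted with disjoint positions (unless collision injection is
enabled):

* HSVs — fixed differences between sub-genomes, placed so that any two
  sub-genomes differ at an expected ``hsv_rate`` per bp (default 1/109,
  matching the density the stringent reference assembly of Continental tall
  fescue exhibits);
* allelic SNPs — segregating within one sub-genome of one morphotype,
  carried by at least 2 and at most n-1 of the morphotype's genotypes, with
  per-genotype dosage in {0,1,2} drawn from a truncated Binomial(2, f);
* diagnostic variants — fixed within each morphotype but differing between
  morphotypes, planted across all three sub-genomes at the site (an
  orthologous fixed difference, visible in a majority consensus).

Reads are pyrosequencing-like: error-perturbed substrings of haplotypes,
with uniform substitution errors plus indel errors confined to homopolymer
runs (>= 3 of one base) and their flanking positions, prefixed with an 8 bp
genotype barcode (pairwise Hamming distance >= 3). Identical configuration
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from polysnp import seqio
from polysnp.seqio import BarcodeTable, TaggedRead
from polysnp.util import BASES

SUBGENOMES = ("P", "G1", "G2")
MORPHOTYPE_NAMES = ("C", "M", "R")
HAPLOTYPES = tuple((s, a) for s in SUBGENOMES for a in (0, 1))


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator configuration; defaults are the bundled study conditions."""

    n_amplicons: int = 20
    amplicon_length: int = 500
    hsv_rate: float = 1.0 / 109.0       # expected HSVs per bp between any two sub-genomes
    snp_rate: float = 10.0              # expected qualifying SNPs per amplicon per morphotype
    diagnostic_rate: float = 2.0        # expected fixed inter-morphotype differences per amplicon
    n_genotypes_per_morphotype: int = 6
    n_morphotypes: int = 2
    depth: int = 25                     # reads per genotype per amplicon
    read_length: int = 450              # Titanium-era pyrosequencing read length
    sub_error: float = 0.005
    homopolymer_indel_rate: float = 0.005
    barcode_length: int = 8
    carrier_allele_freq: float = 0.5
    progenitor_divergence: float = 0.005
    fallback_divergence: float = 0.02
    depth_mode: str = "exact"           # exact | uniform | poisson
    allow_collisions: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.amplicon_length <= 0:
            raise SimConfigError("amplicon_length must be positive")
        if self.n_amplicons <= 0:
            raise SimConfigError("n_amplicons must be positive")
        for name in ("hsv_rate", "sub_error", "homopolymer_indel_rate",
                     "carrier_allele_freq", "progenitor_divergence", "fallback_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.snp_rate < 0 or self.diagnostic_rate < 0:
            raise SimConfigError("rates must be non-negative")
        if self.read_length > self.amplicon_length:
            raise SimConfigError("read_length exceeds amplicon_length")
        if self.read_length <= 0 or self.depth < 1:
            raise SimConfigError("read_length and depth must be positive")
        if self.snp_rate > 0 and self.n_genotypes_per_morphotype < 3:
            raise SimConfigError(
                "qualifying SNPs need >= 3 genotypes per morphotype "
                "(carrier count must fit in [2, n-1])"
            )
        if not (1 <= self.n_morphotypes <= len(MORPHOTYPE_NAMES)):
            raise SimConfigError("n_morphotypes must be 1..3")
        if self.depth_mode not in ("exact", "uniform", "poisson"):
            raise SimConfigError(f"unknown depth_mode {self.depth_mode!r}")

    @property
    def morphotypes(self) -> tuple[str, ...]:
        return MORPHOTYPE_NAMES[: self.n_morphotypes]

    def genotype_ids(self, morphotype: str) -> list[str]:
        return [f"{morphotype}{i + 1}" for i in range(self.n_genotypes_per_morphotype)]

    @property
    def all_genotypes(self) -> list[str]:
        return [g for m in self.morphotypes for g in self.genotype_ids(m)]


@dataclass
class HsvRecord:
    amplicon: str
    position: int  # 0-based
    alleles: dict[str, str]  # sub-genome -> base


@dataclass
class SnpRecord:
    amplicon: str
    morphotype: str
    subgenome: str
    position: int  # 0-based
    ref: str
    alt: str
    dosages: dict[str, int]  # genotype -> 0..2

    @property
    def carriers(self) -> list[str]:
        return [g for g, d in sorted(self.dosages.items()) if d > 0]


@dataclass
class DiagnosticRecord:
    amplicon: str
    position: int  # 0-based
    alleles: dict[str, str]  # morphotype -> base


@dataclass
class TruthSet:
    """Planted truth for a simulated dataset: the acceptance oracle."""

    config: SimConfig
    amplicons: list[str]
    ancestral: dict[str, str]
    subgenome_refs: dict[str, dict[str, str]]               # amplicon -> subgenome -> seq
    morphotype_refs: dict[str, dict[str, dict[str, str]]]   # morphotype -> amplicon -> subgenome
    hsv_records: list[HsvRecord]
    snp_records: list[SnpRecord]
    diagnostic_records: list[DiagnosticRecord]
    progenitors: dict[str, dict[str, str]]                  # amplicon -> {"P","G"} -> seq
    fallback_templates: dict[str, str]
    haplotypes: dict[str, dict[str, dict[tuple[str, int], str]]]
    barcode_table: BarcodeTable
    read_truth: pd.DataFrame | None = None

    def hsv_positions(self) -> set[tuple[str, int]]:
        return {(r.amplicon, r.position) for r in self.hsv_records}

    def variant_table(self) -> pd.DataFrame:
        """All planted variants, 1-based positions, one row per record."""
        rows = []
        for r in self.hsv_records:
            rows.append({"amplicon": r.amplicon, "position": r.position + 1, "class": "HSV",
                         "alleles": "/".join(r.alleles[s] for s in SUBGENOMES),
                         "carriers": "", "subgenome": "", "morphotype": ""})
        for r in self.snp_records:
            rows.append({"amplicon": r.amplicon, "position": r.position + 1, "class": "SNP",
                         "alleles": f"{r.ref}/{r.alt}", "carriers": ",".join(r.carriers),
                         "subgenome": r.subgenome, "morphotype": r.morphotype})
        for r in self.diagnostic_records:
            rows.append({"amplicon": r.amplicon, "position": r.position + 1,
                         "class": "DIAGNOSTIC",
                         "alleles": "/".join(r.alleles[m] for m in self.config.morphotypes),
                         "carriers": "", "subgenome": "", "morphotype": ""})
        cols = ["amplicon", "position", "class", "alleles", "carriers", "subgenome", "morphotype"]
        return pd.DataFrame(rows, columns=cols)


def _amplicon_ids(n: int) -> list[str]:
    return [f"amp{i + 1:03d}" for i in range(n)]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        base = arr[i].decode()
        arr[i] = rng.choice([b for b in BASES if b != base]).encode()
    return arr.tobytes().decode()


def simulate_subgenomes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, dict[str, str]], list[HsvRecord]]:
    """Three sub-genome references per amplicon from one ancestral sequence.

    At each HSV site exactly one sub-genome deviates from the ancestral base,
    so a site selected with probability 1.5 * hsv_rate yields an expected
    pairwise difference density of hsv_rate for every sub-genome pair, and
    the truth set equals the column-wise difference set by construction.
    """
    config.validate()
    amplicons = _amplicon_ids(config.n_amplicons)
    ancestral: dict[str, str] = {}
    refs: dict[str, dict[str, str]] = {}
    hsvs: list[HsvRecord] = []
    p_site = min(1.0, 1.5 * config.hsv_rate)
    for amp in amplicons:
        anc = "".join(rng.choice(list(BASES), size=config.amplicon_length))
        ancestral[amp] = anc
        seqs = {s: list(anc) for s in SUBGENOMES}
        sites = np.flatnonzero(rng.random(config.amplicon_length) < p_site)
        for pos in sites:
            sub = SUBGENOMES[rng.integers(len(SUBGENOMES))]
            ref_base = anc[pos]
            alt = rng.choice([b for b in BASES if b != ref_base])
            seqs[sub][pos] = alt
            hsvs.append(HsvRecord(amp, int(pos),
                                  {s: seqs[s][pos] for s in SUBGENOMES}))
        refs[amp] = {s: "".join(seqs[s]) for s in SUBGENOMES}
    return ancestral, refs, hsvs


def _truncated_dosages(
    n: int, f: float, rng: np.random.Generator, max_tries: int = 10_000
) -> np.ndarray:
    """Per-genotype dosages ~ Binomial(2, f), conditioned on 2 <= carriers <= n-1."""
    for _ in range(max_tries):
        d = rng.binomial(2, f, size=n)
        carriers = int((d > 0).sum())
        if 2 <= carriers <= n - 1:
            return d
    raise SimConfigError("could not sample a qualifying carrier configuration")


def simulate_genotypes(
    subgenome_refs: dict[str, dict[str, str]],
    config: SimConfig,
    rng: np.random.Generator,
    hsv_records: list[HsvRecord] | None = None,
):
    """Morphotype references, per-genotype haplotypes, SNP and diagnostic truth."""
    config.validate()
    amplicons = sorted(subgenome_refs)
    hsv_pos: dict[str, set[int]] = {a: set() for a in amplicons}
    if hsv_records and not config.allow_collisions:
        for r in hsv_records:
            hsv_pos[r.amplicon].add(r.position)

    morphotype_refs: dict[str, dict[str, dict[str, str]]] = {
        m: {a: dict(subgenome_refs[a]) for a in amplicons} for m in config.morphotypes
    }
    used: dict[str, set[int]] = {a: set(hsv_pos[a]) for a in amplicons}
    diagnostics: list[DiagnosticRecord] = []
    snps: list[SnpRecord] = []

    def free_position(amp: str) -> int | None:
        avail = [p for p in range(config.amplicon_length)
                 if config.allow_collisions or p not in used[amp]]
        if not avail:
            return None
        pos = int(rng.choice(avail))
        used[amp].add(pos)
        return pos

    # diagnostic variants: one morphotype deviates across all three sub-genomes
    if config.n_morphotypes >= 2:
        for amp in amplicons:
            for _ in range(rng.poisson(config.diagnostic_rate)):
                pos = free_position(amp)
                if pos is None:
                    continue
                ref_base = subgenome_refs[amp]["P"][pos]
                alt = str(rng.choice([b for b in BASES if b != ref_base]))
                deviant = config.morphotypes[int(rng.integers(1, config.n_morphotypes))]
                for sub in SUBGENOMES:
                    seq = morphotype_refs[deviant][amp][sub]
                    morphotype_refs[deviant][amp][sub] = seq[:pos] + alt + seq[pos + 1:]
                diagnostics.append(DiagnosticRecord(
                    amp, pos,
                    {m: (alt if m == deviant else ref_base) for m in config.morphotypes},
                ))

    # allelic SNPs: one sub-genome of one morphotype, truncated-binomial carriers
    if config.snp_rate > 0:
        for morph in config.morphotypes:
            genotypes = config.genotype_ids(morph)
            for amp in amplicons:
                for _ in range(rng.poisson(config.snp_rate)):
                    pos = free_position(amp)
                    if pos is None:
                        continue
                    sub = SUBGENOMES[int(rng.integers(len(SUBGENOMES)))]
                    ref_base = morphotype_refs[morph][amp][sub][pos]
                    alt = str(rng.choice([b for b in BASES if b != ref_base]))
                    dosages = _truncated_dosages(
                        len(genotypes), config.carrier_allele_freq, rng
                    )
                    snps.append(SnpRecord(
                        amp, morph, sub, pos, ref_base, alt,
                        {g: int(d) for g, d in zip(genotypes, dosages)},
                    ))

    # assemble per-genotype haplotypes (2 alleles x 3 sub-genomes)
    haplotypes: dict[str, dict[str, dict[tuple[str, int], str]]] = {}
    snps_by_key: dict[tuple[str, str], list[SnpRecord]] = {}
    for s in snps:
        snps_by_key.setdefault((s.morphotype, s.amplicon), []).append(s)
    for morph in config.morphotypes:
        for g in config.genotype_ids(morph):
            haplotypes[g] = {}
            for amp in amplicons:
                haps: dict[tuple[str, int], str] = {}
                for sub in SUBGENOMES:
                    base_seq = morphotype_refs[morph][amp][sub]
                    copies = [list(base_seq), list(base_seq)]
                    for s in snps_by_key.get((morph, amp), []):
                        if s.subgenome != sub:
                            continue
                        dose = s.dosages.get(g, 0)
                        for c in range(dose):
                            copies[c][s.position] = s.alt
                    haps[(sub, 0)] = "".join(copies[0])
                    haps[(sub, 1)] = "".join(copies[1])
                haplotypes[g][amp] = haps
    return morphotype_refs, haplotypes, snps, diagnostics


def homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside or adjacent to homopolymer runs >= min_run."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[max(0, i - 1): min(n, j + 1)] = True
        i = j
    return mask


def _generate_barcodes(
    n: int, length: int, rng: np.random.Generator, min_dist: int = 3
) -> list[str]:
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 100_000:
            raise SimConfigError("cannot generate enough well-separated barcodes")
        cand = "".join(rng.choice(list(BASES), size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def _perturb_read(seq: str, hp_mask: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply substitution and homopolymer-indel errors; returns (seq, n_sub, n_indel)."""
    chars = list(seq)
    n_sub = 0
    if config.sub_error > 0:
        for i in np.flatnonzero(rng.random(len(chars)) < config.sub_error):
            chars[i] = str(rng.choice([b for b in BASES if b != chars[i]]))
            n_sub += 1
    n_indel = 0
    if config.homopolymer_indel_rate > 0:
        sites = np.flatnonzero(hp_mask & (rng.random(len(hp_mask)) < config.homopolymer_indel_rate))
        for i in sorted(sites, reverse=True):  # right-to-left keeps indices valid
            if rng.random() < 0.5:
                del chars[i]
            else:
                chars.insert(i, chars[i])
            n_indel += 1
    return "".join(chars), n_sub, n_indel


def simulate_reads(
    truth: TruthSet, config: SimConfig, rng: np.random.Generator
) -> tuple[list[TaggedRead], pd.DataFrame]:
    """Barcode-tagged error-perturbed reads plus a per-read origin truth table."""
    config.validate()
    reads: list[TaggedRead] = []
    rows = []
    counter = 0
    L, rl = config.amplicon_length, config.read_length
    barcode_of = {g: b for b, (g, _) in truth.barcode_table.mapping.items()}
    hp_masks: dict[tuple[str, str, str, int], np.ndarray] = {}
    for morph in config.morphotypes:
        for g in config.genotype_ids(morph):
            for amp in truth.amplicons:
                if config.depth_mode == "poisson":
                    n_reads = int(rng.poisson(config.depth))
                else:
                    n_reads = config.depth
                for k in range(n_reads):
                    if config.depth_mode == "uniform":
                        sub, allele = HAPLOTYPES[k % len(HAPLOTYPES)]
                    else:
                        sub, allele = HAPLOTYPES[int(rng.integers(len(HAPLOTYPES)))]
                    hap = truth.haplotypes[g][amp][(sub, allele)]
                    key = (g, amp, sub, allele)
                    if key not in hp_masks:
                        hp_masks[key] = homopolymer_mask(hap)
                    offset = int(rng.integers(0, L - rl + 1))
                    raw = hap[offset: offset + rl]
                    seq, n_sub, n_indel = _perturb_read(
                        raw, hp_masks[key][offset: offset + rl], config, rng
                    )
                    read_id = f"r{counter:06d}"
                    counter += 1
                    barcode = barcode_of[g]
                    reads.append(TaggedRead(
                        read_id=read_id, sequence=barcode + seq,
                        quality="I" * (len(barcode) + len(seq)),
                    ))
                    rows.append({
                        "read_id": read_id, "genotype": g, "morphotype": morph,
                        "amplicon": amp, "subgenome": sub, "allele": allele,
                        "offset": offset, "n_sub_errors": n_sub, "n_indel_errors": n_indel,
                    })
    read_truth = pd.DataFrame(rows)
    return reads, read_truth


def simulate_intensity(
    dosage_table: pd.DataFrame,
    scenario: str,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-channel theta values from B-allele copy numbers.

    dosage_table needs columns sample_id, locus_id, b_copies. theta is
    (B copies) / (total amplified copies) + Gaussian noise, clipped to [0,1];
    the amplified complement is 2 for the single-sub-genome scenario and 6
    when all sub-genomes amplify.
    """
    from polysnp.genotyping import SCENARIOS  # shared scenario definitions

    if scenario not in SCENARIOS:
        raise SimConfigError(f"unknown intensity scenario {scenario!r}")
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be >= 0")
    total = SCENARIOS[scenario].total_copies
    theta = dosage_table["b_copies"].to_numpy(dtype=float) / total
    if noise_sd > 0:
        theta = theta + rng.normal(0.0, noise_sd, size=len(theta))
    theta = np.clip(theta, 0.0, 1.0)
    out = dosage_table[["sample_id", "locus_id"]].copy()
    out["theta"] = theta
    return out


@dataclass
class SimulatedDataset:
    config: SimConfig
    reads: list[TaggedRead]
    truth: TruthSet


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """One deterministic end-to-end dataset: references, haplotypes, reads, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ancestral, refs, hsvs = simulate_subgenomes(config, rng)
    morphotype_refs, haplotypes, snps, diagnostics = simulate_genotypes(
        refs, config, rng, hsvs
    )
    amplicons = _amplicon_ids(config.n_amplicons)
    progenitors = {
        amp: {
            "P": _mutate(refs[amp]["P"], config.progenitor_divergence, rng),
            "G": _mutate(refs[amp]["G1"], config.progenitor_divergence, rng),
        }
        for amp in amplicons
    }
    fallback = {amp: _mutate(ancestral[amp], config.fallback_divergence, rng)
                for amp in amplicons}
    genotypes = config.all_genotypes
    barcodes = _generate_barcodes(len(genotypes), config.barcode_length, rng)
    table = BarcodeTable({
        bc: (g, g[0]) for bc, g in zip(barcodes, genotypes)
    })
    truth = TruthSet(
        config=config, amplicons=amplicons, ancestral=ancestral,
        subgenome_refs=refs, morphotype_refs=morphotype_refs,
        hsv_records=hsvs, snp_records=snps, diagnostic_records=diagnostics,
        progenitors=progenitors, fallback_templates=fallback,
        haplotypes=haplotypes, barcode_table=table,
    )
    reads, read_truth = simulate_reads(truth, config, rng)
    truth.read_truth = read_truth
    return SimulatedDataset(config=config, reads=reads, truth=truth)


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Materialise a simulated dataset as FASTQ/FASTA/TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reads"] = out / "reads.fastq"
    seqio.write_sequences(dataset.reads, paths["reads"], "fastq")

    paths["barcodes"] = out / "barcodes.tsv"
    dataset.truth.barcode_table.to_tsv(paths["barcodes"])

    paths["templates"] = out / "templates.fasta"
    seqio.write_fasta_dict(
        {amp: dataset.truth.progenitors[amp]["P"] for amp in dataset.truth.amplicons},
        paths["templates"],
    )
    paths["progenitors"] = out / "progenitors.fasta"
    seqio.write_fasta_dict(
        {f"{amp}|{k}": s for amp in dataset.truth.amplicons
         for k, s in dataset.truth.progenitors[amp].items()},
        paths["progenitors"],
    )
    paths["fallback"] = out / "fallback_templates.fasta"
    seqio.write_fasta_dict(
        {amp: dataset.truth.fallback_templates[amp] for amp in dataset.truth.amplicons},
        paths["fallback"],
    )
    paths["subgenomes"] = out / "subgenome_refs.fasta"
    seqio.write_fasta_dict(
        {f"{amp}|{s}": dataset.truth.subgenome_refs[amp][s]
         for amp in dataset.truth.amplicons for s in SUBGENOMES},
        paths["subgenomes"],
    )
    paths["truth_variants"] = out / "truth_variants.tsv"
    seqio.write_tsv(dataset.truth.variant_table(), paths["truth_variants"])

    paths["read_truth"] = out / "truth_reads.tsv"
    seqio.write_tsv(dataset.truth.read_truth, paths["read_truth"], sort_by=["read_id"])

    paths["config"] = out / "sim_config.tsv"
    cfg = pd.DataFrame(
        [{"parameter": k, "value": v} for k, v in sorted(asdict(dataset.config).items())]
    )
    seqio.write_tsv(cfg, paths["config"], sort_by=["parameter"])
    return paths
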