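# polysnp

Sub-genome-aware SNP discovery from amplicon resequencing of allopolyploids.

## The problem

In an outbreeding allohexaploid such as tall fescue (*Festuca arundinacea*,
2n = 6x = 42), every locus exists in three ancestral copies: the
meadow-fescue-derived P sub-genome and two *F. arundinacea* var.
*glaucescens*-derived sub-genomes G₁ and G₂. Resequenced amplicons therefore
mix two kinds of nucleotide variation:

* **homoeologous sequence variants (HSVs)** — fixed differences between
  sub-genomes, present in every individual and useless as genetic markers;
* **allelic SNPs** — variants segregating among individuals *within* one
  sub-genome, the marker class breeders and geneticists actually want.

`polysnp` implements a rule-based discovery pipeline that separates the two:
reads are demultiplexed by 8 bp barcode, assembled per genotype at high
stringency (≥ 97% identity over ≥ 100 bp, ≥ 5 reads per contig) so that
contigs approximate single sub-genome haplotypes, contigs are attributed to
amplicons through progenitor orthologs (80% / 10 bp), HSV positions are
masked, and a variant qualifies as a SNP only when it is a substitution
carried by more than one but not all panel genotypes away from HSV
positions. Positions fixed within each morphotype panel but differing
between panels are classed **diagnostic**. Qualified SNP haplotypes are
attributed to the P or G sub-genomes by neighbour-joining trees built with
progenitor orthologs (p/JC69/K2P distances), two-channel intensity ratios
are converted to co-dominant dosage calls (θ = d/2k for dosage d of 2k
amplified allele copies, e.g. centres {0, 1/6, 2/6} when all sub-genomes
amplify), and panel diversity is summarised with Dice similarity
(D = 2a/(2a+b+c)) and a UPGMA phenogram.

A bundled generator (`polysnp.simulate`) produces synthetic allohexaploid
amplicon populations — sub-genome references at a configurable HSV density
(default 1 per 109 bp), per-genotype haplotypes with planted qualifying
SNPs and diagnostic variants, pyrosequencing-like reads with substitution
and homopolymer-indel errors, and intensity tables — together with the full
planted truth, so every stage is testable without external data.

## Worked example

Run a small simulated discovery end to end (about 15 seconds):

```python
from polysnp import RunConfig, SimConfig, run_discovery

cfg = RunConfig(out_dir="demo_out", seed=11,
                simulate=SimConfig(n_amplicons=6, depth=12, seed=11))
manifest = run_discovery(cfg)
print(manifest.counts)
```

which prints (abridged):

```
input_reads: 864            demux_assigned: 864
contigs_C: 7                contigs_M: 6
snps_C: 47                  snps_M: 49
diagnostic_positions: 9     subgenome_assignments: 47
dosage_accuracy_pct: 100.0
truth_snp_sensitivity: 0.7207
truth_snp_precision: 0.8438
truth_diagnostic_sensitivity: 0.9
```

Reading the numbers: 864 barcode-tagged reads (6 amplicons × 12 genotypes ×
depth 12) all demultiplex exactly; each morphotype's reference genotype
assembles into ~1 contig per amplicon (at 1 HSV/109 bp the sub-genomes are
~99% identical, above the 97% threshold, so they co-assemble and HSVs are
instead eliminated by the not-in-all-genotypes rule); 96 variants qualify
as SNPs, of which 72% of the planted SNPs are recovered at 84% precision —
at this reduced depth of 12 reads per amplicon a heterozygous variant on
one of six haplotypes is often sampled by fewer than two reads, which is
why the bundled study conditions use depth 25, where sensitivity and
precision reach 0.87 and 0.96. Nine inter-morphotype diagnostic positions
and 47 sub-genome attributions are reported, and noise-free intensity data
yields perfect dosage calls. `demo_out/` holds the per-stage TSV/FASTA/VCF
reports, Newick trees, the phenogram, and a `manifest.json` whose per-file
SHA-256 digests are reproduced exactly by a second run with the same
configuration.

The same pipeline is scriptable from the shell (`polysnp run-all --config
run.yaml`), and each stage has its own verb (`simulate`, `demux`,
`coverage`, `assemble`, `hsv`, `attribute`, `genotype`, `diversity`).

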