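# Methods

This note documents the models, rules and numerical choices behind
`polysnp`, and what the bundled simulator does and does not emulate.

## The discovery model

The pipeline targets amplicon resequencing of an outbreeding allohexaploid
with three resident sub-genomes (P, G₁, G₂), two alleles each. Its central
assumption is that fixed inter-sub-genome differences (HSVs) are denser
than within-sub-genome allelic variation, so that assembling one genotype's
reads at a stringency between the within- and between-sub-genome identity
levels decomposes each amplicon into putative single-sub-genome contigs.
All downstream classification is rule-based, not model-based: no genotype
likelihoods, no base-quality recalibration.

Stage order and the thresholds that define the method:

1. **Demultiplexing** — exact 8 bp barcode prefix match (a 1-mismatch
   policy exists but is not the default; the barcode generator guarantees
   pairwise Hamming distance ≥ 3, so exact matching is safe and keeps the
   truth accounting clean). The barcode (plus an optional, config-driven
   adaptor, off by default) is trimmed from the 5′ end.
2. **Coverage / template assignment** — each read is assigned to its best
   amplicon template when the Karlin–Altschul expectation
   E = K·m·n·e^(−λS) of the best affine score is ≤ 0.001. λ = 0.624 and
   K = 0.41 are configured constants appropriate for +2/−3 scoring, not
   fitted values; the pipeline relies only on clear accept/reject regimes.
3. **Stringent assembly** (reference genotype of each morphotype panel) —
   greedy centroid clustering: reads processed longest-first, a read joins
   the first cluster whose running consensus it matches over ≥ 100 aligned
   columns at ≥ 97% identity (gap columns count; identity is
   matches/columns), clusters with < 5 reads dissolve to unassembled
   ("singletons saved"). The running consensus is refreshed whenever
   membership grows by 25%; the final call is per-column majority with ties
   encoded as IUPAC codes and terminal columns of depth < 2 trimmed.
   Heterozygous alleles that diverge beyond the threshold intentionally
   split into separate contigs; no allele merging is attempted.
4. **Attribution** — contigs map to amplicons through progenitor ortholog
   sequences at relaxed stringency (≥ 80% identity, ≥ 10 bp overlap), with
   a second pass against the amplicon design templates for contigs that
   miss, and UNATTRIBUTED otherwise.
5. **HSV detection** — every pair of co-attributed contig consensuses is
   overlap-aligned (free end gaps); pairs below 10 bp overlap or 80%
   identity are not compared. Differing columns are HSVs projected into
   each contig's own coordinates; indel columns mask every position they
   cover (a conservative reading of co-location).
6. **Mapping and tabulation** — every panel genotype's reads map to the
   morphotype's reference contigs (best placement with ≥ 50 bp overlap at
   ≥ 80% identity; the "greater than 50 bp" boundary is implemented
   inclusively with a `strict_gt` switch). Per (contig, position, allele),
   an observation requires ≥ 2 supporting reads *and* ≥ 5% of site depth
   (see "Support thresholds" below).
7. **Qualification** — precedence: indel → HSV-colocated → ubiquitous
   (carried by every panel genotype) → singleton → SNP. SNPs are keyed per
   alternate allele, so tri-allelic sites yield multiple records; carriers
   must share the same alternate allele (relaxable flag). Contig terminal
   10 bp are excluded before qualification, echoing the practice of
   validating only mid-contig variants; the width is configurable.
8. **Diagnostics** — a position is diagnostic when the two panels'
   co-attributed reference consensuses differ there, no genotype of either
   panel shows a variant at it, and ≥ 2 genotypes per panel cover it.
9. **Sub-genome attribution** — for each SNP-bearing contig, the contig
   and the P and G progenitor orthologs are projected onto the P ortholog's
   coordinate frame, trimmed to the columns all taxa cover, and joined by
   neighbour joining on a selectable distance (p, JC69, K2P; JC69 default).
   The query is assigned P (or G) when its patristic distance to the
   nearest P-labelled (G-labelled) leaf is smaller by a relative margin of
   10%; with only one progenitor class in the tree the query must be that
   leaf's sister. Everything else is AMBIGUOUS. The margin is a declared
   operationalisation of "clear affinity", not an estimated quantity. The
   composite-likelihood distance of the original desktop tool is
   deliberately replaced by these closed forms: attribution depends on
   relative, not absolute, distances, and closed forms are testable to
   machine precision. G₁ and G₂ are not distinguished.
10. **Dosage genotyping** — θ (B-allele signal fraction) is assigned to the
    nearest scenario-fixed centre: {0, ½, 1} for single-sub-genome
    amplification, {0, 1/6, 2/6} and {0 … 4/6} when all sub-genomes
    amplify with one or two polymorphic. Centres are not free k-means
    clusters because their identities carry dosage meaning; an optional
    single re-fit round of per-cluster means absorbs channel skew. Locus
    patterns are categorised by occupied centres and a dispersion score
    (mean residual relative to a quarter of the centre spacing — the value
    uniform noise attains); the 0.3 dispersion threshold and minimum
    cluster size 2 are declared parameters. Cross-assay concordance
    collapses calls to detected allele sets and excludes missing pairs
    from numerator and denominator.
11. **Diversity** — per-allele binary scoring (one column per observed
    allele per locus), Dice similarity with pairwise deletion of missing
    data, dissimilarity 1 − D, UPGMA with size-weighted averages and merge
    height d/2, lexicographic tie-breaks. Every emitted phenogram is
    checked for ultrametricity.

Stages communicate via files (TSV with 1-based coordinates, FASTA/FASTQ,
minimal VCF, Newick); internal coordinates are 0-based half-open. A run
manifest records per-stage counts and per-file SHA-256 digests; identical
configuration and seed reproduce identical manifests.

## Support thresholds

The read-mapper used in the original desktop workflow does not document its
caller internals, so the support rule here is explicit: an allele needs
≥ 2 reads and ≥ 5% of site depth. The floor of two reads suppresses the
0.5% substitution-error process (expected error support per allele at depth
25 is ≈ 0.04 reads, and a qualified SNP additionally needs two genotypes
showing the same allele). The fraction floor must sit *below* the binomial
sampling noise of a one-in-six allele at working depth — a true
heterozygous dosage-1 signal is frequently 2/25 = 8% — because a higher
floor silently deletes true carriers; in a co-assembled hexaploid contig
that failure mode is worse than noise, since an HSV missing one carrier
stops looking ubiquitous and leaks into the SNP class. 5% satisfies both
constraints with margin. Both values are configurable.

## Why one contig per amplicon at 1 HSV/109 bp

At the emulated HSV density the sub-genomes are ~99.1% identical, above the
97% clustering threshold, so the stringent assembly yields a single
co-assembled contig per amplicon and HSV sites surface as intra-contig
variants in *every* genotype — which the not-in-all-genotypes rule then
rejects. Decomposition into one contig per sub-genome occurs when pairwise
identity falls below the threshold (the assembler checks enforce exactly
three clusters at ≤ 96% identity). Both regimes are exercised by the test
suite; the interplay is a property of identity-threshold clustering, and
real stringent assemblers that exploit local mismatch patterns can separate
haplotypes at somewhat higher identities.

## The simulator

What it emulates: three sub-genome references derived from one ancestral
sequence (uniform base composition) with exactly one deviating sub-genome
per HSV site, placed so each sub-genome pair differs at an expected
`hsv_rate` per bp; morphotype reference sets carrying diagnostic
substitutions; per-genotype haplotypes with qualifying SNPs whose
per-genotype dosage is Binomial(2, f = 0.5) conditioned on a carrier count
in [2, n−1]; reads as error-perturbed haplotype substrings (uniform offset,
uniform haplotype choice; exact-count, deterministic-cycling and Poisson
depth modes) with uniform substitutions and indels confined to homopolymer
runs ≥ 3 and their flanks; 8 bp barcodes at pairwise Hamming ≥ 3; constant
quality strings (qualities are not used downstream); progenitor orthologs
as sub-genome references mutated at 0.5% (P from P, G from G₁) and
fallback templates as the ancestral sequence mutated at 2%; and intensity
tables in θ space.

Default study conditions: 20 amplicons × 500 bp, 1 HSV/109 bp, two
morphotype panels of 6 genotypes, Poisson-mean 10 qualifying SNPs and 2
diagnostic variants per amplicon per panel, depth 25, read length 450
(Titanium-era pyrosequencing), 0.5% substitution + 0.5% homopolymer-indel
error. Reduced problem sizes used in the test suite (fewer amplicons,
depth 10–12) exercise the same code paths; the reference conditions are
what the headline recovery numbers refer to.

What it does not emulate — and hence what passing tests do not show about
real data: flowgram-level signal artefacts beyond the homopolymer-indel
rate; paralogous gene families (a known confounder that inflates contig
counts); coverage bias from shearing and barcode-ligation efficiency
(depth varies 9–146× in real panels); chimeric reads; primer-site
divergence that silences whole sub-genomes; and real channel normalisation
for intensity data (θ is simulated directly). Diagnostic variants are
planted across all three sub-genomes of the deviating morphotype
(orthologous fixed differences); a fixed difference confined to a single
sub-genome would be invisible in a majority consensus of co-assembled
sub-genomes, and its detection is not claimed.

Allele-frequency caveat: the truncated-binomial carrier model is a
stand-in, not an inference about any real panel's frequency spectrum.

## Numerical and tie-break conventions

* Affine scoring match +2, mismatch −3, gap open −5, gap extend −2
  (a length-k gap costs open + k·extend); all configurable.
* Unit-cost edit alignment (edlib) places reads; the affine re-score of
  its path ranks placements. The path minimises edit distance, not affine
  score — exact for the reported path, approximate for ranking; the
  optimal affine aligner backs the `local_align` primitive and all
  contig-versus-contig comparisons.
* Deterministic tie-breaks everywhere: mapping prefers higher score, then
  higher identity, then the lexicographically smaller reference id;
  template assignment breaks equal screens lexicographically; NJ takes the
  lowest index pair on equal Q; UPGMA the lexicographically smallest pair.
* Negative NJ branch estimates are clamped to zero with the raw value
  recorded on the node (`raw_length`).
* JC69 is undefined at p ≥ 3/4 and raises; K2P raises when its logarithms'
  arguments are non-positive. Gap/N columns are excluded pairwise.
* Dice of two rows with no mutually scored columns, or only mutual
  absences, is undefined and reported as missing rather than invented.
* Degenerate inputs fail loudly: empty read sets, empty clusters,
  non-symmetric matrices, panels of fewer than three genotypes for SNP
  qualification (the in-more-than-one-but-not-all rule is vacuous below
  three).

## Design choices that were genuinely open

* **Greedy clustering stands in for a full overlap-layout assembler.** The
  method's substance is the parameterisation (97% / 100 bp / 5 reads), not
  assembler internals; a greedy centroid scheme honours the thresholds and
  is order-deterministic (longest first, first passing cluster wins).
* **Reads are binned by amplicon template before clustering** in the
  pipeline. Unrelated ~500 bp amplicons cannot co-cluster at 97%, so
  binning changes no outcome, only cost; the clustering function itself
  accepts unbinned input and is tested that way.
* **Only each panel's reference genotype is assembled de novo**; remaining
  genotypes are mapped against its contigs, mirroring the
  reference-plus-mapping structure of the original workflow.
* **Truth evaluation counts either planted allele as a recovery** at a
  planted SNP position: when the panel's reference genotype is itself a
  carrier, the contig consensus may carry the alternate base and
  non-carriers then surface as carriers of the complementary allele. The
  marker is discovered either way.
* **Per-allele binary scoring** for diversity (not per-genotype-class),
  with a flag left for the alternative reading.

## Known limitations

* At realistic HSV densities the identity-threshold assembler does not
  separate sub-genomes (see above); sub-genome attribution of co-assembled
  consensuses is correspondingly often AMBIGUOUS, and the ≥ 95%
  P-attribution property is demonstrated on planted haplotypes.
* The e-value is an extreme-value approximation with configured constants,
  not a reimplementation of BLAST statistics.
* Homopolymer indels longer than one base, and indel *markers* generally,
  are out of scope (indels are never SNPs by rule).
* The pipeline processes morphotype panels independently and compares them
  only for diagnostics; no joint calling across panels.
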