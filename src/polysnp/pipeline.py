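"""End-to-end discovery pipeline: demultiplex -> coverage -> stringent
assembly -> amplicon attribution -> HSV detection -> mapping -> SNP
qualification -> diagnostics -> attribution trees -> dosage genotyping ->
diversity -> reports.

Stages communicate through files in the declared formats so each stage is
independently runnable and the whole run is reproducible: identical
configuration (seed included) reproduces byte-identical outputs, which the
run manifest certifies with per-file SHA-256 digests. When the input is the
bundled simulator, a truth-comparison report (sensitivity/precision per
variant class against the planted truth) is produced as well.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polysnp import seqio
from polysnp.align import (KarlinAltschul, MappingParams, Scoring,
                           assign_to_template, local_align, map_read)
from polysnp.assembly import (AssemblyParams, SubgenomeContig, assemble_genotype,
                              assembly_summary, attribute_contigs)
from polysnp.diversity import (binary_encode, dice_matrix, is_ultrametric,
                               to_newick, upgma)
from polysnp.genotyping import SCENARIOS, call_dosage, classify_locus_pattern, concordance
from polysnp.phylo import (align_to_frame, assign_subgenome, distance_matrix,
                           nj_tree, trim_to_common_span)
from polysnp.seqio import BarcodeTable, TaggedRead
from polysnp.simulate import SimConfig, simulate_dataset, simulate_intensity, write_dataset
from polysnp.util import revcomp, sha256_file
from polysnp.varcall import (OBSERVATION_COLUMNS, SupportParams, classify_diagnostic,
                             detect_hsvs, qualify_snps, snp_summary,
                             tabulate_variants, write_vcf)

logger = logging.getLogger("polysnp")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One configuration for a full discovery run.

    Exactly one of ``simulate`` (a generator configuration) or the input
    paths (reads/barcodes/templates/progenitors) must be provided. Parameter
    defaults are the pipeline's standard stringencies: 97% / 100 bp / 5
    reads for sub-genome assembly, 80% / 10 bp for contig attribution and
    HSV detection, >= 50 bp at >= 80% for genotype mapping, e-value <= 0.001
    for template assignment.
    """

    out_dir: str = "polysnp_out"
    seed: int = 0
    # external inputs (alternative to `simulate`)
    reads_path: str | None = None
    barcodes_path: str | None = None
    templates_path: str | None = None
    progenitors_path: str | None = None
    fallback_path: str | None = None
    simulate: SimConfig | None = None
    # stage parameters
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    support: SupportParams = field(default_factory=SupportParams)
    hsv_min_identity: float = 0.80
    hsv_min_overlap: int = 10
    attribution_min_identity: float = 0.80
    attribution_min_overlap: int = 10
    max_evalue: float = 0.001
    diagnostic_min_observed: int = 2
    nj_model: str = "JC69"
    assignment_margin: float = 0.10
    intensity_noise_sd: float = 0.03
    intensity_scenario: str = "all_subgenomes_one"
    max_intensity_loci: int = 30
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.reads_path is not None
        if has_paths == (self.simulate is not None):
            raise PipelineError(
                "provide exactly one of `simulate` or external input paths"
            )
        if has_paths and not (self.barcodes_path and self.templates_path
                              and self.progenitors_path):
            raise PipelineError("external input needs reads, barcodes, templates "
                                "and progenitors paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if kwargs.get("simulate") is not None:
            kwargs["simulate"] = SimConfig(**kwargs["simulate"])
        for key, klass in (("assembly", AssemblyParams), ("mapping", MappingParams),
                           ("support", SupportParams)):
            if isinstance(kwargs.get(key), dict):
                sub = dict(kwargs[key])
                if "scoring" in sub and isinstance(sub["scoring"], dict):
                    sub["scoring"] = Scoring(**sub["scoring"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict
    files: dict  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


def _setup_logging(out: Path, level: str) -> logging.Handler:
    logger.setLevel(level.upper())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    return handler


def run_discovery(config: RunConfig) -> RunManifest:
    """Execute the full discovery pipeline; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    counts: dict = {}
    try:
        logger.info("run configuration: %s",
                    json.dumps(config.to_dict(), sort_keys=True, default=str))

        # ------------------------------------------------------------------
        # stage 0: inputs (simulate or load)
        # ------------------------------------------------------------------
        truth = None
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate)
            dataset = simulate_dataset(sim)
            write_dataset(dataset, out / "sim")
            reads = dataset.reads
            truth = dataset.truth
            barcode_table = truth.barcode_table
            templates = {a: truth.progenitors[a]["P"] for a in truth.amplicons}
            progenitor_refs = {a: dict(truth.progenitors[a]) for a in truth.amplicons}
            fallback = dict(truth.fallback_templates)
        else:
            reads = seqio.read_sequences(config.reads_path)
            barcode_table = BarcodeTable.from_tsv(config.barcodes_path)
            templates = seqio.read_fasta_dict(config.templates_path)
            progenitor_refs = {}
            for name, seq in seqio.read_fasta_dict(config.progenitors_path).items():
                amp, _, label = name.partition("|")
                progenitor_refs.setdefault(amp, {})[label or "P"] = seq
            fallback = (seqio.read_fasta_dict(config.fallback_path)
                        if config.fallback_path else {})
        if not reads:
            raise PipelineError("input stage: empty read set")
        counts["input_reads"] = len(reads)
        logger.info("input: %d reads, %d templates", len(reads), len(templates))

        # ------------------------------------------------------------------
        # stage 1: demultiplex
        # ------------------------------------------------------------------
        assigned, unassigned = seqio.demultiplex(reads, barcode_table, "exact")
        counts["demux_assigned"] = sum(len(v) for v in assigned.values())
        counts["demux_unassigned"] = len(unassigned)
        demux_dir = out / "demux"
        demux_dir.mkdir(exist_ok=True)
        for g in sorted(assigned):
            seqio.write_sequences(assigned[g], demux_dir / f"{g}.fastq", "fastq")
        morphotypes: dict[str, list[str]] = {}
        for g in sorted(assigned):
            morphotypes.setdefault(barcode_table.morphotype_of(g), []).append(g)
        logger.info("demultiplexed: %d assigned / %d unassigned; morphotypes %s",
                    counts["demux_assigned"], len(unassigned), sorted(morphotypes))

        # ------------------------------------------------------------------
        # stage 2: coverage / template binning
        # ------------------------------------------------------------------
        ka = KarlinAltschul()
        bins: dict[str, dict[str, list[TaggedRead]]] = {}
        template_hits: dict[str, list[str]] = {}
        for g in sorted(assigned):
            bins[g] = {}
            hits = []
            for read in assigned[g]:
                res = assign_to_template(read.sequence, templates,
                                         config.max_evalue, config.mapping.scoring, ka)
                if res is None:
                    continue
                amp, _ = res
                hits.append(amp)
                bins[g].setdefault(amp, []).append(read)
            template_hits[g] = hits
        from polysnp.align import coverage_summary
        coverage = coverage_summary(template_hits, templates, sorted(assigned))
        seqio.write_tsv(coverage, out / "coverage.tsv", sort_by=["genotype"])
        counts["reads_assigned_to_templates"] = sum(len(h) for h in template_hits.values())

        # ------------------------------------------------------------------
        # stage 3: stringent assembly of the reference genotype per morphotype
        # ------------------------------------------------------------------
        contigs_by_morph: dict[str, list[SubgenomeContig]] = {}
        for morph in sorted(morphotypes):
            ref_genotype = sorted(morphotypes[morph])[0]
            contigs: list[SubgenomeContig] = []
            n_unassembled = 0
            for amp in sorted(bins[ref_genotype]):
                cs, un = assemble_genotype(
                    bins[ref_genotype][amp], ref_genotype, config.assembly,
                    contig_prefix=f"{morph}_{amp}",
                )
                contigs.extend(cs)
                n_unassembled += len(un)
            attribute_contigs(contigs, progenitor_refs, fallback,
                              config.attribution_min_identity,
                              config.attribution_min_overlap,
                              config.assembly.scoring)
            contigs_by_morph[morph] = contigs
            counts[f"contigs_{morph}"] = len(contigs)
            counts[f"unassembled_{morph}"] = n_unassembled
            seqio.write_fasta_dict(
                {f"{c.contig_id}|{c.amplicon_id}": c.consensus for c in contigs},
                out / f"contigs_{morph}.fasta",
            )
            logger.info("assembled %s (reference %s): %d contigs, %d unassembled reads",
                        morph, ref_genotype, len(contigs), n_unassembled)

        # ------------------------------------------------------------------
        # stage 4: HSV detection between co-attributed contigs
        # ------------------------------------------------------------------
        hsv_tables = []
        hsv_masks: dict[str, dict[str, set[int]]] = {}
        for morph in sorted(contigs_by_morph):
            hsv_df, mask = detect_hsvs(contigs_by_morph[morph],
                                       config.hsv_min_identity,
                                       config.hsv_min_overlap,
                                       config.assembly.scoring)
            hsv_df.insert(0, "morphotype", morph)
            hsv_tables.append(hsv_df)
            hsv_masks[morph] = mask
            counts[f"hsv_positions_{morph}"] = int(
                sum(len(v) for v in mask.values())
            )
        hsv_all = pd.concat(hsv_tables, ignore_index=True) if hsv_tables else pd.DataFrame()
        seqio.write_tsv(hsv_all, out / "hsv.tsv")

        # assembly summary (needs HSV counts)
        summary_rows = []
        for morph in sorted(contigs_by_morph):
            summary_rows.append(assembly_summary(
                contigs_by_morph[morph],
                counts[f"hsv_positions_{morph}"] // 2 if counts[f"hsv_positions_{morph}"] else 0,
                morph,
            ))
        seqio.write_tsv(pd.DataFrame(summary_rows), out / "assembly_summary.tsv",
                        sort_by=["morphotype"])

        # ------------------------------------------------------------------
        # stage 5: per-genotype mapping and variant tabulation
        # ------------------------------------------------------------------
        observations: dict[str, pd.DataFrame] = {}
        depths: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for morph in sorted(contigs_by_morph):
            contig_map = {c.contig_id: c for c in contigs_by_morph[morph]}
            refs = {cid: c.consensus for cid, c in contig_map.items()}
            per_geno_tables = []
            depths[morph] = {}
            if not refs:
                observations[morph] = pd.DataFrame(columns=seqio.VARIANT_REPORT_COLUMNS[:-1])
                continue
            for g in sorted(morphotypes[morph]):
                placements = []
                for read in assigned[g]:
                    res = map_read(read.sequence, refs, config.mapping, read.read_id)
                    if res is None:
                        continue
                    oriented = read.sequence if res.strand == "+" else revcomp(read.sequence)
                    placements.append((oriented, res))
                obs, table = tabulate_variants(g, placements, contig_map, config.support)
                per_geno_tables.append(obs)
                depths[morph][g] = {cid: cc.depth for cid, cc in table.items()}
            observations[morph] = (pd.concat(per_geno_tables, ignore_index=True)
                                   if per_geno_tables else pd.DataFrame())
            counts[f"observations_{morph}"] = len(observations[morph])
        nonempty_obs = [observations[m] for m in sorted(observations)
                        if len(observations[m])]
        obs_all = (pd.concat(nonempty_obs, ignore_index=True)
                   if nonempty_obs else pd.DataFrame(columns=OBSERVATION_COLUMNS))
        seqio.write_tsv(obs_all, out / "observations.tsv")

        # ------------------------------------------------------------------
        # stage 6: SNP qualification per morphotype panel
        # ------------------------------------------------------------------
        classified_tables = []
        for morph in sorted(contigs_by_morph):
            panel = sorted(morphotypes[morph])
            lengths = {c.contig_id: len(c.consensus) for c in contigs_by_morph[morph]}
            if len(panel) < 3:
                logger.warning("panel %s has %d genotypes; SNP qualification skipped",
                               morph, len(panel))
                continue
            classified = qualify_snps(observations[morph], hsv_masks[morph],
                                      len(panel), lengths, config.support, morph)
            classified_tables.append(classified)
            counts[f"snps_{morph}"] = int((classified["class"] == "SNP").sum()) \
                if len(classified) else 0
        classified_all = (pd.concat(classified_tables, ignore_index=True)
                          if classified_tables else pd.DataFrame())
        seqio.write_tsv(classified_all, out / "classified.tsv")
        write_vcf(classified_all if len(classified_all) else
                  pd.DataFrame(columns=["contig", "position", "ref", "alt", "type",
                                        "class", "n_carriers", "carriers"]),
                  out / "variants.vcf")
        counts["snp_calls"] = int((classified_all["class"] == "SNP").sum()) \
            if len(classified_all) else 0

        # snp summary
        sum_rows = []
        for morph in sorted(contigs_by_morph):
            cls = classified_all[classified_all["morphotype"] == morph] \
                if len(classified_all) else pd.DataFrame()
            amps = {c.amplicon_id for c in contigs_by_morph[morph]
                    if c.amplicon_id != "UNATTRIBUTED"}
            sum_rows.append(snp_summary(cls, len(amps), len(contigs_by_morph[morph]), morph))
        seqio.write_tsv(pd.concat(sum_rows, ignore_index=True) if sum_rows else pd.DataFrame(),
                        out / "snp_summary.tsv", sort_by=["morphotype", "class"])

        # ------------------------------------------------------------------
        # stage 7: diagnostic variants between morphotype panels
        # ------------------------------------------------------------------
        diag_tables = []
        morphs = sorted(contigs_by_morph)
        for i in range(len(morphs)):
            for j in range(i + 1, len(morphs)):
                a, b = morphs[i], morphs[j]
                diag = classify_diagnostic(
                    contigs_by_morph[a], contigs_by_morph[b],
                    observations[a], observations[b],
                    depths.get(a, {}), depths.get(b, {}),
                    config.diagnostic_min_observed,
                    config.hsv_min_identity, config.hsv_min_overlap,
                    config.assembly.scoring, (a, b),
                )
                diag.insert(0, "group_b", b)
                diag.insert(0, "group_a", a)
                diag_tables.append(diag)
        diagnostics = (pd.concat(diag_tables, ignore_index=True)
                       if diag_tables else pd.DataFrame())
        seqio.write_tsv(diagnostics, out / "diagnostics.tsv")
        counts["diagnostic_positions"] = len(diagnostics)

        # ------------------------------------------------------------------
        # stage 8: sub-genome attribution trees (first morphotype panel)
        # ------------------------------------------------------------------
        tree_lines = []
        assign_rows = []
        if morphs and len(classified_all):
            morph = morphs[0]
            snps = classified_all[(classified_all["morphotype"] == morph)
                                  & (classified_all["class"] == "SNP")]
            contig_map = {c.contig_id: c for c in contigs_by_morph[morph]}
            for amp in sorted(snps["amplicon"].unique()):
                if amp not in progenitor_refs or "P" not in progenitor_refs[amp]:
                    continue
                frame = progenitor_refs[amp]["P"]
                others = {f"G|{amp}": progenitor_refs[amp].get("G", "")}
                others = {k: v for k, v in others.items() if v}
                queries = {c.contig_id: c.consensus
                           for c in contigs_by_morph[morph] if c.amplicon_id == amp}
                if not queries:
                    continue
                aligned = align_to_frame(f"P|{amp}", frame, {**others, **queries},
                                         config.assembly.scoring)
                try:
                    block = trim_to_common_span(aligned)
                    taxa, dm = distance_matrix(block, config.nj_model)
                    tree = nj_tree(taxa, dm)
                except Exception as exc:  # non-overlapping contigs etc.
                    logger.warning("attribution skipped for %s: %s", amp, exc)
                    continue
                tree_lines.append(f"{amp}\t{to_newick(tree)}")
                labels = {"P": [f"P|{amp}"], "G": [f"G|{amp}"] if others else []}
                for snp in snps[snps["amplicon"] == amp].to_dict("records"):
                    cid = snp["contig"]
                    if cid not in block.taxa:
                        continue
                    res = assign_subgenome(tree, cid, labels, config.assignment_margin)
                    assign_rows.append({
                        "amplicon": amp, "contig": cid,
                        "position": snp["position"], "alt": snp["alt"],
                        "assignment": res.assignment,
                        "d_p": "" if res.d_p is None else round(res.d_p, 6),
                        "d_g": "" if res.d_g is None else round(res.d_g, 6),
                        "margin": res.margin,
                    })
        (out / "trees.nwk").write_text("\n".join(tree_lines) + ("\n" if tree_lines else ""))
        seqio.write_tsv(pd.DataFrame(assign_rows, columns=[
            "amplicon", "contig", "position", "alt", "assignment", "d_p", "d_g", "margin",
        ]), out / "subgenome_assignments.tsv")
        counts["subgenome_assignments"] = len(assign_rows)

        # ------------------------------------------------------------------
        # stage 9: dosage genotyping demonstration (simulated truth only)
        # ------------------------------------------------------------------
        if truth is not None and truth.snp_records:
            rng = np.random.default_rng(config.seed + 1)
            scenario = config.intensity_scenario
            labels = SCENARIOS[scenario].labels
            records = [r for r in truth.snp_records][: config.max_intensity_loci]
            dose_rows = []
            for k, rec in enumerate(records):
                locus = f"{rec.amplicon}:{rec.position + 1}"
                for g in sorted(rec.dosages):
                    dose_rows.append({"sample_id": g, "locus_id": locus,
                                      "b_copies": rec.dosages[g]})
            dosage_df = pd.DataFrame(dose_rows)
            intensity = simulate_intensity(dosage_df, scenario,
                                           config.intensity_noise_sd, rng)
            seqio.write_tsv(intensity, out / "intensity.tsv",
                            sort_by=["locus_id", "sample_id"])
            call_tables = []
            pattern_rows = []
            truth_calls = []
            for locus, grp in intensity.groupby("locus_id", sort=True):
                thetas = grp.set_index("sample_id")["theta"]
                calls, _ = call_dosage(thetas, scenario)
                calls.insert(0, "locus_id", locus)
                call_tables.append(calls)
                pattern_rows.append({"locus_id": locus,
                                     "pattern": classify_locus_pattern(thetas)})
                td = dosage_df[dosage_df["locus_id"] == locus]
                for r in td.itertuples():
                    truth_calls.append({"sample_id": r.sample_id, "locus_id": locus,
                                        "class": labels[int(r.b_copies)]})
            calls_all = pd.concat(call_tables, ignore_index=True)
            seqio.write_tsv(calls_all, out / "dosage_calls.tsv",
                            sort_by=["locus_id", "sample_id"])
            seqio.write_tsv(pd.DataFrame(pattern_rows), out / "locus_patterns.tsv",
                            sort_by=["locus_id"])
            per_locus, overall = concordance(
                calls_all[["sample_id", "locus_id", "class"]],
                pd.DataFrame(truth_calls),
            )
            exact = (calls_all.merge(pd.DataFrame(truth_calls),
                                     on=["sample_id", "locus_id"], suffixes=("", "_truth")))
            acc = float((exact["class"] == exact["class_truth"]).mean()) if len(exact) else np.nan
            seqio.write_tsv(per_locus, out / "dosage_concordance.tsv", sort_by=["locus_id"])
            counts["dosage_accuracy_pct"] = round(100.0 * acc, 2)
            counts["dosage_concordance_pct"] = round(overall, 2) if overall == overall else None

        # ------------------------------------------------------------------
        # stage 10: diversity (Dice + UPGMA over SNP and diagnostic calls)
        # ------------------------------------------------------------------
        call_rows = _allele_calls_for_diversity(classified_all, observations,
                                                diagnostics, morphotypes, depths)
        if call_rows:
            calls_df = pd.DataFrame(call_rows)
            binary = binary_encode(calls_df)
            sim_m = dice_matrix(binary)
            seqio.write_tsv(sim_m.reset_index(names="genotype"), out / "similarity.tsv",
                            sort_by=["genotype"])
            dis = 1.0 - sim_m
            if not dis.isna().any().any():
                tree = upgma(dis)
                if not is_ultrametric(tree):
                    raise PipelineError("UPGMA produced a non-ultrametric phenogram")
                (out / "phenogram.nwk").write_text(to_newick(tree) + "\n")
            counts["diversity_loci"] = len({r["locus"] for r in call_rows})

        # ------------------------------------------------------------------
        # stage 11: truth comparison (simulated input only)
        # ------------------------------------------------------------------
        if truth is not None:
            eval_df = evaluate_against_truth(
                truth, classified_all, diagnostics, contigs_by_morph,
                config.assembly.scoring,
            )
            seqio.write_tsv(eval_df, out / "truth_eval.tsv", sort_by=["metric"])
            for r in eval_df.itertuples():
                counts[f"truth_{r.metric}"] = r.value

        # ------------------------------------------------------------------
        # manifest
        # ------------------------------------------------------------------
        files = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("run.log", "manifest.json"):
                files[str(p.relative_to(out))] = sha256_file(p)
        manifest = RunManifest(
            config_hash=config.config_hash(),
            version=_version(),
            counts=counts,
            files=files,
        )
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
        logger.info("run complete: %d output files", len(files))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _version() -> str:
    from polysnp import __version__

    return __version__


def _allele_calls_for_diversity(classified_all, observations, diagnostics,
                                morphotypes, depths) -> list[dict]:
    """Per-genotype allele strings at qualified SNP and diagnostic loci.

    SNP loci use generic allele symbols A (reference) / B (alternate): a
    carrier whose alternate fraction is >= 0.9 scores B only, other carriers
    AB, covered non-carriers A, uncovered genotypes missing. Diagnostic loci
    score the group-fixed allele for every genotype of each group.
    """
    rows: list[dict] = []
    if len(classified_all):
        snps = classified_all[classified_all["class"] == "SNP"]
        for snp in snps.to_dict("records"):
            morph = snp["morphotype"]
            locus = f"{snp['contig']}:{snp['position']}:{snp['alt']}"
            obs = observations.get(morph)
            obs_here = obs[(obs["contig"] == snp["contig"])
                           & (obs["position"] == snp["position"])
                           & (obs["alt"] == snp["alt"])] if obs is not None and len(obs) else None
            support = {r["genotype"]: (r["alt_support"], r["depth"])
                       for r in obs_here.to_dict("records")} if obs_here is not None else {}
            for g in sorted(morphotypes.get(morph, [])):
                d = depths.get(morph, {}).get(g, {}).get(snp["contig"])
                covered = d is not None and snp["position"] - 1 < len(d) \
                    and d[snp["position"] - 1] > 0
                if g in support:
                    alt_n, dep = support[g]
                    alleles = "B" if dep and alt_n / dep >= 0.9 else "AB"
                elif covered:
                    alleles = "A"
                else:
                    alleles = ""
                rows.append({"genotype": g, "locus": locus, "alleles": alleles})
    if len(diagnostics):
        for r in diagnostics.to_dict("records"):
            locus = f"diag:{r['amplicon']}:{r['position_a']}"
            for g in sorted(morphotypes.get(r["group_a"], [])):
                rows.append({"genotype": g, "locus": locus, "alleles": "A"})
            for g in sorted(morphotypes.get(r["group_b"], [])):
                rows.append({"genotype": g, "locus": locus, "alleles": "B"})
    # deduplicate (a diagnostic position can be reported per contig pair)
    seen = set()
    out = []
    for r in rows:
        key = (r["genotype"], r["locus"])
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def contig_to_amplicon_map(contig: SubgenomeContig, amplicon_seq: str,
                           scoring: Scoring = Scoring()) -> dict[int, int]:
    """0-based contig position -> 0-based amplicon position via overlap alignment."""
    res = local_align(contig.consensus, amplicon_seq, scoring, mode="overlap")
    mapping: dict[int, int] = {}
    if res is None:
        return mapping
    q, t = res.query_span[0], res.target_span[0]
    for n, op in re.findall(r"(\d+)([=XID])", res.cigar):
        n = int(n)
        if op in "=X":
            for k in range(n):
                mapping[q + k] = t + k
            q += n
            t += n
        elif op == "I":
            q += n
        else:
            t += n
    return mapping


def evaluate_against_truth(truth, classified_all, diagnostics, contigs_by_morph,
                           scoring: Scoring = Scoring()) -> pd.DataFrame:
    """Sensitivity/precision of SNP and diagnostic calls against planted truth.

    A planted SNP is recovered when a qualified SNP call lands at its
    projected amplicon position with either allele of the planted pair (the
    complementary allele surfaces when the panel's reference genotype is a
    carrier). Precision is the fraction of SNP calls at planted SNP
    positions; the HSV co-location rate is the fraction of SNP calls at
    planted HSV positions.
    """
    coord: dict[str, dict[int, int]] = {}
    contig_amp: dict[str, str] = {}
    for morph, contigs in contigs_by_morph.items():
        for c in contigs:
            if c.amplicon_id == "UNATTRIBUTED":
                continue
            amp_seq = truth.subgenome_refs.get(c.amplicon_id, {}).get("P")
            if amp_seq is None:
                continue
            coord[c.contig_id] = contig_to_amplicon_map(c, amp_seq, scoring)
            contig_amp[c.contig_id] = c.amplicon_id

    hsv_pos = truth.hsv_positions()
    planted: dict[str, set[tuple[str, int]]] = {}
    planted_alleles: dict[tuple[str, int], set[str]] = {}
    for rec in truth.snp_records:
        planted.setdefault(rec.morphotype, set()).add((rec.amplicon, rec.position))
        planted_alleles.setdefault((rec.amplicon, rec.position), set()).update(
            (rec.ref, rec.alt)
        )

    snp_calls: dict[str, list[tuple[str, int, str]]] = {}
    if len(classified_all):
        for r in classified_all[classified_all["class"] == "SNP"].to_dict("records"):
            cmap = coord.get(r["contig"])
            if cmap is None:
                continue
            amp_pos = cmap.get(r["position"] - 1)
            if amp_pos is None:
                continue
            snp_calls.setdefault(r["morphotype"], []).append(
                (contig_amp[r["contig"]], amp_pos, r["alt"])
            )

    rows = []
    all_calls = [c for calls in snp_calls.values() for c in calls]
    n_at_hsv = sum(1 for amp, pos, _ in all_calls if (amp, pos) in hsv_pos)
    rows.append({"metric": "snp_calls_total", "value": len(all_calls),
                 "n": len(all_calls)})
    rows.append({
        "metric": "pct_snp_calls_at_hsv",
        "value": round(100.0 * n_at_hsv / len(all_calls), 3) if all_calls else 0.0,
        "n": len(all_calls),
    })
    for morph in sorted(planted):
        truth_set = planted[morph]
        calls = snp_calls.get(morph, [])
        called_pos = {(amp, pos) for amp, pos, _ in calls}
        recovered = sum(
            1 for (amp, pos) in truth_set
            if any((amp, pos) == (ca, cp) and alt in planted_alleles[(amp, pos)]
                   for ca, cp, alt in calls)
        )
        tp_calls = sum(1 for (ca, cp, alt) in calls
                       if (ca, cp) in truth_set and alt in planted_alleles.get((ca, cp), ()))
        rows.append({"metric": f"snp_sensitivity_{morph}",
                     "value": round(recovered / len(truth_set), 4) if truth_set else 1.0,
                     "n": len(truth_set)})
        rows.append({"metric": f"snp_precision_{morph}",
                     "value": round(tp_calls / len(calls), 4) if calls else 1.0,
                     "n": len(calls)})
        _ = called_pos

    # pooled
    n_truth = sum(len(v) for v in planted.values())
    n_rec = 0
    n_tp = 0
    for morph, truth_set in planted.items():
        calls = snp_calls.get(morph, [])
        n_rec += sum(1 for (amp, pos) in truth_set
                     if any((amp, pos) == (ca, cp) and alt in planted_alleles[(amp, pos)]
                            for ca, cp, alt in calls))
        n_tp += sum(1 for (ca, cp, alt) in calls
                    if (ca, cp) in truth_set and alt in planted_alleles.get((ca, cp), ()))
    rows.append({"metric": "snp_sensitivity", "n": n_truth,
                 "value": round(n_rec / n_truth, 4) if n_truth else 1.0})
    rows.append({"metric": "snp_precision", "n": len(all_calls),
                 "value": round(n_tp / len(all_calls), 4) if all_calls else 1.0})

    # diagnostics
    diag_truth = {(r.amplicon, r.position) for r in truth.diagnostic_records}
    diag_called = set()
    if len(diagnostics):
        for r in diagnostics.to_dict("records"):
            cmap = coord.get(r["contig_a"])
            if cmap is None:
                continue
            amp_pos = cmap.get(r["position_a"] - 1)
            if amp_pos is not None:
                diag_called.add((r["amplicon"], amp_pos))
    n_diag_tp = len(diag_truth & diag_called)
    rows.append({"metric": "diagnostic_sensitivity", "n": len(diag_truth),
                 "value": round(n_diag_tp / len(diag_truth), 4) if diag_truth else 1.0})
    rows.append({"metric": "diagnostic_precision", "n": len(diag_called),
                 "value": round(n_diag_tp / len(diag_called), 4) if diag_called else 1.0})
    return pd.DataFrame(rows, columns=["metric", "value", "n"])
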