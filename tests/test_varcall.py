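"""Variant tabulation and the SNP qualification rule algebra."""

import random

import numpy as np
import pandas as pd
import pytest

from polysnp.align import MappingParams, map_read
from polysnp.assembly import SubgenomeContig
from polysnp.varcall import (SupportParams, VarcallError, classify_diagnostic,
                             detect_hsvs, qualify_snps, snp_summary,
                             tabulate_variants, write_vcf)


def _contig(cid, seq, amp="amp1"):
    return SubgenomeContig(cid, "g", seq, [], np.ones(len(seq)), amplicon_id=amp)


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _place(reads, contigs):
    refs = {cid: c.consensus for cid, c in contigs.items()}
    placements = []
    for seq in reads:
        res = map_read(seq, refs, MappingParams(both_strands=False))
        assert res is not None
        placements.append((seq, res))
    return placements


def test_unanimous_substitution_recorded_with_full_support():
    rng = random.Random(0)
    ref = _random_seq(rng, 200)
    contigs = {"c1": _contig("c1", ref)}
    alt = ref[:50] + ("G" if ref[50] != "G" else "T") + ref[51:]
    obs, _ = tabulate_variants("g1", _place([alt] * 10, contigs), contigs)
    assert len(obs) == 1
    row = obs.iloc[0]
    assert (row.position, row.type, row.depth, row.alt_support) == (51, "SUB", 10, 10)
    assert row.ref == ref[50] and row.alt == alt[50]


def test_single_supporting_read_below_threshold_ignored():
    rng = random.Random(1)
    ref = _random_seq(rng, 200)
    contigs = {"c1": _contig("c1", ref)}
    alt = ref[:50] + ("T" if ref[50] != "T" else "A") + ref[51:]
    obs, _ = tabulate_variants("g1", _place([alt] + [ref] * 19, contigs), contigs,
                               SupportParams(min_reads=2))
    assert len(obs) == 0


def test_deletion_observed_as_del_type():
    rng = random.Random(2)
    ref = _random_seq(rng, 200)
    contigs = {"c1": _contig("c1", ref)}
    deleted = ref[:100] + ref[101:]
    obs, _ = tabulate_variants("g1", _place([deleted] * 6 + [ref] * 6, contigs), contigs)
    dels = obs[obs.type == "DEL"]
    assert len(dels) == 1
    assert dels.iloc[0].position == 101
    assert dels.iloc[0].alt_support == 6


def test_unknown_contig_in_placement_is_an_error():
    rng = random.Random(3)
    ref = _random_seq(rng, 150)
    known = {"c1": _contig("c1", ref)}
    placements = _place([ref] * 2, known)
    with pytest.raises(VarcallError):
        tabulate_variants("g1", placements, {"other": _contig("other", ref)})


def test_hsvs_projected_from_single_differing_column():
    rng = random.Random(4)
    a = _random_seq(rng, 120)
    b = a[:41] + ("C" if a[41] != "C" else "G") + a[42:]  # aligned column 42
    table, mask = detect_hsvs([_contig("cA", a), _contig("cB", b)])
    assert mask["cA"] == {41} and mask["cB"] == {41}
    assert set(table.position) == {42}
    assert set(table.contig) == {"cA", "cB"}


def test_identical_contigs_yield_no_hsvs():
    rng = random.Random(5)
    a = _random_seq(rng, 120)
    table, mask = detect_hsvs([_contig("cA", a), _contig("cB", a)])
    assert len(table) == 0
    assert mask["cA"] == set() == mask["cB"]


def test_short_overlap_pairs_not_compared():
    rng = random.Random(6)
    a = _random_seq(rng, 60)
    b = a[51:] + _random_seq(rng, 51)  # only 9 bp of shared sequence
    table, mask = detect_hsvs([_contig("cA", a), _contig("cB", b)],
                              min_overlap=10, min_identity=0.8)
    assert len(table) == 0


def _obs_row(genotype, contig, position, ref, alt, vtype="SUB", depth=20, support=8):
    return {"genotype": genotype, "amplicon": "amp1", "contig": contig,
            "position": position, "ref": ref, "alt": alt, "type": vtype,
            "depth": depth, "alt_support": support}


def test_qualification_rule_algebra():
    lengths = {"c1": 400}
    rows = []
    rows += [_obs_row(f"g{i}", "c1", 100, "A", "G") for i in (1, 2)]         # SNP
    rows += [_obs_row(f"g{i}", "c1", 150, "C", "T") for i in range(1, 7)]    # all 6
    rows += [_obs_row(f"g{i}", "c1", 200, "G", "-", "DEL") for i in (1, 2, 3)]
    rows += [_obs_row(f"g{i}", "c1", 250, "T", "A") for i in (2, 4)]         # at HSV
    rows += [_obs_row("g5", "c1", 300, "A", "C")]                            # singleton
    out = qualify_snps(pd.DataFrame(rows), {"c1": {249}}, panel_size=6,
                       contig_lengths=lengths)
    cls = out.set_index("position")["class"]
    assert cls[100] == "SNP"
    assert cls[150] == "REJECT_UBIQUITOUS"
    assert cls[200] == "REJECT_INDEL"
    assert cls[250] == "REJECT_HSV_COLOCATED"
    assert cls[300] == "REJECT_SINGLETON"
    assert set(out["class"].value_counts().values) == {1}


def test_terminal_positions_excluded_from_qualification():
    rows = [_obs_row(f"g{i}", "c1", 5, "A", "G") for i in (1, 2)]
    rows += [_obs_row(f"g{i}", "c1", 395, "A", "G") for i in (1, 2)]
    out = qualify_snps(pd.DataFrame(rows), {}, 6, {"c1": 400},
                       SupportParams(end_exclude=10))
    assert len(out) == 0


def test_small_panel_rejected():
    with pytest.raises(VarcallError):
        qualify_snps(pd.DataFrame(), {}, panel_size=2, contig_lengths={})


def test_removing_a_genotype_never_promotes_a_variant():
    """Panel-shrink monotonicity: SNP can demote to singleton, never reverse."""
    rng = random.Random(7)
    for _ in range(20):
        panel = [f"g{i}" for i in range(1, 6)]
        carriers = rng.sample(panel, rng.randint(1, 5))
        rows = [_obs_row(g, "c1", 100, "A", "G") for g in carriers]
        full = qualify_snps(pd.DataFrame(rows), {}, len(panel), {"c1": 400})
        removed = rng.choice(panel)
        sub_rows = [r for r in rows if r["genotype"] != removed]
        if not sub_rows:
            continue
        sub = qualify_snps(pd.DataFrame(sub_rows), {}, len(panel) - 1, {"c1": 400})
        c_full = full.iloc[0]["class"]
        c_sub = sub.iloc[0]["class"]
        if c_full == "REJECT_SINGLETON":
            assert c_sub == "REJECT_SINGLETON"
        if c_sub == "SNP":
            assert c_full in ("SNP", "REJECT_UBIQUITOUS")


def _depths(genotypes, contig, length, covered=True):
    d = np.full(length, 20 if covered else 0)
    return {g: {contig: d} for g in genotypes}


def test_fixed_intergroup_difference_is_diagnostic():
    rng = random.Random(8)
    a = _random_seq(rng, 200)
    b = a[:99] + ("T" if a[99] != "T" else "C") + a[100:]
    empty = pd.DataFrame(columns=["contig", "position"])
    out = classify_diagnostic([_contig("cA", a)], [_contig("cB", b)],
                              empty, empty,
                              _depths(["a1", "a2"], "cA", 200),
                              _depths(["b1", "b2"], "cB", 200))
    assert len(out) == 1
    row = out.iloc[0]
    assert (row.position_a, row.allele_a, row.allele_b) == (100, a[99], b[99])


def test_within_group_polymorphism_blocks_diagnostic():
    rng = random.Random(9)
    a = _random_seq(rng, 200)
    b = a[:99] + ("T" if a[99] != "T" else "C") + a[100:]
    poly_a = pd.DataFrame([_obs_row("a1", "cA", 100, a[99], "G")])
    empty = pd.DataFrame(columns=["contig", "position"])
    out = classify_diagnostic([_contig("cA", a)], [_contig("cB", b)],
                              poly_a, empty,
                              _depths(["a1", "a2"], "cA", 200),
                              _depths(["b1", "b2"], "cB", 200))
    assert len(out) == 0


def test_insufficient_group_coverage_withholds_diagnostic():
    rng = random.Random(10)
    a = _random_seq(rng, 200)
    b = a[:99] + ("T" if a[99] != "T" else "C") + a[100:]
    empty = pd.DataFrame(columns=["contig", "position"])
    depths_b = {"b1": {"cB": np.full(200, 5)}, "b2": {"cB": np.zeros(200)}}
    out = classify_diagnostic([_contig("cA", a)], [_contig("cB", b)],
                              empty, empty,
                              _depths(["a1", "a2"], "cA", 200), depths_b,
                              min_observed=2)
    assert len(out) == 0


def test_no_shared_amplicons_warns_and_returns_empty():
    rng = random.Random(11)
    empty = pd.DataFrame(columns=["contig", "position"])
    with pytest.warns(UserWarning):
        out = classify_diagnostic([_contig("cA", _random_seq(rng, 100), "ampX")],
                                  [_contig("cB", _random_seq(rng, 100), "ampY")],
                                  empty, empty, {}, {})
    assert len(out) == 0


def test_snp_summary_means():
    cls = pd.DataFrame({
        "class": ["SNP"] * 30 + ["REJECT_INDEL"] * 4,
        "type": ["SUB"] * 30 + ["DEL"] * 4,
    })
    out = snp_summary(cls, n_amplicons=2, n_contigs=10, morphotype="C")
    snp_row = out[out["class"] == "SNP"].iloc[0]
    assert snp_row["count"] == 30
    assert snp_row.per_amplicon == 15.0
    assert snp_row.per_contig == 3.0
    zero = snp_summary(pd.DataFrame(), 2, 10, "C")
    assert (zero["count"] == 0).all()


def test_vcf_emission_has_one_record_per_substitution(tmp_path):
    cls = pd.DataFrame([
        {"contig": "c1", "position": 10, "ref": "A", "alt": "G", "type": "SUB",
         "class": "SNP", "n_carriers": 2, "carriers": "g1,g2"},
        {"contig": "c1", "position": 20, "ref": "C", "alt": "-", "type": "DEL",
         "class": "REJECT_INDEL", "n_carriers": 3, "carriers": "g1,g2,g3"},
    ])
    path = tmp_path / "out.vcf"
    write_vcf(cls, path)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(body) == 1
    assert body[0].split("\t")[:5] == ["c1", "10", ".", "A", "G"]
    assert "CLASS=SNP" in body[0]
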