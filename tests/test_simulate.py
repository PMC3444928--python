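"""The synthetic generator's planted truth must be exact by construction."""

import math

import numpy as np
import pytest

from polysnp.simulate import (SUBGENOMES, SimConfig, SimConfigError,
                              _perturb_read, _truncated_dosages,
                              homopolymer_mask, simulate_dataset,
                              simulate_genotypes, simulate_intensity,
                              simulate_reads, simulate_subgenomes, write_dataset)
from polysnp.util import sha256_file


def test_hsv_truth_equals_columnwise_difference_set():
    for seed in (0, 1, 2):
        cfg = SimConfig(n_amplicons=2, seed=seed)
        rng = np.random.default_rng(seed)
        _, refs, hsvs = simulate_subgenomes(cfg, rng)
        for amp, seqs in refs.items():
            diffs = {i for i in range(cfg.amplicon_length)
                     if len({seqs[s][i] for s in SUBGENOMES}) > 1}
            truth = {r.position for r in hsvs if r.amplicon == amp}
            assert diffs == truth


def test_zero_hsv_rate_gives_identical_subgenomes(rng):
    cfg = SimConfig(n_amplicons=2, hsv_rate=0.0)
    _, refs, hsvs = simulate_subgenomes(cfg, rng)
    assert hsvs == []
    for seqs in refs.values():
        assert seqs["P"] == seqs["G1"] == seqs["G2"]


def test_pairwise_hsv_count_matches_poisson_expectation():
    """Monte-Carlo mean pairwise HSV count vs the binomial/Poisson oracle.

    With amplicon length 545 and an HSV every 109 bp, each sub-genome pair
    differs at Binomial(545, 1/109) sites: mean 5.
    """
    L, rate, reps = 545, 1.0 / 109.0, 1000
    rng = np.random.default_rng(42)
    cfg = SimConfig(n_amplicons=1, amplicon_length=L, hsv_rate=rate)
    counts = []
    for _ in range(reps):
        _, refs, _ = simulate_subgenomes(cfg, rng)
        a, b = refs["amp001"]["P"], refs["amp001"]["G1"]
        counts.append(sum(x != y for x, y in zip(a, b)))
    expected = L * rate
    se = math.sqrt(expected * (1 - rate) / reps)
    assert abs(np.mean(counts) - expected) < 3 * se


@pytest.mark.parametrize(
    "kwargs",
    [
        {"amplicon_length": 0},
        {"n_amplicons": 0},
        {"read_length": 600},  # longer than the amplicon
        {"hsv_rate": 1.5},
        {"depth_mode": "bogus"},
        {"n_genotypes_per_morphotype": 2, "snp_rate": 1.0},
    ],
)
def test_invalid_configurations_rejected(kwargs):
    with pytest.raises(SimConfigError):
        SimConfig(**kwargs).validate()


def test_planted_snp_carriers_within_qualifying_range():
    ds = simulate_dataset(SimConfig(n_amplicons=4, seed=3))
    n = ds.config.n_genotypes_per_morphotype
    assert ds.truth.snp_records
    for rec in ds.truth.snp_records:
        carriers = len(rec.carriers)
        assert 2 <= carriers <= n - 1
        assert all(0 <= d <= 2 for d in rec.dosages.values())


def test_zero_snp_and_diagnostic_rates_give_reference_haplotypes(rng):
    cfg = SimConfig(n_amplicons=2, snp_rate=0, diagnostic_rate=0)
    _, refs, hsvs = simulate_subgenomes(cfg, rng)
    _, haplotypes, snps, diags = simulate_genotypes(refs, cfg, rng, hsvs)
    assert snps == [] and diags == []
    for per_geno in haplotypes.values():
        for amp, haps in per_geno.items():
            for (sub, _), seq in haps.items():
                assert seq == refs[amp][sub]


def test_truncated_binomial_carrier_mean_matches_enumeration():
    """Sampled carrier counts vs brute-force enumeration of the truncated law."""
    n, f, reps = 6, 0.5, 500
    q = 1 - (1 - f) ** 2  # per-genotype carrier probability under Binomial(2, f)
    pmf = {k: math.comb(n, k) * q**k * (1 - q) ** (n - k) for k in range(2, n)}
    z = sum(pmf.values())
    expected = sum(k * p for k, p in pmf.items()) / z
    var = sum(k * k * p for k, p in pmf.items()) / z - expected**2
    rng = np.random.default_rng(7)
    counts = [(int((_truncated_dosages(n, f, rng) > 0).sum())) for _ in range(reps)]
    se = math.sqrt(var / reps)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_exact_depth_mode_read_count():
    cfg = SimConfig(n_amplicons=10, depth=25, n_genotypes_per_morphotype=6,
                    n_morphotypes=1, seed=0)
    ds = simulate_dataset(cfg)
    assert len(ds.reads) == 25 * 6 * 10


def test_error_free_reads_are_exact_haplotype_substrings():
    cfg = SimConfig(n_amplicons=2, depth=5, sub_error=0.0,
                    homopolymer_indel_rate=0.0, seed=2)
    ds = simulate_dataset(cfg)
    blen = cfg.barcode_length
    truth = ds.truth.read_truth.set_index("read_id")
    for read in ds.reads:
        row = truth.loc[read.read_id]
        hap = ds.truth.haplotypes[row.genotype][row.amplicon][(row.subgenome, row.allele)]
        assert read.sequence[blen:] in hap


def test_homopolymer_indels_confined_to_runs():
    seq = "ACGAACGA" + "TTTT" + "CGAACGAC"
    mask = homopolymer_mask(seq)
    assert set(np.flatnonzero(mask)) == set(range(7, 13))  # run plus flanks
    cfg = SimConfig(sub_error=0.0, homopolymer_indel_rate=1.0)
    rng = np.random.default_rng(0)
    for _ in range(50):
        out, n_sub, n_indel = _perturb_read(seq, mask, cfg, rng)
        assert n_sub == 0 and n_indel >= 1
        # bases outside the masked region are untouched on both flanks
        assert out[:7] == seq[:7]
        assert out[-7:] == seq[-7:]


def test_substitution_error_rate_converges():
    cfg = SimConfig(n_amplicons=4, depth=20, homopolymer_indel_rate=0.0,
                    n_genotypes_per_morphotype=3, n_morphotypes=1, seed=9)
    ds = simulate_dataset(cfg)
    total_bases = len(ds.truth.read_truth) * cfg.read_length
    observed = ds.truth.read_truth["n_sub_errors"].sum() / total_bases
    se = math.sqrt(cfg.sub_error * (1 - cfg.sub_error) / total_bases)
    assert abs(observed - cfg.sub_error) < 3 * se


def test_hsv_and_snp_positions_disjoint_by_default():
    ds = simulate_dataset(SimConfig(n_amplicons=4, seed=5))
    hsv = ds.truth.hsv_positions()
    for rec in ds.truth.snp_records:
        assert (rec.amplicon, rec.position) not in hsv
    for rec in ds.truth.diagnostic_records:
        assert (rec.amplicon, rec.position) not in hsv


def test_read_truth_is_a_bijection_onto_reads():
    ds = simulate_dataset(SimConfig(n_amplicons=2, depth=6, seed=4))
    ids = {r.read_id for r in ds.reads}
    assert set(ds.truth.read_truth["read_id"]) == ids
    assert len(ds.truth.read_truth) == len(ids)


@pytest.mark.parametrize(
    "scenario,b_copies,expected",
    [
        ("single_subgenome", 2, 1.0),       # BB homozygote: all signal from B
        ("all_subgenomes_one", 1, 1 / 6),   # one B allele of six
        ("single_subgenome", 0, 0.0),
        ("all_subgenomes_two", 0, 0.0),
    ],
)
def test_noise_free_intensity_values(scenario, b_copies, expected, rng):
    import pandas as pd

    table = pd.DataFrame([{"sample_id": "s1", "locus_id": "l1", "b_copies": b_copies}])
    out = simulate_intensity(table, scenario, 0.0, rng)
    assert out["theta"].iloc[0] == pytest.approx(expected)


def test_unknown_intensity_scenario_rejected(rng):
    import pandas as pd

    table = pd.DataFrame([{"sample_id": "s1", "locus_id": "l1", "b_copies": 0}])
    with pytest.raises(SimConfigError):
        simulate_intensity(table, "nonsense", 0.0, rng)


def test_identical_config_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(n_amplicons=2, depth=6, seed=13)
    p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
    p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
    assert p1.keys() == p2.keys()
    for key in p1:
        assert sha256_file(p1[key]) == sha256_file(p2[key]), key
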