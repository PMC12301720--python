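"""Statistical structure and determinism of the synthetic-data generator."""

import math

import numpy as np
import pytest

from karyoscope import io_formats as iof
from karyoscope import simulate as sim
from karyoscope.errors import ConfigError


def _cfg(**kw):
    base = dict(seed=7, chrom_lengths=[20_000], baseline_ploidy=2, het_rate=1.0)
    base.update(kw)
    return sim.SimulationConfig(**base)


# --------------------------------------------------------------- determinism

def test_same_seed_same_bytes(tmp_path):
    cfg = _cfg()
    outs = []
    for run in ("a", "b"):
        chroms, truth = sim.simulate_genome(cfg)
        sites = sim.simulate_variants(truth, cfg)
        depths = sim.simulate_depth(truth, cfg)
        fa = tmp_path / f"{run}.fasta"
        vcf = tmp_path / f"{run}.vcf"
        dp = tmp_path / f"{run}.tsv"
        iof.write_fasta(chroms, fa)
        iof.write_vcf_sites(sites, vcf)
        iof.write_depth_table(depths, dp)
        outs.append((fa.read_bytes(), vcf.read_bytes(), dp.read_bytes()))
    assert outs[0] == outs[1]


def test_truth_skeleton_matches_full_genome():
    cfg = _cfg(chrom_lengths=[20_000, 30_000])
    _, truth_full = sim.simulate_genome(cfg)
    truth_lite = sim.simulate_truth(cfg)
    assert truth_lite.telomere_spans == truth_full.telomere_spans
    assert truth_lite.copy_number == truth_full.copy_number
    assert truth_lite.telomere_capped == truth_full.telomere_capped


def test_truth_json_round_trip(tmp_path):
    cfg = _cfg()
    _, truth = sim.simulate_genome(cfg)
    sim.simulate_variants(truth, cfg)
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = sim.SimulationTruth.from_json(p)
    assert back.copy_number == truth.copy_number
    assert back.het_sites == truth.het_sites
    assert back.telomere_spans == truth.telomere_spans


# -------------------------------------------------------------------- genome

def test_uncapped_ends_recorded():
    cfg = _cfg(telomere_copies=0)
    _, truth = sim.simulate_genome(cfg)
    for ends in truth.telomere_capped.values():
        assert ends == {"five_prime": False, "three_prime": False}


def test_genome_structure_and_gc():
    cfg = _cfg(chrom_lengths=[100_000], telomere_copies=10)
    chroms, truth = sim.simulate_genome(cfg)
    seq = chroms[0].sequence
    span5, span3 = truth.telomere_spans["chr01"]
    # 5' array is the reverse complement of a T{3,5}AGG tandem run
    assert seq[:span5].startswith("CCT")
    assert seq[-span3:].endswith("AGG")
    core = seq[span5 : len(seq) - span3]
    gc = (core.count("G") + core.count("C")) / len(core)
    sigma = math.sqrt(0.25 / len(core))
    assert abs(gc - 0.5) < 4 * sigma


def test_chromosome_too_short_for_telomeres():
    with pytest.raises(ConfigError, match="too short"):
        sim.simulate_genome(_cfg(chrom_lengths=[100], telomere_copies=10))


def test_haploid_with_het_rate_rejected():
    with pytest.raises(ConfigError, match="heterozygous"):
        sim.SimulationConfig(seed=0, baseline_ploidy=1, het_rate=0.5)


# ------------------------------------------------------------------ variants

def test_het_site_count_poisson_bound():
    # density matching the most heterozygous study strain: 2.75 sites/kb
    cfg = _cfg(chrom_lengths=[1_000_000], het_rate=2.75, telomere_copies=0)
    truth = sim.simulate_truth(cfg)
    sim.simulate_variants(truth, cfg)
    n = len(truth.het_sites["chr01"])
    lam = 2.75 * 1000
    assert abs(n - lam) < 4 * math.sqrt(lam)


def test_diploid_sites_have_half_fraction():
    cfg = _cfg(chrom_lengths=[200_000], het_rate=1.0, error_rate=0.0)
    truth = sim.simulate_truth(cfg)
    sites = sim.simulate_variants(truth, cfg)
    assert all(j == 1 for _, j in truth.het_sites["chr01"])
    mean_f = np.mean([s.alt_freq for s in sites])
    assert mean_f == pytest.approx(0.5, abs=0.01)


def test_triploid_dosage_modes():
    cfg = _cfg(
        chrom_lengths=[500_000], het_rate=1.0, error_rate=0.0,
        copy_number_overrides={"chr01": 3}, mean_depth=100.0,
    )
    truth = sim.simulate_truth(cfg)
    sites = sim.simulate_variants(truth, cfg)
    j_of = dict(truth.het_sites["chr01"])
    f1 = [s.alt_freq for s in sites if j_of[s.pos] == 1]
    f2 = [s.alt_freq for s in sites if j_of[s.pos] == 2]
    assert np.mean(f1) == pytest.approx(1 / 3, abs=0.01)
    assert np.mean(f2) == pytest.approx(2 / 3, abs=0.01)
    # no mass far from the two modes (binomial 4-sigma at depth ~300)
    sigma = math.sqrt((1 / 3) * (2 / 3) / 200)
    assert all(abs(f - 1 / 3) < 4 * sigma for f in f1)


def test_error_sites_have_low_fraction():
    cfg = _cfg(
        chrom_lengths=[500_000], baseline_ploidy=1, het_rate=0.0,
        error_site_rate=0.1, error_rate=0.01,
    )
    truth = sim.simulate_truth(cfg)
    sites = sim.simulate_variants(truth, cfg)
    assert sites, "expected some error sites"
    assert np.mean([s.alt_freq for s in sites]) < 0.05


# --------------------------------------------------------------------- depth

def test_depth_ratio_reflects_copy_number():
    cfg = _cfg(
        chrom_lengths=[150_000, 150_000], mean_depth=100.0,
        copy_number_overrides={"chr02": 3}, telomere_copies=0,
    )
    truth = sim.simulate_truth(cfg)
    depths = sim.simulate_depth(truth, cfg)
    ratio = np.median(depths["chr02"]) / np.median(depths["chr01"])
    assert ratio == pytest.approx(1.5, abs=0.05)


def test_depth_poisson_limit():
    cfg = _cfg(chrom_lengths=[200_000], depth_dispersion=1e9, telomere_copies=0)
    truth = sim.simulate_truth(cfg)
    d = sim.simulate_depth(truth, cfg)["chr01"].astype(float)
    # variance approaches the mean as dispersion -> infinity
    assert d.var() / d.mean() == pytest.approx(1.0, rel=0.05)


def test_telomere_attenuation():
    cfg = _cfg(
        chrom_lengths=[50_000], telomere_copies=30,
        telomere_depth_attenuation=0.5, mean_depth=100.0,
    )
    truth = sim.simulate_truth(cfg)
    d = sim.simulate_depth(truth, cfg)["chr01"].astype(float)
    span5, span3 = truth.telomere_spans["chr01"]
    assert d[:span5].mean() < 0.7 * d[span5:-span3].mean()
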