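"""Heterozygosity filtering, AF model selection, depth normalization,
and the genome-level ploidy call."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from karyoscope import ploidy as pl
from karyoscope import simulate as sim
from karyoscope.errors import ValidationError
from karyoscope.io_formats import VariantSite


# ------------------------------------------------------------- het filtering

def test_het_window_rule():
    lengths = {"c1": 100_000}
    variants = [
        VariantSite("c1", 10, "A", "G", 60, 40),   # 0.40 -> retained
        VariantSite("c1", 20, "A", "G", 5, 95),    # 0.95 -> homozygous-alt
        VariantSite("c1", 30, "A", "G", 95, 5),    # 0.05 -> sub-threshold
    ]
    het = pl.filter_het_sites(variants, lengths)
    assert het["c1"].n_sites == 1
    assert het["c1"].sites == [(40, 100)]


def test_unknown_chromosome_rejected():
    with pytest.raises(ValidationError, match="length map"):
        pl.filter_het_sites([VariantSite("cX", 1, "A", "G", 50, 50)], {"c1": 100})


def test_zero_variants_zero_density():
    het = pl.filter_het_sites([], {"c1": 100_000, "c2": 50_000})
    assert all(h.het_density == 0.0 for h in het.values())


@pytest.mark.parametrize(
    "n_sites,genome_bp,expected,ndigits",
    [
        (46_222, 16_820_234, 2.75, 2),
        (7_714, 17_400_691, 0.44, 2),
        (3_441, 17_584_162, 0.20, 2),
        (302, 16_791_247, 0.02, 2),
    ],
)
def test_het_density_study_arithmetic(n_sites, genome_bp, expected, ndigits):
    """Published strain-level heterozygosity densities are pure arithmetic."""
    assert pl.round_half_up(pl.per_kb_density(n_sites, genome_bp), ndigits) == expected


def test_het_density_linear_and_label_invariant(rng):
    sites = [VariantSite("c1", int(p), "A", "G", 50, 50) for p in range(1, 101)]
    h1 = pl.filter_het_sites(sites, {"c1": 100_000})["c1"]
    relabeled = [VariantSite("cZ", s.pos, "A", "G", 50, 50) for s in sites]
    h2 = pl.filter_het_sites(relabeled, {"cZ": 100_000})["cZ"]
    assert h1.het_density == h2.het_density == pytest.approx(1.0)
    h3 = pl.filter_het_sites(sites, {"c1": 200_000})["c1"]
    assert h3.het_density == pytest.approx(h1.het_density / 2)


# --------------------------------------------------------- AF model selection

def _sites_for_k(rng, k, n_sites=200, depth=100, e=0.01):
    totals = np.maximum(rng.poisson(depth, n_sites), 1)
    js = rng.integers(1, k, size=n_sites)
    probs = (js / k) * (1 - 2 * e) + e
    alts = rng.binomial(totals, probs)
    return pl.HetSiteSet("c1", list(zip(alts.tolist(), totals.tolist())), 1_000_000)


@pytest.mark.parametrize("k", [2, 3])
def test_best_k_recovers_truth(rng, k):
    hs = _sites_for_k(rng, k)
    fit = pl.fit_af_models(hs)
    assert fit.best_k_af == k


def test_homozygous_alt_prefers_error_model():
    # alt_count == total at every site: the fixed-alt arm of the error-only
    # model (p = 1 - e) dominates the k=2 mixture's p = 0.5
    hs = pl.HetSiteSet("c1", [(100, 100)] * 200, 1_000_000)
    fit = pl.fit_af_models(hs)
    assert fit.best_k_af == 1
    assert fit.bic[1] < fit.bic[2]


def test_few_sites_uninformative():
    hs = pl.HetSiteSet("c1", [(50, 100)] * 10, 1_000_000)
    fit = pl.fit_af_models(hs, min_sites=30)
    assert fit.best_k_af is None
    assert not fit.informative


def test_zero_depth_sites_dropped():
    hs = pl.HetSiteSet("c1", [(0, 0)] * 50 + [(50, 100)] * 40, 1_000_000)
    fit = pl.fit_af_models(hs)
    assert fit.n_sites == 40


def test_likelihood_matches_brute_force_oracle(rng):
    """Vectorized mixture log-likelihood vs direct per-site enumeration."""
    totals = np.maximum(rng.poisson(80, 1000), 1)
    alts = rng.binomial(totals, rng.uniform(0.05, 0.95, size=1000))
    hs = pl.HetSiteSet("c1", list(zip(alts.tolist(), totals.tolist())), 1_000_000)
    e = 0.01
    fit = pl.fit_af_models(hs, k_candidates=(1, 2, 3), error_rate=e)
    for k in (1, 2, 3):
        expected = 0.0
        probs = [e, 1 - e] if k == 1 else [
            (j / k) * (1 - 2 * e) + e for j in range(1, k)
        ]
        for a, t in hs.sites:
            expected += math.log(
                sum(binom.pmf(a, t, p) for p in probs) / len(probs)
            )
        assert fit.log_likelihood[k] == pytest.approx(expected, abs=1e-9)
        assert fit.bic[k] == pytest.approx(-2 * expected, abs=1e-9)


# -------------------------------------------------------- depth normalization

def test_uniform_depth_normalizes_to_one():
    depths = {"c1": np.full(50_000, 100), "c2": np.full(30_000, 100)}
    prof = pl.normalize_depth(depths)
    assert np.allclose(prof.windows["normalized"], 1.0)
    assert prof.copy_ratio == {"c1": 1.0, "c2": 1.0}


def test_scale_invariance(rng):
    depths = {"c1": rng.integers(50, 150, size=40_000)}
    p1 = pl.normalize_depth(depths)
    p2 = pl.normalize_depth({"c1": depths["c1"] * 7})
    assert np.allclose(
        p1.windows["normalized"], p2.windows["normalized"], atol=1e-12
    )


def test_non_overlapping_window_count():
    depths = {"c1": np.full(95_000, 10)}
    prof = pl.normalize_depth(depths, window=10_000, step=10_000)
    # floor((L - window) / step) + 1 windows when step == window
    assert (prof.windows["chrom"] == "c1").sum() == 9


def test_masked_window_absent():
    depths = {"c1": np.full(30_000, 100)}
    mask = {"c1": np.zeros(30_000, dtype=bool)}
    mask["c1"][:10_000] = True  # first window fully masked
    prof = pl.normalize_depth(depths, mask=mask)
    first = prof.windows.iloc[0]
    assert np.isnan(first["mean_depth"])


def test_planted_copy_ratio_recovered():
    cfg = sim.SimulationConfig(
        seed=5, chrom_lengths=[200_000] * 4, baseline_ploidy=2, het_rate=0.0,
        copy_number_overrides={"chr03": 3}, mean_depth=50.0, telomere_copies=0,
    )
    truth = sim.simulate_truth(cfg)
    depths = sim.simulate_depth(truth, cfg)
    prof = pl.normalize_depth(depths)
    assert prof.copy_ratio["chr03"] == pytest.approx(1.5, abs=0.05)
    for c in ("chr01", "chr02", "chr04"):
        assert prof.copy_ratio[c] == pytest.approx(1.0, abs=0.05)


# ------------------------------------------------------------- genome calls

def _fit(chrom, k, n=100):
    return pl.AFModelFit(chrom, n, {}, {}, k)


def _het(chrom, n, length=1_000_000):
    return pl.HetSiteSet(chrom, [(50, 100)] * n, length)


def test_consensus_diploid_label():
    chroms = [f"c{i}" for i in range(5)]
    fits = {c: _fit(c, 2) for c in chroms}
    ratios = {c: 1.0 for c in chroms}
    het = {c: _het(c, 300) for c in chroms}
    rep = pl.call_genome_ploidy(fits, ratios, het)
    assert rep.baseline_ploidy == 2
    assert rep.ploidy_state_label == "diploid"
    assert rep.aneuploid_chroms == []


def test_haploid_fallback_on_low_heterozygosity():
    chroms = [f"c{i}" for i in range(5)]
    fits = {c: pl.AFModelFit(c, 2, {}, {}, None) for c in chroms}
    ratios = {c: 1.0 for c in chroms}
    het = {c: _het(c, 2) for c in chroms}  # 0.002/kb << 0.10/kb
    rep = pl.call_genome_ploidy(fits, ratios, het)
    assert rep.baseline_ploidy == 1
    assert rep.ploidy_state_label == "haploid"
    assert rep.baseline_evidence == "depth_only"


def test_aneuploid_anchor_forces_diploid_baseline():
    # near-homozygous baseline chromosomes, but a 1.5x chromosome with
    # informative 1/3-2/3 AF modes pins the genome to diploid
    chroms = ["c1", "c2", "c3", "c4", "c5"]
    fits = {c: pl.AFModelFit(c, 0, {}, {}, None) for c in chroms[:-1]}
    fits["c5"] = _fit("c5", 3)
    ratios = {c: 1.0 for c in chroms[:-1]} | {"c5": 1.5}
    het = {c: _het(c, 0) for c in chroms[:-1]} | {"c5": _het("c5", 200)}
    rep = pl.call_genome_ploidy(fits, ratios, het)
    assert rep.baseline_ploidy == 2
    assert rep.baseline_evidence == "af_anchor"
    c5 = next(c for c in rep.calls if c.chrom_id == "c5")
    assert c5.copy_number == 3 and c5.aneuploid and c5.evidence == "af+depth"


def test_conflicting_evidence_recorded_depth_wins():
    chroms = ["c1", "c2", "c3"]
    fits = {c: _fit(c, 2) for c in chroms}
    fits["c3"] = _fit("c3", 2)  # AF says 2 ...
    ratios = {"c1": 1.0, "c2": 1.0, "c3": 1.5}  # ... depth says 3
    het = {c: _het(c, 300) for c in chroms}
    rep = pl.call_genome_ploidy(fits, ratios, het)
    c3 = next(c for c in rep.calls if c.chrom_id == "c3")
    assert c3.copy_number == 3  # retained per depth
    assert c3.conflict and c3.evidence == "depth_only"
    assert rep.ploidy_state_label == "mostly diploid"
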