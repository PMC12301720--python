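"""End-to-end pipelines and seeded recovery batteries.

These functions wire the modules into the workflows a user would run:
simulate a strain and call its ploidy, and score the caller / chainer /
classifier against planted truth under the study conditions the package is
designed for (haploid strains with near-zero heterozygosity vs diploid
strains at 0.20–2.75 het sites/kb, ~100x genome coverage, chromosome-scale
assemblies with up to two aneuploid chromosomes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .ploidy import (
    GenomePloidyReport,
    HetSiteSet,
    call_genome_ploidy,
    filter_het_sites,
    fit_af_models,
    normalize_depth,
    ploidy_label,
)
from .simulate import (
    PlantedEvent,
    SimulationConfig,
    SimulationTruth,
    fission,
    reciprocal_translocation,
    simulate_depth,
    simulate_rearrangements,
    simulate_truth,
    simulate_variants,
)
from .synteny import chain_collinear, classify_rearrangements, index_anchors

#: heterozygosity densities (sites per kb) of the diploid study strains
DIPLOID_HET_RATES = (0.20, 0.44, 2.75)
#: residual error-site rate seen in the haploid study strains (per kb)
HAPLOID_ERROR_SITE_RATE = 0.02
#: genome-wide sequencing coverage emulated by the batteries
TARGET_COVERAGE = 100.0


def run_ploidy_pipeline(
    config: SimulationConfig,
) -> tuple[GenomePloidyReport, SimulationTruth]:
    """Simulate one strain's evidence and run the full ploidy caller on it."""
    truth = simulate_truth(config)
    variants = simulate_variants(truth, config)
    depths = simulate_depth(truth, config)
    het = filter_het_sites(variants, truth.chrom_lengths)
    fits = {c: fit_af_models(h) for c, h in het.items()}
    profile = normalize_depth(depths, config.window, config.step)
    report = call_genome_ploidy(fits, profile.copy_ratio, het)
    return report, truth


@dataclass
class RecoveryScore:
    """Outcome of a seeded recovery battery."""

    n_genomes: int
    n_chromosomes: int
    chrom_correct: int
    label_correct: int

    @property
    def chrom_accuracy(self) -> float:
        return self.chrom_correct / self.n_chromosomes

    @property
    def label_accuracy(self) -> float:
        return self.label_correct / self.n_genomes


def ploidy_recovery_battery(
    seed: int,
    n_genomes: int = 50,
    n_chroms: int = 12,
    chrom_length: int = 100_000,
) -> RecoveryScore:
    """Score copy-number and genome-label recovery over simulated strains.

    Each genome draws a baseline ploidy from {1, 2} and 0–2 aneuploid
    chromosomes (copy 2 in haploids; copy 1 or 3 in diploids). Diploids get
    a heterozygosity density from the study range; haploids carry only
    residual error sites. Per-copy depth is set so genome coverage is ~100x.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n_chrom_total = chrom_correct = label_correct = 0
    for i in range(n_genomes):
        baseline = int(rng.choice([1, 2]))
        n_aneu = int(rng.choice([0, 1, 2]))
        chrom_ids = [f"chr{j + 1:02d}" for j in range(n_chroms)]
        aneu = rng.choice(n_chroms, size=n_aneu, replace=False)
        overrides = {}
        for a in aneu:
            if baseline == 1:
                overrides[chrom_ids[a]] = 2
            else:
                overrides[chrom_ids[a]] = int(rng.choice([1, 3]))
        het_rate = float(rng.choice(DIPLOID_HET_RATES)) if baseline == 2 else 0.0
        cfg = SimulationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            chrom_lengths=[chrom_length] * n_chroms,
            baseline_ploidy=baseline,
            copy_number_overrides=overrides,
            het_rate=het_rate,
            error_site_rate=HAPLOID_ERROR_SITE_RATE if baseline == 1 else 0.0,
            mean_depth=TARGET_COVERAGE / baseline,
            telomere_copies=0,
        )
        report, truth = run_ploidy_pipeline(cfg)
        calls = {c.chrom_id: c.copy_number for c in report.calls}
        for c, k_true in truth.copy_number.items():
            n_chrom_total += 1
            if calls[c] == k_true:
                chrom_correct += 1
        true_label = ploidy_label(
            baseline, any(k != baseline for k in truth.copy_number.values())
        )
        if report.ploidy_state_label == true_label:
            label_correct += 1
    return RecoveryScore(n_genomes, n_chrom_total, chrom_correct, label_correct)


def chloropicon_like_scenario(seed: int = 11) -> tuple[GenomePloidyReport, SimulationTruth]:
    """The mostly-diploid scenario: 20 chromosomes, chromosome 17 at copy 3.

    Mirrors a diploid strain carrying a triploid chromosome confirmed by
    both the allele-frequency spectrum (1/3 and 2/3 modes) and a 1.5x depth
    ratio. Chromosomes are 200 kb so even a 0.2/kb heterozygosity density
    yields an informative AF fit.
    """
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths=[200_000] * 20,
        baseline_ploidy=2,
        copy_number_overrides={"chr17": 3},
        het_rate=0.2,
        mean_depth=TARGET_COVERAGE / 2,
        telomere_copies=0,
    )
    return run_ploidy_pipeline(cfg)


def af_model_selection_battery(
    seed: int,
    n_replicates: int = 20,
    n_sites: int = 200,
    depth: float = 100.0,
    ks: tuple[int, ...] = (2, 3),
) -> dict[int, int]:
    """Count BIC recoveries of the true copy number per candidate ``k``.

    Each replicate draws ``n_sites`` heterozygous sites at negative-binomial
    total depth around ``depth`` with uniform latent dosage, then refits the
    mixture over k in {1, 2, 3}.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    e = 0.01
    recovered = {k: 0 for k in ks}
    for k in ks:
        for _ in range(n_replicates):
            size = 20.0
            totals = rng.negative_binomial(size, size / (size + depth), n_sites)
            totals = np.maximum(totals, 1)
            js = rng.integers(1, k, size=n_sites)
            probs = (js / k) * (1 - 2 * e) + e
            alts = rng.binomial(totals, probs)
            hs = HetSiteSet("sim", list(zip(alts.tolist(), totals.tolist())), 1_000_000)
            fit = fit_af_models(hs, error_rate=e)
            if fit.best_k_af == k:
                recovered[k] += 1
    return recovered


def brute_force_monotone_runs(
    perm: list[int], min_anchors: int = 2
) -> list[tuple[int, int, str]]:
    """Reference enumeration of maximal rank-adjacent monotone runs.

    Independent of the chaining implementation: walks the B-rank sequence of
    a single chromosome pair and splits wherever the step is not exactly +1
    or -1 in the current direction. Returns (start index, end index,
    orientation) triples for runs of at least ``min_anchors`` anchors.
    """
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(perm)
    while i < n:
        j = i
        direction = 0
        while j + 1 < n:
            step = perm[j + 1] - perm[j]
            if step not in (1, -1):
                break
            if direction == 0:
                direction = step
            elif step != direction:
                break
            j += 1
        if j - i + 1 >= min_anchors:
            runs.append((i, j, "reverse" if direction == -1 else "forward"))
        i = j + 1 if j > i else i + 1
    return runs


def _random_events(
    rng: np.random.Generator, n_events: int, n_chroms: int, genes_per_chrom: int
) -> list[PlantedEvent]:
    """Non-overlapping fission/translocation specs on distinct chromosomes."""
    avail = [f"chrB{i + 1:02d}" for i in range(n_chroms)]
    rng.shuffle(avail)
    events: list[PlantedEvent] = []
    lo, hi = 6, genes_per_chrom - 6
    for _ in range(n_events):
        if len(avail) >= 2 and rng.random() < 0.4:
            cx, cy = avail.pop(), avail.pop()
            events.append(
                reciprocal_translocation(
                    cx, int(rng.integers(lo, hi)), cy, int(rng.integers(lo, hi))
                )
            )
        else:
            events.append(fission(avail.pop(), int(rng.integers(lo, hi))))
    return events


def rearrangement_recovery_battery(
    seed: int,
    n_seeds: int = 25,
    n_chroms: int = 12,
    genes_per_chrom: int = 50,
) -> tuple[int, int]:
    """Plant 1–5 events per replicate; count exact multiset recoveries.

    Replicate 0 always plants the three fission/fusion plus two reciprocal
    translocation combination; the rest draw event lists at random on
    distinct chromosomes. Returns (n recovered exactly, n replicates).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    n_ok = 0
    for rep in range(n_seeds):
        if rep == 0:
            events = [
                fission("chrB01", 25), fission("chrB02", 20), fission("chrB03", 30),
                reciprocal_translocation("chrB04", 20, "chrB05", 25),
                reciprocal_translocation("chrB06", 15, "chrB07", 30),
            ]
        else:
            events = _random_events(
                rng, int(rng.integers(1, 6)), n_chroms, genes_per_chrom
            )
        anchors, truth = simulate_rearrangements(
            [genes_per_chrom] * n_chroms, events, seed=int(rng.integers(0, 2**31 - 1))
        )
        indexed = index_anchors(anchors)
        blocks = chain_collinear(indexed)
        detected = classify_rearrangements(blocks, indexed)
        if Counter(e.type for e in detected) == Counter(
            e.detected_type for e in truth.events
        ):
            n_ok += 1
    return n_ok, n_seeds
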