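"""Ground-truthed synthetic data for every pipeline stage.

The generator emits *post-calling* evidence — chromosome sequences, variant
sites with read counts, per-base depth profiles, and ortholog anchor tables —
with the statistical structure the downstream analyses assume:

* chromosomes are capped by tandem arrays of the T{3,5}AGG telomere-unit
  family (hexamer to octamer), reverse-complemented at the 5' end;
* heterozygous sites occur at a per-kb Poisson rate in the chromosome core;
  a site on a copy-``k`` chromosome carries a latent allele dosage ``j``
  drawn uniformly from ``{1..k-1}``, its total read depth is negative
  binomial with mean ``mean_depth * k``, and its alternate-allele count is
  binomial with success probability ``(j/k)(1-2e) + e`` (sequencing error
  ``e`` shrinks the modes toward 0.5);
* per-position depth is negative binomial with mean ``mean_depth * k`` and a
  configurable dispersion (size) parameter, so windowed depth scales with
  the per-chromosome copy ratio;
* an ancestral gene order is transformed by fission/fusion, reciprocal
  translocation, and inversion events into a pair of anchor tables.

Every operation derives its random stream from ``config.seed`` with a fixed
per-stage stream id, so a given config reproduces byte-identical outputs
regardless of which stages are run or in which order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import AnchorRecord, ChromosomeSeq, VariantSite, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed substream ids: genome / variants / depth keep independent,
# reproducible streams off the one user seed
_STREAM_GENOME = 1
_STREAM_VARIANTS = 2
_STREAM_DEPTH = 3

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated strain.

    ``mean_depth`` is the expected read depth contributed by a single
    chromosome copy; a chromosome at copy number ``k`` therefore has expected
    depth ``mean_depth * k``. ``depth_dispersion`` is the negative-binomial
    size parameter (variance = m + m^2/size); large values approach Poisson.
    ``het_rate`` is heterozygous sites per kb on copy >= 2 chromosomes.
    ``error_site_rate`` plants spurious homozygous-error sites (per kb, any
    copy number) whose alternate fraction is just the error rate — these
    emulate the residual variant calls seen in haploid strains.
    """

    seed: int = 0
    chrom_lengths: Sequence[int] = (100_000,)
    baseline_ploidy: int = 2
    copy_number_overrides: Mapping[str, int] = field(default_factory=dict)
    het_rate: float = 0.5  # per kb
    mean_depth: float = 50.0  # per haploid copy
    depth_dispersion: float = 20.0  # NB size
    telomere_unit: str = "TTTAGG"
    telomere_copies: int = 12
    uncapped_ends: Sequence[tuple[str, str]] = ()
    error_rate: float = 0.01
    error_site_rate: float = 0.0  # per kb
    telomere_depth_attenuation: float = 1.0  # 1.0 = off
    window: int = 10_000
    step: int = 5_000
    strain_id: str = "sim"

    def __post_init__(self) -> None:
        if self.baseline_ploidy < 1:
            raise ConfigError("baseline_ploidy must be >= 1")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ConfigError("error_rate must lie in [0, 0.1]")
        if self.depth_dispersion <= 0:
            raise ConfigError("depth_dispersion must be > 0")
        if self.step > self.window:
            raise ConfigError("step must be <= window")
        if self.telomere_copies < 0:
            raise ConfigError("telomere_copies must be >= 0")
        if (
            self.het_rate > 0
            and self.baseline_ploidy == 1
            and not any(k > 1 for k in self.copy_number_overrides.values())
        ):
            raise ConfigError(
                "het_rate > 0 requires baseline_ploidy >= 2 or a copy-number "
                "override > 1: haploid chromosomes carry no heterozygous sites"
            )

    @property
    def chrom_ids(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(len(self.chrom_lengths))]

    def copy_number(self, chrom_id: str) -> int:
        return int(self.copy_number_overrides.get(chrom_id, self.baseline_ploidy))


@dataclass
class PlantedEvent:
    """One structural event applied to genome B's gene order."""

    kind: str  # fission | fusion | reciprocal_translocation | inversion
    params: dict

    @property
    def detected_type(self) -> str:
        """Event type the rearrangement classifier should report."""
        if self.kind in ("fission", "fusion"):
            return "fusion_fission"
        if self.kind == "reciprocal_translocation":
            return "reciprocal_translocation"
        return "intra_shift"


@dataclass
class SimulationTruth:
    """Ground-truth labels emitted alongside every generated file set."""

    chrom_lengths: dict[str, int]
    copy_number: dict[str, int]
    baseline_ploidy: int
    telomere_spans: dict[str, tuple[int, int]]  # (5' array len, 3' array len)
    telomere_capped: dict[str, dict[str, bool]]  # chrom -> end -> capped
    het_sites: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # chrom -> [(pos, latent dosage j)]; expected alt fraction is j / copy_number
    error_sites: dict[str, list[int]] = field(default_factory=dict)
    events: list[PlantedEvent] = field(default_factory=list)

    def expected_alt_fraction(self, chrom_id: str, j: int) -> float:
        return j / self.copy_number[chrom_id]

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["events"] = [dataclasses.asdict(e) for e in self.events]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["events"] = [PlantedEvent(**e) for e in payload["events"]]
        payload["chrom_lengths"] = {k: int(v) for k, v in payload["chrom_lengths"].items()}
        payload["copy_number"] = {k: int(v) for k, v in payload["copy_number"].items()}
        payload["telomere_spans"] = {
            k: tuple(v) for k, v in payload["telomere_spans"].items()
        }
        payload["het_sites"] = {
            k: [tuple(t) for t in v] for k, v in payload["het_sites"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _telomere_array(rng: np.random.Generator, n_units: int) -> str:
    """Tandem array of n_units from the T{3,5}AGG family, lengths 6/7/8 uniform."""
    lengths = rng.integers(3, 6, size=n_units)  # number of leading Ts
    return "".join("T" * int(t) + "AGG" for t in lengths)


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Build the ground-truth skeleton (copy numbers, telomere plan) only.

    The sequence-free entry point: variant and depth simulation need lengths
    and copy numbers, not bases.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    uncapped = {(c, e) for c, e in config.uncapped_ends}
    spans: dict[str, tuple[int, int]] = {}
    capped: dict[str, dict[str, bool]] = {}
    for chrom_id, length in zip(config.chrom_ids, config.chrom_lengths):
        cap5 = config.telomere_copies > 0 and (chrom_id, FIVE_PRIME) not in uncapped
        cap3 = config.telomere_copies > 0 and (chrom_id, THREE_PRIME) not in uncapped
        arr5 = _telomere_array(rng, config.telomere_copies) if cap5 else ""
        arr3 = _telomere_array(rng, config.telomere_copies) if cap3 else ""
        if length < 2 * max(len(arr5), len(arr3)) + 1:
            raise ConfigError(
                f"{chrom_id}: length {length} too short for telomere arrays"
            )
        spans[chrom_id] = (len(arr5), len(arr3))
        capped[chrom_id] = {FIVE_PRIME: cap5, THREE_PRIME: cap3}
        # keep rng state aligned with simulate_genome: draw the core too
        rng.integers(0, 4, size=length - len(arr5) - len(arr3))
    return SimulationTruth(
        chrom_lengths=dict(zip(config.chrom_ids, map(int, config.chrom_lengths))),
        copy_number={c: config.copy_number(c) for c in config.chrom_ids},
        baseline_ploidy=config.baseline_ploidy,
        telomere_spans=spans,
        telomere_capped=capped,
    )


def simulate_genome(config: SimulationConfig) -> tuple[list[ChromosomeSeq], SimulationTruth]:
    """Generate chromosome sequences: 5' telomere array (reverse-complement
    orientation) + uniform A/C/G/T core + 3' telomere array."""
    rng = _rng(config.seed, _STREAM_GENOME)
    uncapped = {(c, e) for c, e in config.uncapped_ends}
    chroms: list[ChromosomeSeq] = []
    spans: dict[str, tuple[int, int]] = {}
    capped: dict[str, dict[str, bool]] = {}
    for chrom_id, length in zip(config.chrom_ids, config.chrom_lengths):
        cap5 = config.telomere_copies > 0 and (chrom_id, FIVE_PRIME) not in uncapped
        cap3 = config.telomere_copies > 0 and (chrom_id, THREE_PRIME) not in uncapped
        arr5 = revcomp(_telomere_array(rng, config.telomere_copies)) if cap5 else ""
        arr3 = _telomere_array(rng, config.telomere_copies) if cap3 else ""
        if length < 2 * max(len(arr5), len(arr3)) + 1:
            raise ConfigError(
                f"{chrom_id}: length {length} too short for telomere arrays"
            )
        core_len = length - len(arr5) - len(arr3)
        core = _BASES[rng.integers(0, 4, size=core_len)].tobytes().decode()
        chroms.append(
            ChromosomeSeq(config.strain_id, chrom_id, arr5 + core + arr3)
        )
        spans[chrom_id] = (len(arr5), len(arr3))
        capped[chrom_id] = {FIVE_PRIME: cap5, THREE_PRIME: cap3}
    truth = SimulationTruth(
        chrom_lengths=dict(zip(config.chrom_ids, map(int, config.chrom_lengths))),
        copy_number={c: config.copy_number(c) for c in config.chrom_ids},
        baseline_ploidy=config.baseline_ploidy,
        telomere_spans=spans,
        telomere_capped=capped,
    )
    return chroms, truth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_variants(truth: SimulationTruth, config: SimulationConfig) -> list[VariantSite]:
    """Draw heterozygous and (optionally) error variant sites with read counts.

    Updates ``truth.het_sites`` / ``truth.error_sites`` in place and returns
    the combined site list sorted by (chromosome, position).
    """
    rng = _rng(config.seed, _STREAM_VARIANTS)
    e = config.error_rate
    sites: list[VariantSite] = []
    for chrom_id, length in truth.chrom_lengths.items():
        k = truth.copy_number[chrom_id]
        span5, span3 = truth.telomere_spans[chrom_id]
        lo, hi = span5 + 1, length - span3  # core, 1-based inclusive
        chrom_sites: list[tuple[int, int, int, float]] = []  # pos, j, k, p
        if k >= 2 and config.het_rate > 0:
            n_het = rng.poisson(config.het_rate * length / 1000.0)
            n_het = min(n_het, hi - lo + 1)
            pos = rng.choice(np.arange(lo, hi + 1), size=n_het, replace=False)
            js = rng.integers(1, k, size=n_het)
            for p_, j_ in zip(pos, js):
                frac = j_ / k
                chrom_sites.append((int(p_), int(j_), k, frac * (1 - 2 * e) + e))
        truth.het_sites[chrom_id] = [(p_, j_) for p_, j_, _, _ in chrom_sites]
        err_positions: list[int] = []
        if config.error_site_rate > 0:
            n_err = rng.poisson(config.error_site_rate * length / 1000.0)
            taken = {p_ for p_, *_ in chrom_sites}
            pos = rng.integers(lo, hi + 1, size=n_err)
            for p_ in pos:
                if int(p_) not in taken:
                    err_positions.append(int(p_))
                    chrom_sites.append((int(p_), 0, k, max(e, 1e-4)))
        truth.error_sites[chrom_id] = err_positions
        chrom_sites.sort()
        if chrom_sites:
            totals = _nb_draw(
                rng, config.mean_depth * k, config.depth_dispersion, len(chrom_sites)
            )
            totals = np.maximum(totals, 1)
            probs = np.array([p for *_, p in chrom_sites])
            alts = rng.binomial(totals, probs)
            refs = totals - alts
            ref_bases = _BASES[rng.integers(0, 4, size=len(chrom_sites))]
            alt_shift = rng.integers(1, 4, size=len(chrom_sites))
            for (pos_, j_, _, _), rc, ac, rb, sh in zip(
                chrom_sites, refs, alts, ref_bases, alt_shift
            ):
                ref = rb.decode()
                alt = "ACGT"[("ACGT".index(ref) + int(sh)) % 4]
                sites.append(
                    VariantSite(chrom_id, pos_, ref, alt, int(rc), int(ac))
                )
    return sites


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def simulate_depth(
    truth: SimulationTruth, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Per-position read depth: NB(mean = mean_depth * copy_number, dispersion).

    Telomere-array positions are attenuated by ``telomere_depth_attenuation``
    (1.0 by default, i.e. no attenuation) to emulate mapping loss in repeats.
    """
    rng = _rng(config.seed, _STREAM_DEPTH)
    out: dict[str, np.ndarray] = {}
    for chrom_id, length in truth.chrom_lengths.items():
        k = truth.copy_number[chrom_id]
        mean = config.mean_depth * k
        depth = _nb_draw(rng, mean, config.depth_dispersion, length)
        att = config.telomere_depth_attenuation
        if att != 1.0:
            span5, span3 = truth.telomere_spans[chrom_id]
            if span5:
                depth[:span5] = _nb_draw(rng, mean * att, config.depth_dispersion, span5)
            if span3:
                depth[-span3:] = _nb_draw(rng, mean * att, config.depth_dispersion, span3)
        out[chrom_id] = depth.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------

def fission(chrom: str, breakpoint: int) -> PlantedEvent:
    """Split one B chromosome into two at gene index ``breakpoint``."""
    return PlantedEvent("fission", {"chrom": chrom, "breakpoint": int(breakpoint)})


def fusion(chrom_x: str, chrom_y: str) -> PlantedEvent:
    """Concatenate two B chromosomes into one."""
    return PlantedEvent("fusion", {"chrom_x": chrom_x, "chrom_y": chrom_y})


def reciprocal_translocation(
    chrom_x: str, break_x: int, chrom_y: str, break_y: int
) -> PlantedEvent:
    """Exchange the tails of two B chromosomes at the two gene indices."""
    return PlantedEvent(
        "reciprocal_translocation",
        {"chrom_x": chrom_x, "break_x": int(break_x),
         "chrom_y": chrom_y, "break_y": int(break_y)},
    )


def inversion(chrom: str, start: int, stop: int) -> PlantedEvent:
    """Reverse the gene slice [start, stop) on a B chromosome, flipping strands."""
    return PlantedEvent("inversion", {"chrom": chrom, "start": int(start), "stop": int(stop)})


def simulate_rearrangements(
    n_genes_per_chrom: Sequence[int],
    events: Iterable[PlantedEvent] = (),
    seed: int = 0,
    strain_a: str = "genomeA",
    strain_b: str = "genomeB",
) -> tuple[list[AnchorRecord], SimulationTruth]:
    """Transform an ancestral gene order into a pair of anchor tables.

    Genome A keeps the ancestral order; ``events`` are applied sequentially
    to genome B's chromosome list. Anchors carry synthetic coordinates at
    1 kb gene spacing. Gene-index breakpoints are validated against the
    chromosome's current gene count.
    """
    a_chroms: dict[str, list[tuple[str, str]]] = {}  # chrom -> [(gene, strand)]
    gid = 0
    for i, n in enumerate(n_genes_per_chrom):
        chrom = f"chrA{i + 1:02d}"
        genes = []
        for _ in range(n):
            gid += 1
            genes.append((f"g{gid:05d}", "+"))
        a_chroms[chrom] = genes

    b_chroms: dict[str, list[tuple[str, str]]] = {
        c.replace("chrA", "chrB"): list(genes) for c, genes in a_chroms.items()
    }
    next_new = len(n_genes_per_chrom) + 1
    events = list(events)
    for ev in events:
        p = ev.params
        if ev.kind == "fission":
            chrom = p["chrom"]
            if chrom not in b_chroms:
                raise ConfigError(f"fission: unknown B chromosome {chrom!r}")
            genes = b_chroms.pop(chrom)
            bp = p["breakpoint"]
            if not 0 < bp < len(genes):
                raise ConfigError(f"fission breakpoint {bp} outside gene range")
            b_chroms[f"chrB{next_new:02d}"] = genes[:bp]
            next_new += 1
            b_chroms[f"chrB{next_new:02d}"] = genes[bp:]
            next_new += 1
        elif ev.kind == "fusion":
            x, y = p["chrom_x"], p["chrom_y"]
            if x not in b_chroms or y not in b_chroms:
                raise ConfigError(f"fusion: unknown B chromosome {x!r} or {y!r}")
            genes = b_chroms.pop(x) + b_chroms.pop(y)
            b_chroms[f"chrB{next_new:02d}"] = genes
            next_new += 1
        elif ev.kind == "reciprocal_translocation":
            x, y = p["chrom_x"], p["chrom_y"]
            if x not in b_chroms or y not in b_chroms:
                raise ConfigError("reciprocal_translocation: unknown B chromosome")
            bx, by = p["break_x"], p["break_y"]
            gx, gy = b_chroms[x], b_chroms[y]
            if not (0 < bx < len(gx) and 0 < by < len(gy)):
                raise ConfigError("translocation breakpoint outside gene range")
            b_chroms[x], b_chroms[y] = gx[:bx] + gy[by:], gy[:by] + gx[bx:]
        elif ev.kind == "inversion":
            chrom = p["chrom"]
            if chrom not in b_chroms:
                raise ConfigError(f"inversion: unknown B chromosome {chrom!r}")
            i, j = p["start"], p["stop"]
            genes = b_chroms[chrom]
            if not (0 <= i < j <= len(genes)):
                raise ConfigError("inversion slice outside gene range")
            flipped = [
                (g, "-" if s == "+" else "+") for g, s in reversed(genes[i:j])
            ]
            b_chroms[chrom] = genes[:i] + flipped + genes[j:]
        else:
            raise ConfigError(f"unknown event kind {ev.kind!r}")

    b_index: dict[str, tuple[str, int, str]] = {}
    for chrom, genes in b_chroms.items():
        for idx, (g, s) in enumerate(genes):
            b_index[g] = (chrom, idx, s)

    anchors: list[AnchorRecord] = []
    for chrom_a, genes in a_chroms.items():
        for idx, (g, strand_a_) in enumerate(genes):
            chrom_b, idx_b, strand_b_ = b_index[g]
            anchors.append(
                AnchorRecord(
                    orthogroup_id=f"OG_{g}",
                    strain_a=strain_a, chrom_a=chrom_a,
                    pos_a=(idx + 1) * 1000, strand_a=strand_a_, gene_a=f"{g}_a",
                    strain_b=strain_b, chrom_b=chrom_b,
                    pos_b=(idx_b + 1) * 1000, strand_b=strand_b_, gene_b=f"{g}_b",
                )
            )

    truth = SimulationTruth(
        chrom_lengths={c: len(g) * 1000 for c, g in a_chroms.items()},
        copy_number={c: 1 for c in a_chroms},
        baseline_ploidy=1,
        telomere_spans={c: (0, 0) for c in a_chroms},
        telomere_capped={
            c: {FIVE_PRIME: False, THREE_PRIME: False} for c in a_chroms
        },
        events=events,
    )
    return anchors, truth
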