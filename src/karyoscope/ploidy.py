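"""Per-chromosome copy-number and genome ploidy inference.

The evidence is twofold, mirroring how aneuploidy is confirmed in practice:

1.  **Allele-frequency spectra.** At a heterozygous site on a chromosome
    present in ``k`` copies, the alternate allele occupies ``j`` of the
    ``k`` copies, so its read fraction clusters at ``j/k``. Retained sites
    (alt fraction within a het window, default [0.10, 0.90]) are scored
    under a binomial mixture per candidate ``k``: the site likelihood is the
    equal-weight average over ``j in {1..k-1}`` of
    ``Binomial(alt; total, p_j)`` with ``p_j = (j/k)(1-2e) + e`` (sequencing
    error ``e`` shrinks the modes toward 0.5); ``k = 1`` is an error-only
    model mixing ``p = e`` and ``p = 1 - e`` (alternate allele absent or
    fixed). The mixture has no free parameters, so BIC reduces
    to ``-2 log L`` and model choice is driven purely by mode positions.

2.  **Normalized depth.** Windowed mean depth (default 10 kb windows,
    5 kb step) is divided by the genome-wide median of window means; the
    per-chromosome copy ratio is the median of its normalized windows, so a
    chromosome at copy ``k`` in a baseline-``b`` genome sits near ``k/b``.

The genome call combines both: chromosomes near the modal copy ratio define
the baseline set; baseline ploidy is the AF-model consensus over informative
baseline chromosomes, falling back to a heterozygosity-density rule
(a genome below ``hap_threshold`` het sites/kb with no informative AF fit is
haploid). Per-chromosome copy number is ``round(ratio * baseline)``;
an aneuploid call is corroborated when the chromosome's own AF fit equals
the depth-implied copy number ("af+depth"), otherwise flagged "depth_only".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .io_formats import VariantSite

DEFAULT_HET_WINDOW = (0.10, 0.90)
DEFAULT_K_CANDIDATES = (1, 2, 3)
DEFAULT_ERROR_RATE = 0.01
DEFAULT_MIN_SITES = 30
DEFAULT_HAP_THRESHOLD = 0.10  # het sites per kb
DEFAULT_BASELINE_BAND = 0.2  # copy-ratio distance from the modal ratio


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal-style half-up rounding used for all reported densities."""
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def per_kb_density(count: int, length_bp: int) -> float:
    """Events per kilobase; the unit used for heterozygosity and gene density."""
    if length_bp <= 0:
        raise ValidationError("length must be positive")
    return count / (length_bp / 1000.0)


# ---------------------------------------------------------------------------
# het-site filtering
# ---------------------------------------------------------------------------

@dataclass
class HetSiteSet:
    """Retained heterozygous sites of one chromosome."""

    chrom_id: str
    sites: list[tuple[int, int]]  # (alt_count, total_count)
    length_bp: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def het_density(self) -> float:
        return per_kb_density(self.n_sites, self.length_bp)


def filter_het_sites(
    variants: Sequence[VariantSite],
    chrom_lengths: Mapping[str, int],
    af_window: tuple[float, float] = DEFAULT_HET_WINDOW,
) -> dict[str, HetSiteSet]:
    """Retain SNVs whose alternate fraction lies inside the het window.

    Sites above the window are treated as homozygous-alternate, below as
    sub-threshold; both are excluded. Every chromosome in ``chrom_lengths``
    receives an entry (possibly empty); a variant on an unknown chromosome
    raises :class:`ValidationError`.
    """
    lo, hi = af_window
    out = {
        c: HetSiteSet(c, [], int(length)) for c, length in chrom_lengths.items()
    }
    for v in variants:
        if v.chrom_id not in out:
            raise ValidationError(
                f"variant on chromosome {v.chrom_id!r} absent from length map"
            )
        if lo <= v.alt_freq <= hi:
            total = v.total_count
            if total is None:
                continue  # AF-only site: counts required for model fitting
            out[v.chrom_id].sites.append((v.alt_count, total))
    return out


def genome_het_density(het: Mapping[str, HetSiteSet]) -> float:
    """Total retained sites per kb over all chromosomes."""
    n = sum(h.n_sites for h in het.values())
    bp = sum(h.length_bp for h in het.values())
    return per_kb_density(n, bp)


# ---------------------------------------------------------------------------
# AF model selection
# ---------------------------------------------------------------------------

@dataclass
class AFModelFit:
    """Binomial-mixture fit of one chromosome's allele-frequency spectrum."""

    chrom_id: str
    n_sites: int
    log_likelihood: dict[int, float]
    bic: dict[int, float]
    best_k_af: int | None  # None = uninformative (too few sites)

    @property
    def informative(self) -> bool:
        return self.best_k_af is not None


def _mixture_loglik(
    alt: np.ndarray, total: np.ndarray, k: int, error_rate: float
) -> float:
    """Summed log-likelihood of sites under the copy-``k`` mixture.

    ``k = 1`` is the error-only model: a site carries a single allele and
    reads disagree with it at the error rate, so the alternate fraction sits
    near ``e`` (alt allele absent) or ``1 - e`` (alt allele fixed).
    """
    if k == 1:
        probs = np.array([error_rate, 1 - error_rate])
    else:
        j = np.arange(1, k)
        probs = (j / k) * (1 - 2 * error_rate) + error_rate
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    # log Binomial pmf for each site x mixture component
    a = alt[:, None]
    n = total[:, None]
    p = probs[None, :]
    log_pmf = (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
        + a * np.log(p) + (n - a) * np.log1p(-p)
    )
    site_ll = logsumexp(log_pmf, axis=1) - np.log(len(probs))
    return float(site_ll.sum())


def fit_af_models(
    sites: HetSiteSet,
    k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_sites: int = DEFAULT_MIN_SITES,
) -> AFModelFit:
    """Select the copy number whose mixture best explains the AF spectrum.

    The mixtures carry zero free parameters (fixed equal weights), so
    ``BIC = -2 log L`` and the lowest-BIC candidate wins; ties break toward
    the smaller ``k``. Fewer than ``min_sites`` usable sites yields an
    uninformative fit (``best_k_af is None``). Zero-depth sites are dropped.
    """
    pairs = [(a, t) for a, t in sites.sites if t > 0]
    lls: dict[int, float] = {}
    bics: dict[int, float] = {}
    if pairs:
        alt = np.array([a for a, _ in pairs], dtype=float)
        total = np.array([t for _, t in pairs], dtype=float)
        for k in k_candidates:
            ll = _mixture_loglik(alt, total, k, error_rate)
            lls[k] = ll
            bics[k] = -2.0 * ll  # p = 0 free parameters
    if len(pairs) < min_sites:
        best = None
    else:
        best = min(sorted(bics), key=lambda k: (bics[k], k))
    return AFModelFit(
        chrom_id=sites.chrom_id,
        n_sites=len(pairs),
        log_likelihood=lls,
        bic=bics,
        best_k_af=best,
    )


# ---------------------------------------------------------------------------
# depth normalization
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Sliding-window normalized depth and per-chromosome copy ratios."""

    windows: pd.DataFrame  # chrom, start, end, mean_depth, normalized
    copy_ratio: dict[str, float]
    genome_median: float


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if length <= window:
        return np.array([0])
    n = (length - window) // step + 1
    return np.arange(n) * step


def normalize_depth(
    depths: Mapping[str, np.ndarray],
    window: int = 10_000,
    step: int = 5_000,
    mask: Mapping[str, np.ndarray] | None = None,
) -> DepthProfile:
    """Windowed mean depth normalized by the genome median of window means.

    ``mask`` maps chromosome to a boolean array marking positions to exclude
    (N-rich or repeat regions); windows with more than half their positions
    masked are reported with a missing value and ignored in medians.
    Scale-invariant: multiplying all depths by c > 0 leaves every normalized
    value unchanged.
    """
    rows = []
    for chrom, arr in depths.items():
        arr = np.asarray(arr, dtype=float)
        m = None if mask is None else mask.get(chrom)
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        if m is not None:
            keep = ~np.asarray(m, dtype=bool)
            ksum = np.concatenate([[0], np.cumsum(keep.astype(np.int64))])
            vsum = np.concatenate([[0.0], np.cumsum(arr * keep)])
        for s in _window_starts(len(arr), window, step):
            e = min(s + window, len(arr))
            if m is None:
                mean = (csum[e] - csum[s]) / (e - s)
            else:
                n_keep = ksum[e] - ksum[s]
                if n_keep < (e - s) / 2:
                    mean = np.nan
                else:
                    mean = (vsum[e] - vsum[s]) / n_keep
            rows.append((chrom, int(s + 1), int(e), mean))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth"])
    genome_median = float(np.nanmedian(df["mean_depth"].to_numpy()))
    if not np.isfinite(genome_median) or genome_median <= 0:
        raise ValidationError("normalize_depth: genome median depth is not positive")
    df["normalized"] = df["mean_depth"] / genome_median
    ratios = {
        str(c): float(np.nanmedian(g["normalized"].to_numpy()))
        for c, g in df.groupby("chrom", sort=False)
    }
    return DepthProfile(windows=df, copy_ratio=ratios, genome_median=genome_median)


# ---------------------------------------------------------------------------
# genome-level call
# ---------------------------------------------------------------------------

@dataclass
class PloidyCall:
    """Copy-number decision for one chromosome."""

    chrom_id: str
    copy_ratio: float
    copy_number: int
    evidence: str  # af_only | depth_only | af+depth
    aneuploid: bool
    best_k_af: int | None = None
    conflict: bool = False  # informative AF fit disagreeing with depth call


@dataclass
class GenomePloidyReport:
    """Baseline ploidy, per-chromosome calls, and heterozygosity totals."""

    baseline_ploidy: int
    ploidy_state_label: str
    calls: list[PloidyCall]
    het_sites_total: int
    het_density: float  # per kb, genome-wide
    baseline_evidence: str = "af+depth"

    @property
    def aneuploid_chroms(self) -> list[str]:
        return [c.chrom_id for c in self.calls if c.aneuploid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": c.chrom_id,
                    "copy_ratio": c.copy_ratio,
                    "copy_number": c.copy_number,
                    "best_k_af": "" if c.best_k_af is None else c.best_k_af,
                    "evidence": c.evidence,
                    "aneuploid": c.aneuploid,
                    "conflict": c.conflict,
                }
                for c in self.calls
            ]
        )


_PLOIDY_WORD = {1: "haploid", 2: "diploid", 3: "triploid", 4: "tetraploid"}


def ploidy_label(baseline: int, any_aneuploid: bool) -> str:
    word = _PLOIDY_WORD.get(baseline, f"{baseline}-ploid")
    return f"mostly {word}" if any_aneuploid else word


def call_genome_ploidy(
    fits: Mapping[str, AFModelFit],
    ratios: Mapping[str, float],
    het: Mapping[str, HetSiteSet],
    hap_threshold: float = DEFAULT_HAP_THRESHOLD,
    baseline_band: float = DEFAULT_BASELINE_BAND,
) -> GenomePloidyReport:
    """Combine AF-model fits and copy ratios into a genome ploidy report.

    Decision procedure:

    1. chromosomes whose copy ratio lies within ``baseline_band`` of the
       genome-modal ratio (ratios rounded to 0.1 for the mode) form the
       baseline set;
    2. baseline ploidy is the majority ``best_k_af`` over informative
       baseline chromosomes; with no informative chromosome the genome het
       density decides: below ``hap_threshold`` per kb → haploid, otherwise
       diploid with "depth_only" evidence. An off-baseline chromosome whose
       informative AF fit matches its depth under baseline 2 but not under
       the het-based call (e.g. a 1.5x chromosome with 1/3–2/3 modes) forces
       baseline 2 — the "aneuploid anchor" rule;
    3. per-chromosome copy number is ``round(ratio * baseline)`` (half-up,
       floor 1); aneuploid iff it differs from baseline; corroborated calls
       ("af+depth") require the chromosome's own informative AF fit to equal
       the copy number, otherwise "depth_only" (a disagreeing informative
       fit is additionally marked as a conflict, the depth call standing);
    4. the genome label is "mostly <baseline-word>" iff any chromosome is
       aneuploid.
    """
    chroms = list(ratios)
    if not chroms:
        raise ValidationError("call_genome_ploidy: no chromosomes")
    if set(fits) != set(chroms) or set(het) != set(chroms):
        raise ValidationError("call_genome_ploidy: chromosome sets disagree")

    rounded = Counter(round(ratios[c], 1) for c in chroms)
    top = max(rounded.values())
    modal_ratio = min(r for r, n in rounded.items() if n == top)
    baseline_set = [c for c in chroms if abs(ratios[c] - modal_ratio) <= baseline_band]

    votes = Counter(
        fits[c].best_k_af for c in baseline_set if fits[c].informative
    )
    g_density = genome_het_density(het)
    baseline_evidence = "af+depth"
    if votes:
        top_votes = max(votes.values())
        baseline = min(k for k, n in votes.items() if n == top_votes)
    else:
        baseline = 1 if g_density < hap_threshold else 2
        baseline_evidence = "depth_only"
        if baseline == 1:
            # aneuploid anchor: an off-baseline chromosome with an informative
            # AF fit that matches round(ratio * 2) pins the genome to diploid
            for c in chroms:
                f = fits[c]
                if c in baseline_set or not f.informative:
                    continue
                if f.best_k_af == _round_copy(ratios[c] * 2) != _round_copy(ratios[c]):
                    baseline = 2
                    baseline_evidence = "af_anchor"
                    break

    calls: list[PloidyCall] = []
    for c in chroms:
        cn = _round_copy(ratios[c] * baseline)
        f = fits[c]
        aneuploid = cn != baseline
        conflict = f.informative and f.best_k_af != cn
        evidence = "af+depth" if (f.informative and f.best_k_af == cn) else "depth_only"
        calls.append(
            PloidyCall(
                chrom_id=c,
                copy_ratio=float(ratios[c]),
                copy_number=cn,
                evidence=evidence,
                aneuploid=aneuploid,
                best_k_af=f.best_k_af,
                conflict=conflict,
            )
        )

    n_total = sum(het[c].n_sites for c in chroms)
    return GenomePloidyReport(
        baseline_ploidy=baseline,
        ploidy_state_label=ploidy_label(baseline, any(c.aneuploid for c in calls)),
        calls=calls,
        het_sites_total=n_total,
        het_density=g_density,
        baseline_evidence=baseline_evidence,
    )


def _round_copy(x: float) -> int:
    return max(1, math.floor(x + 0.5))
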