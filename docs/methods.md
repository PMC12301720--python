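# Methods

## Scope and data model

The pipeline consumes post-calling evidence rather than raw reads: a FASTA
assembly, a VCF of variant calls carrying per-sample read counts (or
VarScan-style percent frequencies), a 3-column per-base depth table in the
`samtools depth -aa` dialect, and tab-separated gene, anchor, and
orthogroup tables. Read mapping, variant calling, orthology inference, and
annotation are upstream tools' jobs; their outputs are this package's
inputs. Coordinates are 1-based closed everywhere internally; BED exports
convert to 0-based half-open.

## Ploidy inference

**Heterozygous-site filtering.** Biallelic SNVs with alternate-allele
fraction inside the het window (default [0.10, 0.90]) are retained. The
lower bound matches the common variant-caller minimum variant frequency of
0.1; the upper bound is its mirror image, treating sites above it as
homozygous-alternate differences from the reference rather than
heterozygosity. Heterozygosity density is retained sites per kb; reported
densities are rounded half-up to the printed precision (2 decimals per kb,
3 for gene density).

**Allele-frequency mixture.** A site on a copy-*k* chromosome with latent
dosage *j* has expected alternate fraction *j/k*. Each candidate *k* ≥ 2 is
scored by the equal-weight binomial mixture over *j* ∈ {1..k−1} with
p_j = (j/k)(1−2e) + e; the error rate *e* (default 0.01) shrinks modes
toward 0.5 so boundary modes remain proper probabilities. Equal fixed
weights are deliberate: the dosage mix is not estimated, the mixture has
zero free parameters, BIC reduces to −2 log L, and the k = 2 vs k = 3
contrast depends only on mode positions. The k = 1 (error-only) model is
the equal mixture of p = e and p = 1−e — a single-allele site whose
alternate allele is absent or fixed. The one-sided p = e alternative fails
on homozygous-alternate sites, where it would lose to the k = 2 mixture's
central mode; the two-sided form is the correct error-only null for such
sites. A chromosome with fewer than `min_sites` (default 30) usable sites
is *uninformative*; zero-depth sites are dropped. Ties in BIC break toward
smaller *k*. Candidates default to {1, 2, 3}; ploidy above 4 is out of
scope.

**Depth normalization.** Window means (default 10 kb window, 5 kb step,
matching the window the depth tracks are usually plotted with) are divided
by the genome-wide median of window means — the natural reference unit when
most chromosomes sit at the baseline copy number. A chromosome's copy ratio
is the median of its normalized windows. Masked positions (N-rich or
repeat) are excluded; a window with more than half its positions masked is
reported missing. The statistic is exactly scale-invariant.

**Genome call.** (1) Chromosomes with copy ratio within ±0.2 of the
genome-modal ratio (ratios rounded to 0.1 for the mode; ties toward the
smaller value) form the baseline set. (2) Baseline ploidy is the majority
informative AF fit over baseline chromosomes. With no informative
chromosome, genome heterozygosity density decides: below 0.10 /kb →
haploid, else diploid flagged `depth_only`. The 0.10 /kb threshold sits
between the densities observed in haploid strains (0.02–0.04 /kb, residual
caller noise) and diploid strains (0.20 /kb and up) with margin on both
sides. (3) The *aneuploid anchor* rule: if the het-based call is haploid
but an off-baseline chromosome has an informative AF fit matching its
depth-implied copy under baseline 2 (the classic 1.5× chromosome with
1/3–2/3 modes), baseline is forced to 2 — a triploid chromosome is only
interpretable in a diploid genome, and it anchors absolute ploidy even when
the baseline chromosomes are nearly homozygous. (4) Per-chromosome copy
number is round(ratio × baseline) (half-up, floor 1); aneuploid iff it
differs from baseline. An aneuploid call is `af+depth` when the
chromosome's own informative AF fit agrees, else `depth_only`; an
informative fit that disagrees is recorded as a conflict and the depth call
stands. (5) The genome label is "mostly ⟨word⟩" iff any chromosome is
aneuploid.

The explicit thresholds replace what is often done by visual inspection of
allele-frequency histograms; they are configurable and validated against
planted truth rather than against any particular script's internals.

## Telomere scanning

Terminal windows (default 500 bp) are scanned for maximal tandem runs of
the unit grammar `T{3,5}AGG` — the hexamer-to-octamer family observed in
green-algal chromosomes — in forward orientation at the 3′ end and via
reverse complement of the window at the 5′ end (one grammar serves both
ends and guarantees strand-convention consistency). An end is capped when
the best run has at least `min_copies` units (default 3): the chance of
three tandem units arising in a 500 bp random window is negligible
(verified empirically over seeded batteries), while short genuine arrays
are still accepted. Runs may mix unit lengths; the per-end spectrum counts
units by length. Interstitial telomere-like repeats are ignored. The motif
grammar is configurable for other taxa.

## Orthogroup partitioning

An orthogroup's Venn region is the exact set of strains (or species, after
projection) with at least one member gene, making the region counts a true
partition (asserted on every run). A species-specific orthogroup is one
whose members all belong to strains of a single species — it need not
include every strain of it. Species-specific gene fractions divide a
strain's genes in such orthogroups by the strain's *total predicted gene
count*, which the caller supplies; this is the denominator that reproduces
published per-strain percentages, since annotation includes genes absent
from protein orthogroup tables. The orthogroup table itself is taken as
given; sensitivity to the inference tool's clustering parameters is out of
scope.

## Collinear chaining and rearrangement classification

Anchors are ranked 0-based by gene midpoint per chromosome on each side.
Paralog-ambiguous anchors (a gene in several pairs) keep the pair with the
smallest coordinate offset between sides; the rest are dropped with a log
message. Chaining is greedy left-to-right over A-side rank within each
chromosome pair: a block extends while at most `gap` anchors are skipped on
either side and the B rank continues the established direction. With the
default `gap = 0` this is exactly the set of maximal runs whose B ranks
step by ±1 — the strictest chaining — and is verified equivalent to a
brute-force enumeration exhaustively for small inputs and on random
instances. `min_anchors` defaults to 3 to suppress singleton noise; a
2-anchor run's orientation is the sign of its B-rank step.

Events are read off the bipartite chromosome graph whose edges are blocks
with ≥ `min_event_anchors` (default 5) anchors. One A chromosome joined to
exactly two otherwise-private B chromosomes (or the mirror image) is a
fusion/fission; a 2×2 complete component whose four blocks all sit in the
first or last decile of their chromosomes' anchor ranks (the *terminal*
test, configurable) is a reciprocal translocation; multiple blocks on a
single chromosome pair are an intra-chromosomal shift (inversions manifest
this way, as an orientation flip between flanking forward blocks).
Components matching no template are reported as `complex`, never dropped.
Classification refuses to run when blocks cover less than 90% of anchors,
since unexplained anchor mass makes the templates unreliable. Breakpoint
refinement at base-pair resolution is out of scope.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
raw sequencing: chromosomes are uniform-random A/C/G/T cores capped by
tandem telomere arrays (unit lengths uniform over {6, 7, 8}, 5′ array
reverse-complemented, ends optionally left uncapped); heterozygous sites
are Poisson per kb in the core with dosage *j* uniform on {1..k−1}; site
depth is negative binomial with mean `mean_depth × k` and size
`depth_dispersion` (default 20 — realistic short-read overdispersion;
Poisson is the large-size limit); alternate counts are binomial at
p = (j/k)(1−2e) + e. Per-base depth uses the same negative binomial, with
optional attenuation over telomere arrays (off by default) to exercise
window-exclusion logic. Haploid strains are modeled with `het_rate = 0`
plus a small homozygous-error site rate (default 0.02 /kb in the
batteries, matching the residual call densities such strains show), since
a one-copy chromosome cannot carry heterozygosity — the config rejects
het_rate > 0 for purely haploid genomes. Rearrangement simulation applies
fission, fusion, reciprocal-translocation, and inversion events
sequentially to one genome's gene order and emits anchors at 1 kb synthetic
spacing.

Determinism: every stage derives its generator from the config seed with a
fixed per-stage stream id, so a config reproduces byte-identical artifacts
regardless of stage order, and the truth skeleton built without sequences
matches the one built with them. Variant REF/ALT bases are drawn from the
generator's own stream rather than read from the simulated sequence; the
inference never consults the bases, and this keeps sequence-free pipelines
exact.

What the generator does **not** emulate — and what passing recovery tests
therefore do not establish about real data: mapping artifacts and
reference bias in repeat regions, GC-dependent coverage waves, segmental
duplications and collapsed repeats (which mimic depth shifts), subclonal or
mosaic aneuploidy, linked-allele structure along chromosomes, and gene-order
noise from annotation error. Real analyses should mask repeats before depth
normalization and treat `depth_only` aneuploidy calls as provisional.

## Battery sizes and numerical choices

The seeded recovery batteries use 50 genomes of 12 × 100 kb chromosomes
(ploidy), a 20 × 200 kb mostly-diploid scenario (200 kb so that even a
0.2 /kb het density yields an informative AF fit per chromosome), 20
replicates of 200 sites per candidate ploidy (AF selection), exhaustive
permutations to n = 8 plus 100 random n = 200 instances (chaining), 25
planted event lists on 12 × 50-gene chromosomes (rearrangements), and
20 × 10 kb genomes plus 100 random 10 kb sequences (telomeres). These
sizes are the package's own desk-scale choices: large enough that every
statistic is in its asymptotic regime (binomial/Poisson 4σ bounds,
≥ 30-site AF fits, ≥ 19 depth windows per chromosome), small enough to run
in seconds. Genome-wide coverage is held at ~100× (per-copy depth =
100 / baseline). Likelihoods are computed in log space via `gammaln` and
`logsumexp` with mixture probabilities clipped to [1e−12, 1−1e−12];
density rounding is decimal half-up, not banker's rounding.

## Known limitations

* Ploidy above 4 and mixture-weight estimation are out of scope; the
  equal-weight mixture can be mis-specified when dosages are strongly
  skewed.
* The modal-ratio baseline assumes at least half the chromosomes sit at
  the baseline copy number; a genome that is mostly aneuploid would anchor
  the normalization incorrectly.
* The fusion/fission template requires exactly two partner chromosomes;
  two fissions of the same ancestral chromosome produce a 3-leaf star
  reported as `complex`.
* The chaining is greedy; with `gap > 0` it is a heuristic, not an optimal
  chain, though with `gap = 0` (the default) it is exact.
* Frequency-only VCF records (no read counts, no DP) contribute to
  heterozygosity density but not to AF model fits.
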