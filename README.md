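# karyoscope

Chromosome-scale genome architecture analysis for small eukaryotic genomes:

* **ploidy and aneuploidy inference** from heterozygous-site allele-frequency
  spectra and normalized sequencing depth;
* **telomere-to-telomere (T2T) completeness** assessment by telomere-motif
  scanning of chromosome ends;
* **genome summary statistics** (GC, gene density, exon/intron structure) and
  windowed GC tracks;
* **orthogroup set partitioning** into shared and species-specific
  compartments (Venn regions) across strains;
* **collinear-block chaining** of ortholog anchors between genome pairs and
  classification of the structural events that separate them
  (fusion/fission, reciprocal translocation, intra-chromosomal shifts);
* a **ground-truthed synthetic-data generator** that emits genomes, variant
  calls, depth profiles, and anchor tables with known copy numbers,
  heterozygous sites, telomere status, and planted rearrangements, so every
  stage can be validated against planted truth.

The package is aimed at comparative genomics of compact, chromosome-level
assemblies — for example picoeukaryotic green algae, where strains of one
genus differ in ploidy state, carry individual trisomic chromosomes, and are
separated by a handful of chromosome fusions and reciprocal translocations.

## The model at the core

At a heterozygous site on a chromosome present in *k* copies, the alternate
allele occupies *j* ∈ {1, …, k−1} of the copies, so its read fraction
clusters at *j/k* (1/2 for disomic; 1/3 and 2/3 for trisomic). With
per-site read counts (a, n), each candidate *k* is scored by the
fixed-weight binomial mixture

```
L_k(a, n) = (1/(k−1)) Σ_{j=1..k−1}  Binom(a; n, p_j),   p_j = (j/k)(1−2e) + e
```

with sequencing-error rate *e* (default 0.01); *k* = 1 is the error-only
model mixing p = e and p = 1−e. The mixtures have no free parameters, so
BIC = −2 log L and model selection reduces to comparing mode positions.
Independently, windowed mean depth (10 kb window, 5 kb step) is divided by
the genome-wide median of window means; a chromosome's copy ratio is the
median of its normalized windows, so copy *k* at baseline *b* sits near
*k/b*. The genome call combines both lines of evidence, and an aneuploid
chromosome is "corroborated" when its own AF fit equals its depth-implied
copy number. Telomere arrays are maximal tandem runs of the unit family
`T{3,5}AGG` (hexamer TTTAGG to octamer TTTTTAGG), reverse-complemented at
the 5′ end. Collinear blocks are maximal monotone runs of anchor ranks
(gap = 0 by default), and rearrangements are read off the bipartite
chromosome graph the blocks induce.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

`examples/01_simulate_and_call_ploidy.py` simulates a 20-chromosome diploid
genome with one triploid chromosome and runs the full caller:

```
genome label     : mostly diploid
baseline ploidy  : 2
het density      : 0.21 sites/kb
aneuploid chroms : chr17
  chr17: copy ratio 1.50 -> copy number 3 (AF model k=3, evidence af+depth)
```

The label "mostly diploid" means all chromosomes sit at copy 2 except the
flagged one; `copy ratio 1.50` is chr17's median normalized depth, and
`evidence af+depth` says the 1/3–2/3 allele-frequency modes and the 1.5×
depth ratio independently agree on copy number 3. The other examples cover
telomere completeness (`02`), summary statistics (`03`), orthogroup
partitioning (`04`), and rearrangement recovery (`05`); each prints the
numbers it computes and a line on what they mean.

A thin CLI wraps the same library calls:

```bash
karyoscope simulate --seed 11 --out sim/
karyoscope ploidy --vcf sim/variants.vcf --depth sim/depth.tsv \
    --fasta sim/genome.fasta --out sim/ploidy
karyoscope telomeres --fasta sim/genome.fasta
```

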