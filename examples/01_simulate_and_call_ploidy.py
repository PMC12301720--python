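"""Simulate a mostly-diploid strain and call its ploidy.

Builds a 20-chromosome diploid genome carrying one triploid chromosome
(chr17), generates heterozygous variant sites and per-base depth, and runs
the full caller: allele-frequency mixture fits + normalized-depth ratios.
"""

from karyoscope.workflows import chloropicon_like_scenario

report, truth = chloropicon_like_scenario(seed=11)

print(f"genome label     : {report.ploidy_state_label}")
print(f"baseline ploidy  : {report.baseline_ploidy}")
print(f"het density      : {report.het_density:.2f} sites/kb")
print(f"aneuploid chroms : {', '.join(report.aneuploid_chroms)}")
for call in report.calls:
    if call.aneuploid:
        print(
            f"  {call.chrom_id}: copy ratio {call.copy_ratio:.2f} -> "
            f"copy number {call.copy_number} (AF model k={call.best_k_af}, "
            f"evidence {call.evidence})"
        )

# The label "mostly diploid" means every chromosome is at copy 2 except the
# flagged one; "af+depth" says the 1.5x depth ratio and the 1/3-2/3
# allele-frequency modes independently agree on copy number 3.
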