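"""Partition orthogroups into Venn regions across strains of two species.

Builds a toy five-strain orthogroup table, assigns each orthogroup to the
exact strain set possessing it, and computes species-specific gene
fractions.
"""

from karyoscope.io_formats import OrthoGroupTable
from karyoscope.orthosets import partition_orthogroups, species_specific_gene_fraction

species = {"r1": "ros", "r2": "ros", "p1": "pri", "p2": "pri"}
groups = {
    "OG1": {"r1": ("r1a",), "r2": ("r2a",), "p1": ("p1a",), "p2": ("p2a",)},
    "OG2": {"r1": ("r1b", "r1c"), "r2": ("r2b",)},      # ros-exclusive
    "OG3": {"p1": ("p1b",)},                            # pri-exclusive
    "OG4": {"r1": ("r1d",), "p1": ("p1c",)},
}
table = OrthoGroupTable(groups, species=species)

part = partition_orthogroups(table)
print(part.to_frame().to_string(index=False))
print(f"shared by all strains: {part.shared_all_count} ({part.shared_all_percent}%)")
for strain in table.strains:
    frac = species_specific_gene_fraction(table, strain)
    print(f"{strain}: {frac}% of its genes in species-exclusive orthogroups")

# Each region is the exact strain subset possessing the orthogroup, so the
# counts sum to the orthogroup total and the Venn diagram is a true partition.
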