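"""Orthogroup set partitioning across strains and species.

Every orthogroup is assigned to exactly one Venn region — the exact set of
strains (or species) possessing at least one member gene — so region counts
sum to the orthogroup total. A species-specific orthogroup is one whose
member strains all belong to a single species (it need not include every
strain of that species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io_formats import OrthoGroupTable
from .ploidy import round_half_up


@dataclass
class VennPartition:
    """Counts of orthogroups per region (non-empty subset of units)."""

    grouping: str  # by_strain | by_species
    regions: dict[frozenset, int]
    genes_per_strain: dict[frozenset, dict[str, int]]
    total_orthogroups: int
    units: tuple[str, ...] = ()

    @property
    def shared_all_count(self) -> int:
        return self.regions.get(frozenset(self.units), 0)

    @property
    def shared_all_percent(self) -> float:
        """Percent of orthogroups present in every unit, 1-decimal half-up."""
        return round_half_up(100.0 * self.shared_all_count / self.total_orthogroups, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(sorted(region)),
                "n_units": len(region),
                "orthogroups": count,
            }
            for region, count in sorted(
                self.regions.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


def partition_orthogroups(
    table: OrthoGroupTable, grouping: str = "by_strain"
) -> VennPartition:
    """Assign each orthogroup to its Venn region and count regions.

    ``grouping="by_species"`` projects strains through the table's species
    map first; by-species counts are then a coarsening of by-strain counts.
    """
    if len(table) == 0:
        raise ValidationError("partition_orthogroups: empty orthogroup table")
    if grouping not in ("by_strain", "by_species"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    if grouping == "by_species":
        units = tuple(sorted(set(table.species.values())))
    else:
        units = table.strains
    regions: dict[frozenset, int] = {}
    genes: dict[frozenset, dict[str, int]] = {}
    for og, per_strain in table.groups.items():
        members = set(per_strain)
        if grouping == "by_species":
            region = frozenset(table.species[s] for s in members)
        else:
            region = frozenset(members)
        regions[region] = regions.get(region, 0) + 1
        bucket = genes.setdefault(region, {})
        for s, gs in per_strain.items():
            bucket[s] = bucket.get(s, 0) + len(gs)
    total = sum(regions.values())
    assert total == len(table)  # regions partition the orthogroups
    return VennPartition(
        grouping=grouping,
        regions=regions,
        genes_per_strain=genes,
        total_orthogroups=total,
        units=units,
    )


def species_specific_orthogroups(table: OrthoGroupTable, species: str) -> list[str]:
    """Orthogroups whose member strains all belong to ``species``."""
    strains_of_species = {s for s, sp in table.species.items() if sp == species}
    if not strains_of_species:
        raise ValidationError(f"unknown species {species!r}")
    return [
        og for og in table.groups
        if table.strains_of(og) and table.strains_of(og) <= strains_of_species
    ]


def species_specific_gene_fraction(
    table: OrthoGroupTable,
    strain: str,
    total_genes: int | None = None,
) -> float:
    """Percent of a strain's genes lying in its species' exclusive orthogroups.

    ``total_genes`` is the strain's total predicted gene count (the published
    denominator, which includes genes absent from the orthogroup table);
    when omitted, the strain's gene count within the table is used.
    Result is rounded half-up to one decimal.
    """
    if strain not in table.species:
        raise ValidationError(f"unknown strain {strain!r}")
    species = table.species[strain]
    numerator = 0
    for og in species_specific_orthogroups(table, species):
        numerator += len(table.groups[og].get(strain, ()))
    denom = total_genes if total_genes is not None else table.gene_count(strain)
    if denom <= 0:
        raise ValidationError(f"strain {strain!r} has no genes to count against")
    return round_half_up(100.0 * numerator / denom, 1)
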