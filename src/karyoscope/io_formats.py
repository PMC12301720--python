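"""Readers and writers for every external file format the pipeline touches.

Dialects
--------
FASTA
    Standard multi-FASTA; sequences are uppercased on read and wrapped at 60
    columns on write. Ambiguity codes other than ``N`` are either rejected
    (default) or mapped to ``N``.
VCF
    VCF v4.x subset restricted to biallelic SNVs. Per-sample evidence is taken
    from an ``AD`` field holding ``ref,alt`` read counts, from the VarScan-style
    scalar pair ``RD``/``AD``, or — failing counts — from a VarScan ``FREQ``
    percent string combined with ``DP``. Counts are preferred when both exist.
Depth
    Three-column TSV ``chrom<TAB>pos<TAB>depth`` as emitted by
    ``samtools depth -aa``: one row per position, positions 1-based and
    contiguous within a chromosome.
Gene table
    TSV with header ``gene_id  chrom  start  end  strand  exons``; exons are
    ``start-end`` pairs joined by commas, 1-based closed coordinates.
Anchor table
    TSV with header ``orthogroup_id  strain_a  chrom_a  pos_a  strand_a
    gene_a  strain_b  chrom_b  pos_b  strand_b``; one ortholog pair per row,
    ``pos`` being the gene midpoint.
Orthogroup table
    OrthoFinder-style TSV: header ``Orthogroup`` followed by one column per
    strain; each cell is a comma-separated gene-id list (may be empty).

All coordinates are 1-based closed internally; BED exports are 0-based
half-open via :func:`to_bed_interval` / :func:`from_bed_interval`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeSeq:
    """One assembled chromosome of one strain."""

    strain_id: str
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"chromosome {self.chrom_id!r} contains invalid bases: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class VariantSite:
    """One biallelic SNV with per-allele read support.

    ``ref_count``/``alt_count`` may be ``None`` when the source VCF carried
    only a frequency field; ``alt_freq`` is always populated.
    """

    chrom_id: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_count: int | None
    alt_count: int | None
    alt_freq: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_count is not None and self.alt_count is not None:
            total = self.ref_count + self.alt_count
            if self.ref_count < 0 or self.alt_count < 0:
                raise ValidationError("read counts must be non-negative")
            self.alt_freq = self.alt_count / total if total else 0.0
        elif self.alt_freq is None:
            raise ValidationError("either read counts or alt_freq is required")

    @property
    def total_count(self) -> int | None:
        if self.ref_count is None or self.alt_count is None:
            return None
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class DepthRecord:
    chrom_id: str
    pos: int  # 1-based
    depth: int


@dataclass
class GeneRecord:
    """An annotated gene with its exon structure (1-based closed intervals)."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"gene {self.gene_id}: exon start > end")
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based closed."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass(frozen=True)
class AnchorRecord:
    """One ortholog gene pair between two genomes (a synteny anchor)."""

    orthogroup_id: str
    strain_a: str
    chrom_a: str
    pos_a: int
    strand_a: str
    gene_a: str
    strain_b: str
    chrom_b: str
    pos_b: int
    strand_b: str
    gene_b: str


class OrthoGroupTable:
    """Orthogroup membership across strains, with a strain → species map.

    Invariant: every gene id appears in exactly one orthogroup (and once).
    """

    def __init__(
        self,
        groups: Mapping[str, Mapping[str, Sequence[str]]],
        species: Mapping[str, str] | None = None,
    ) -> None:
        self.groups: dict[str, dict[str, tuple[str, ...]]] = {
            og: {s: tuple(genes) for s, genes in per_strain.items() if genes}
            for og, per_strain in groups.items()
        }
        self.strains: tuple[str, ...] = tuple(
            sorted({s for per in self.groups.values() for s in per})
        )
        self.species: dict[str, str] = dict(species or {s: s for s in self.strains})
        seen: dict[str, str] = {}
        for og, per_strain in self.groups.items():
            for strain, genes in per_strain.items():
                for g in genes:
                    if g in seen:
                        raise ValidationError(
                            f"gene {g!r} appears in orthogroups {seen[g]!r} and {og!r}"
                        )
                    seen[g] = og

    def __len__(self) -> int:
        return len(self.groups)

    def strains_of(self, og_id: str) -> frozenset[str]:
        return frozenset(self.groups[og_id])

    def gene_count(self, strain: str) -> int:
        """Number of genes of ``strain`` present anywhere in the table."""
        return sum(len(per.get(strain, ())) for per in self.groups.values())


# ---------------------------------------------------------------------------
# BED conversion
# ---------------------------------------------------------------------------

def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    strain_id: str | None = None,
    ambiguous: str = "reject",
) -> list[ChromosomeSeq]:
    """Read a multi-FASTA into :class:`ChromosomeSeq` records, order preserved.

    Parameters
    ----------
    ambiguous:
        ``"reject"`` (default) raises on IUPAC codes other than N;
        ``"mask"`` maps them to N.
    """
    path = Path(path)
    if strain_id is None:
        strain_id = path.stem
    records: list[ChromosomeSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            if ambiguous == "mask":
                seq = re.sub(f"[{''.join(re.escape(b) for b in bad)}]", "N", seq)
            else:
                raise FormatError(
                    f"{path}: record {rec.id!r} has ambiguous bases {sorted(bad)} "
                    "(pass ambiguous='mask' to map them to N)"
                )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate chromosome id {rec.id!r}")
        seen.add(rec.id)
        records.append(ChromosomeSeq(strain_id=strain_id, chrom_id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(chroms: Iterable[ChromosomeSeq], path: str | Path, width: int = 60) -> None:
    """Write chromosomes as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for c in chroms:
            fh.write(f">{c.chrom_id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_freq(value) -> float:
    if isinstance(value, (tuple, list)):
        value = value[0]
    if isinstance(value, bytes):
        value = value.decode()
    s = str(value).rstrip("%")
    return float(s) / 100.0


def read_vcf_sites(path: str | Path, sample: str | None = None) -> list[VariantSite]:
    """Parse biallelic SNVs from a VCF; indels/multiallelics are skipped.

    Per-sample evidence resolution order: tuple ``AD`` (ref,alt); VarScan
    ``RD`` + scalar ``AD``; ``FREQ`` percent (with ``DP`` to reconstruct
    counts when present). A record offering none of these raises
    :class:`FormatError`.
    """
    import pysam

    sites: list[VariantSite] = []
    n_indel = n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        if sample is None:
            sample = samples[0]
        elif sample not in samples:
            raise FormatError(f"{path}: sample {sample!r} not in VCF ({samples})")
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                n_indel += 1
                continue
            fmt = rec.samples[sample]
            ref_count = alt_count = None
            ad = fmt.get("AD") if "AD" in fmt else None
            if isinstance(ad, (tuple, list)) and len(ad) >= 2 and ad[0] is not None:
                ref_count, alt_count = int(ad[0]), int(ad[1])
            elif "RD" in fmt and ad is not None:
                rd = fmt["RD"]
                rd = rd[0] if isinstance(rd, (tuple, list)) else rd
                a = ad[0] if isinstance(ad, (tuple, list)) else ad
                if rd is not None and a is not None:
                    ref_count, alt_count = int(rd), int(a)
            if ref_count is None:
                if "FREQ" in fmt and fmt.get("FREQ") is not None:
                    freq = _parse_freq(fmt["FREQ"])
                    dp = fmt.get("DP") if "DP" in fmt else None
                    if dp:
                        dp = int(dp[0] if isinstance(dp, (tuple, list)) else dp)
                        alt_count = int(round(freq * dp))
                        ref_count = dp - alt_count
                        sites.append(
                            VariantSite(rec.chrom, rec.pos, ref, alt, ref_count, alt_count)
                        )
                    else:
                        sites.append(
                            VariantSite(rec.chrom, rec.pos, ref, alt, None, None, alt_freq=freq)
                        )
                    continue
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} has neither read counts "
                    "(AD / RD+AD) nor a FREQ field"
                )
            sites.append(VariantSite(rec.chrom, rec.pos, ref, alt, ref_count, alt_count))
    if n_indel or n_multi:
        logger.info(
            "read_vcf_sites(%s): skipped %d indel and %d multiallelic records",
            path, n_indel, n_multi,
        )
    return sites


def write_vcf_sites(
    sites: Sequence[VariantSite], path: str | Path, sample: str = "sample1"
) -> None:
    """Write sites as a minimal VCF v4.2 with GT:AD:DP sample fields."""
    chroms = list(dict.fromkeys(s.chrom_id for s in sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for s in sites:
            if s.ref_count is None:
                raise ValidationError(
                    f"cannot write site {s.chrom_id}:{s.pos} without read counts"
                )
            dp = s.ref_count + s.alt_count
            fh.write(
                f"{s.chrom_id}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD:DP\t0/1:{s.ref_count},{s.alt_count}:{dp}\n"
            )


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path) -> Iterator[DepthRecord]:
    """Stream a 3-column depth TSV; positions must strictly increase per chrom."""
    last: dict[str, int] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            chrom, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if chrom in last and pos <= last[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: non-monotone position {pos} on {chrom}"
                )
            last[chrom] = pos
            n += 1
            yield DepthRecord(chrom, pos, depth)
    if n == 0:
        logger.warning("read_depth_table(%s): file is empty", path)


def read_depth_arrays(path: str | Path) -> dict[str, np.ndarray]:
    """Load a ``samtools depth -aa``-style TSV into per-chromosome arrays.

    Requires positions 1..L contiguous within each chromosome (the ``-aa``
    dialect); index ``i`` of the returned array is position ``i + 1``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        logger.warning("read_depth_arrays(%s): file is empty", path)
        return {}
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not (pos[0] == 1 and np.all(np.diff(pos) == 1)):
            raise FormatError(
                f"{path}: positions on {chrom} are not contiguous from 1 "
                "(expected samtools depth -aa output)"
            )
        out[str(chrom)] = grp["depth"].to_numpy()
    return out


def write_depth_table(depths: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-chromosome depth arrays as a 3-column TSV (positions 1..L)."""
    with open(path, "w") as fh:
        for chrom, arr in depths.items():
            pos = np.arange(1, len(arr) + 1)
            pd.DataFrame({"c": chrom, "p": pos, "d": np.asarray(arr, dtype=np.int64)}).to_csv(
                fh, sep="\t", header=False, index=False
            )


# ---------------------------------------------------------------------------
# gene / anchor / orthogroup tables
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand", "exons"]


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(","):
        m = re.fullmatch(r"(\d+)-(\d+)", part)
        if not m:
            raise FormatError(f"malformed exon interval {part!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return tuple(out)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene id {row.gene_id!r}")
        seen.add(row.gene_id)
        exons = _parse_exons(row.exons)
        if not exons:
            exons = ((int(row.start), int(row.end)),)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id, chrom_id=row.chrom,
                start=int(row.start), end=int(row.end),
                strand=row.strand, exons=exons,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom_id, "start": g.start,
            "end": g.end, "strand": g.strand,
            "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


_ANCHOR_COLS = [
    "orthogroup_id",
    "strain_a", "chrom_a", "pos_a", "strand_a", "gene_a",
    "strain_b", "chrom_b", "pos_b", "strand_b", "gene_b",
]


def read_anchor_table(path: str | Path) -> list[AnchorRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANCHOR_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    anchors = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.gene_a, row.gene_b)
        if key in seen:
            raise ValidationError(f"{path}: duplicate anchor for pair {key}")
        seen.add(key)
        anchors.append(
            AnchorRecord(
                orthogroup_id=row.orthogroup_id,
                strain_a=row.strain_a, chrom_a=row.chrom_a,
                pos_a=int(row.pos_a), strand_a=row.strand_a, gene_a=row.gene_a,
                strain_b=row.strain_b, chrom_b=row.chrom_b,
                pos_b=int(row.pos_b), strand_b=row.strand_b, gene_b=row.gene_b,
            )
        )
    return anchors


def write_anchor_table(anchors: Iterable[AnchorRecord], path: str | Path) -> None:
    rows = [
        {
            "orthogroup_id": a.orthogroup_id,
            "strain_a": a.strain_a, "chrom_a": a.chrom_a, "pos_a": a.pos_a,
            "strand_a": a.strand_a, "gene_a": a.gene_a,
            "strain_b": a.strain_b, "chrom_b": a.chrom_b, "pos_b": a.pos_b,
            "strand_b": a.strand_b, "gene_b": a.gene_b,
        }
        for a in anchors
    ]
    pd.DataFrame(rows, columns=_ANCHOR_COLS).to_csv(path, sep="\t", index=False)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``strain<TAB>species`` (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or (lineno == 1 and line.lower().startswith("strain")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_orthogroup_table(
    path: str | Path, species: Mapping[str, str] | None = None
) -> OrthoGroupTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.columns[0].lower() not in {"orthogroup", "orthogroup_id"}:
        raise FormatError(
            f"{path}: first column must be 'Orthogroup', got {df.columns[0]!r}"
        )
    strains = list(df.columns[1:])
    if not strains:
        raise FormatError(f"{path}: no strain columns")
    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    for row in df.itertuples(index=False):
        og = row[0]
        if og in groups:
            raise ValidationError(f"{path}: duplicate orthogroup id {og!r}")
        per: dict[str, tuple[str, ...]] = {}
        for strain, cell in zip(strains, row[1:]):
            genes = tuple(g.strip() for g in cell.split(",") if g.strip())
            if genes:
                per[strain] = genes
        groups[og] = per
    return OrthoGroupTable(groups, species=species)


def write_orthogroup_table(table: OrthoGroupTable, path: str | Path) -> None:
    strains = table.strains
    rows = []
    for og, per in table.groups.items():
        row = {"Orthogroup": og}
        for s in strains:
            row[s] = ", ".join(per.get(s, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *strains]).to_csv(path, sep="\t", index=False)
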