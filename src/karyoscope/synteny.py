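"""Collinear-block chaining of ortholog anchors and rearrangement templates.

Anchors (ortholog gene pairs) are ranked by coordinate on each chromosome of
each genome, then chained greedily left-to-right over the A-side rank: a
block extends while the next anchor is within ``gap`` skipped anchors on
both sides and its B-side rank continues the block's monotone direction.
With ``gap = 0`` this reduces to maximal runs of rank-adjacent anchors whose
B ranks step by exactly +-1 — the strictest chaining, matching the study
setting for collinearity detection.

Rearrangements between two genomes are read off the bipartite chromosome
graph whose edges are well-supported blocks:

* an A chromosome joined to exactly two private B chromosomes (or vice
  versa) is a fusion/fission;
* a 4-cycle of two A and two B chromosomes whose blocks sit at terminal
  rank ranges is a reciprocal translocation;
* several blocks on the same single chromosome pair (offset or orientation
  changes) are an intra-chromosomal shift;
* anything else is reported as "complex", never silently dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import AnchorRecord, to_bed_interval

logger = logging.getLogger(__name__)

DEFAULT_GAP = 0
DEFAULT_MIN_ANCHORS = 3
DEFAULT_MIN_EVENT_ANCHORS = 5
DEFAULT_MIN_COVERAGE = 0.9
DEFAULT_TERMINAL_DECILE = 0.1

FUSION_FISSION = "fusion_fission"
RECIPROCAL_TRANSLOCATION = "reciprocal_translocation"
INTRA_SHIFT = "intra_shift"
COMPLEX = "complex"


@dataclass(frozen=True)
class IndexedAnchor:
    """An anchor with dense 0-based gene-order ranks on both sides."""

    anchor: AnchorRecord
    rank_a: int
    rank_b: int

    @property
    def chrom_a(self) -> str:
        return self.anchor.chrom_a

    @property
    def chrom_b(self) -> str:
        return self.anchor.chrom_b


@dataclass
class CollinearBlock:
    """A maximal run of order-conserved anchors between two chromosomes."""

    chrom_a: str
    chrom_b: str
    orientation: str  # forward | reverse
    anchors: list[IndexedAnchor]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def rank_range_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def rank_range_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_a(self) -> tuple[int, int]:
        pos = [a.anchor.pos_a for a in self.anchors]
        return min(pos), max(pos)

    @property
    def span_b(self) -> tuple[int, int]:
        pos = [a.anchor.pos_b for a in self.anchors]
        return min(pos), max(pos)


@dataclass
class RearrangementEvent:
    """One inferred inter-genome structural event."""

    type: str
    chroms_a: tuple[str, ...]
    chroms_b: tuple[str, ...]
    blocks: list[CollinearBlock] = field(default_factory=list)


# ---------------------------------------------------------------------------
# indexing
# ---------------------------------------------------------------------------

def index_anchors(anchors: Sequence[AnchorRecord]) -> list[IndexedAnchor]:
    """Assign per-chromosome gene-order ranks by midpoint coordinate.

    A gene appearing in several anchors (paralog ambiguity) keeps only the
    anchor minimizing the coordinate offset between its two sides — a proxy
    for the reciprocally nearest pairing — and the rest are dropped with a
    log message. Ranks are dense and unique per chromosome, and invariant
    under permutation of the input order.
    """
    by_gene_a: dict[str, list[AnchorRecord]] = defaultdict(list)
    for a in anchors:
        by_gene_a[a.gene_a].append(a)
    kept: list[AnchorRecord] = []
    n_dropped = 0
    chosen_b: set[str] = set()
    for gene_a in sorted(by_gene_a):
        group = by_gene_a[gene_a]
        group = sorted(group, key=lambda a: (abs(a.pos_a - a.pos_b), a.gene_b))
        picked = None
        for cand in group:
            if cand.gene_b not in chosen_b:
                picked = cand
                break
        if picked is None:
            n_dropped += len(group)
            continue
        chosen_b.add(picked.gene_b)
        kept.append(picked)
        n_dropped += len(group) - 1
    if n_dropped:
        logger.info("index_anchors: dropped %d ambiguous anchors", n_dropped)

    rank_a: dict[str, int] = {}
    for chrom in sorted({a.chrom_a for a in kept}):
        group = sorted(
            (a for a in kept if a.chrom_a == chrom), key=lambda a: (a.pos_a, a.gene_a)
        )
        for r, a in enumerate(group):
            rank_a[a.gene_a] = r
    rank_b: dict[str, int] = {}
    for chrom in sorted({a.chrom_b for a in kept}):
        group = sorted(
            (a for a in kept if a.chrom_b == chrom), key=lambda a: (a.pos_b, a.gene_b)
        )
        for r, a in enumerate(group):
            rank_b[a.gene_b] = r
    out = [
        IndexedAnchor(anchor=a, rank_a=rank_a[a.gene_a], rank_b=rank_b[a.gene_b])
        for a in kept
    ]
    out.sort(key=lambda ia: (ia.chrom_a, ia.rank_a))
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_collinear(
    indexed: Sequence[IndexedAnchor],
    gap: int = DEFAULT_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> list[CollinearBlock]:
    """Greedy monotone chaining within each chromosome pair.

    Within each (chrom_a, chrom_b) pair, anchors sorted by ``rank_a`` are
    extended while at most ``gap`` anchors are skipped on either side and
    the B rank keeps the block's direction (set by the second anchor).
    Maximal runs with at least ``min_anchors`` anchors are emitted; each
    anchor belongs to at most one block.
    """
    pairs: dict[tuple[str, str], list[IndexedAnchor]] = defaultdict(list)
    for ia in indexed:
        pairs[(ia.chrom_a, ia.chrom_b)].append(ia)
    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(pairs.items()):
        group.sort(key=lambda ia: ia.rank_a)
        run: list[IndexedAnchor] = []
        direction = 0
        for ia in group:
            if not run:
                run = [ia]
                direction = 0
                continue
            prev = run[-1]
            da = ia.rank_a - prev.rank_a - 1
            db = ia.rank_b - prev.rank_b
            ok = 0 <= da <= gap and db != 0
            if ok:
                if direction == 0:
                    ok = abs(db) - 1 <= gap
                    new_dir = 1 if db > 0 else -1
                else:
                    ok = (db > 0) == (direction > 0) and abs(db) - 1 <= gap
                    new_dir = direction
            if ok:
                run.append(ia)
                direction = new_dir
            else:
                _emit(blocks, ca, cb, run, direction, min_anchors)
                run = [ia]
                direction = 0
        _emit(blocks, ca, cb, run, direction, min_anchors)
    return blocks


def _emit(
    blocks: list[CollinearBlock],
    ca: str,
    cb: str,
    run: list[IndexedAnchor],
    direction: int,
    min_anchors: int,
) -> None:
    if len(run) >= min_anchors:
        orientation = "reverse" if direction < 0 else "forward"
        blocks.append(CollinearBlock(ca, cb, orientation, list(run)))


# ---------------------------------------------------------------------------
# rearrangement classification
# ---------------------------------------------------------------------------

def _components(edges: set[tuple[str, str]]) -> list[tuple[set[str], set[str]]]:
    """Connected components of the bipartite chromosome graph."""
    adj_a: dict[str, set[str]] = defaultdict(set)
    adj_b: dict[str, set[str]] = defaultdict(set)
    for a, b in edges:
        adj_a[a].add(b)
        adj_b[b].add(a)
    seen_a: set[str] = set()
    comps = []
    for start in sorted(adj_a):
        if start in seen_a:
            continue
        ca: set[str] = set()
        cb: set[str] = set()
        stack = [("a", start)]
        while stack:
            side, node = stack.pop()
            if side == "a":
                if node in ca:
                    continue
                ca.add(node)
                stack.extend(("b", nb) for nb in adj_a[node])
            else:
                if node in cb:
                    continue
                cb.add(node)
                stack.extend(("a", na) for na in adj_b[node])
        seen_a |= ca
        comps.append((ca, cb))
    return comps


def _is_terminal(
    block: CollinearBlock, n_ranks: dict[str, int], decile: float, side: str
) -> bool:
    """Block rank range touches the first or last decile of its chromosome."""
    if side == "a":
        lo, hi = block.rank_range_a
        total = n_ranks[block.chrom_a]
    else:
        lo, hi = block.rank_range_b
        total = n_ranks[block.chrom_b]
    edge = max(1, int(decile * total))
    return lo < edge or hi >= total - edge


def classify_rearrangements(
    blocks: Sequence[CollinearBlock],
    indexed: Sequence[IndexedAnchor],
    min_event_anchors: int = DEFAULT_MIN_EVENT_ANCHORS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    terminal_decile: float = DEFAULT_TERMINAL_DECILE,
) -> list[RearrangementEvent]:
    """Classify inter-genome events from the block-level chromosome graph.

    Refuses (raises :class:`ValidationError`) when the blocks cover fewer
    than ``min_coverage`` of the anchors, since an unexplained anchor mass
    makes the graph templates unreliable. Components matching no template
    are reported with type "complex".
    """
    n_total = len(indexed)
    n_in_blocks = sum(b.n_anchors for b in blocks)
    if n_total and n_in_blocks / n_total < min_coverage:
        raise ValidationError(
            f"blocks cover {n_in_blocks}/{n_total} anchors "
            f"({n_in_blocks / n_total:.1%}) < required {min_coverage:.0%}; "
            "rearrangement classification refused"
        )
    n_ranks_a: dict[str, int] = defaultdict(int)
    n_ranks_b: dict[str, int] = defaultdict(int)
    for ia in indexed:
        n_ranks_a[ia.chrom_a] = max(n_ranks_a[ia.chrom_a], ia.rank_a + 1)
        n_ranks_b[ia.chrom_b] = max(n_ranks_b[ia.chrom_b], ia.rank_b + 1)

    strong = [b for b in blocks if b.n_anchors >= min_event_anchors]
    by_pair: dict[tuple[str, str], list[CollinearBlock]] = defaultdict(list)
    for b in strong:
        by_pair[(b.chrom_a, b.chrom_b)].append(b)
    edges = set(by_pair)

    events: list[RearrangementEvent] = []
    for ca, cb in _components(edges):
        comp_pairs = [(x, y) for (x, y) in edges if x in ca and y in cb]
        comp_blocks = [b for p in comp_pairs for b in by_pair[p]]
        if len(ca) == 1 and len(cb) == 1:
            if len(comp_blocks) >= 2:
                events.append(
                    RearrangementEvent(
                        INTRA_SHIFT, tuple(sorted(ca)), tuple(sorted(cb)), comp_blocks
                    )
                )
            continue  # single full-length correspondence: no event
        if (len(ca), len(cb)) in ((1, 2), (2, 1)) and len(comp_pairs) == 2:
            events.append(
                RearrangementEvent(
                    FUSION_FISSION, tuple(sorted(ca)), tuple(sorted(cb)), comp_blocks
                )
            )
            continue
        if len(ca) == 2 and len(cb) == 2 and len(comp_pairs) == 4:
            terminal = all(
                _is_terminal(b, n_ranks_a, terminal_decile, "a")
                and _is_terminal(b, n_ranks_b, terminal_decile, "b")
                for b in comp_blocks
            )
            if terminal:
                events.append(
                    RearrangementEvent(
                        RECIPROCAL_TRANSLOCATION,
                        tuple(sorted(ca)), tuple(sorted(cb)), comp_blocks,
                    )
                )
                continue
        events.append(
            RearrangementEvent(COMPLEX, tuple(sorted(ca)), tuple(sorted(cb)), comp_blocks)
        )
    return events


# ---------------------------------------------------------------------------
# coordinate exports
# ---------------------------------------------------------------------------

def dotplot_table(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """One line segment per block in both rank and bp coordinates.

    Reverse blocks emit negative-slope segments (B coordinates swapped).
    """
    rows = []
    for b in blocks:
        a0, a1 = b.rank_range_a
        b0, b1 = b.rank_range_b
        pa0, pa1 = b.span_a
        pb0, pb1 = b.span_b
        if b.orientation == "reverse":
            b0, b1 = b1, b0
            pb0, pb1 = pb1, pb0
        rows.append(
            {
                "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                "orientation": b.orientation, "n_anchors": b.n_anchors,
                "rank_a_start": a0, "rank_a_end": a1,
                "rank_b_start": b0, "rank_b_end": b1,
                "bp_a_start": pa0, "bp_a_end": pa1,
                "bp_b_start": pb0, "bp_b_end": pb1,
            }
        )
    return pd.DataFrame(rows)


def ribbon_table(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Block spans in bp on both genomes, for circular-plot ribbons."""
    rows = []
    for b in blocks:
        sa, ea = b.span_a
        sb, eb = b.span_b
        rows.append(
            {
                "chrom_a": b.chrom_a, "start_a": sa, "end_a": ea,
                "chrom_b": b.chrom_b, "start_b": sb, "end_b": eb,
                "orientation": b.orientation, "n_anchors": b.n_anchors,
            }
        )
    return pd.DataFrame(rows)


def blocks_to_bed(blocks: Sequence[CollinearBlock], side: str = "a") -> pd.DataFrame:
    """BED6 rows (0-based half-open) of block spans on one genome side."""
    rows = []
    for i, b in enumerate(blocks):
        chrom = b.chrom_a if side == "a" else b.chrom_b
        span = b.span_a if side == "a" else b.span_b
        start0, end = to_bed_interval(*span)
        rows.append(
            {
                "chrom": chrom, "start": start0, "end": end,
                "name": f"block{i + 1}", "score": b.n_anchors,
                "strand": "+" if b.orientation == "forward" else "-",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
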