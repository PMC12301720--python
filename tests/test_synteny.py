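"""Anchor indexing, collinear-block chaining, and rearrangement templates."""

from collections import Counter
from itertools import permutations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoscope import simulate as sim
from karyoscope import synteny as sy
from karyoscope.errors import ValidationError
from karyoscope.io_formats import AnchorRecord
from karyoscope.workflows import brute_force_monotone_runs


def _anchor(i, pos_a, pos_b, chrom_a="cA", chrom_b="cB", strand_b="+"):
    return AnchorRecord(
        f"OG{i}", "A", chrom_a, pos_a, "+", f"ga{i}", "B", chrom_b, pos_b,
        strand_b, f"gb{i}",
    )


def _from_permutation(perm):
    """Anchors whose B ranks follow ``perm`` along the A chromosome."""
    return [_anchor(i, (i + 1) * 100, (b + 1) * 100) for i, b in enumerate(perm)]


# ------------------------------------------------------------------ indexing

def test_ranks_follow_coordinates():
    anchors = [_anchor(0, 100, 300), _anchor(1, 50, 100), _anchor(2, 200, 200)]
    idx = sy.index_anchors(anchors)
    by_gene = {ia.anchor.gene_a: ia for ia in idx}
    assert [by_gene[f"ga{i}"].rank_a for i in range(3)] == [1, 0, 2]
    assert [by_gene[f"ga{i}"].rank_b for i in range(3)] == [2, 0, 1]


def test_duplicate_gene_keeps_one():
    dup = [
        _anchor(0, 100, 100),
        AnchorRecord("OGx", "A", "cA", 100, "+", "ga0", "B", "cB", 900, "+", "gbx"),
        _anchor(1, 200, 200),
    ]
    idx = sy.index_anchors(dup)
    assert len(idx) == 2
    genes = {ia.anchor.gene_a for ia in idx}
    assert genes == {"ga0", "ga1"}


def test_indexing_permutation_invariant(rng):
    anchors = _from_permutation(list(rng.permutation(20)))
    ref = {(ia.anchor.gene_a, ia.rank_a, ia.rank_b) for ia in sy.index_anchors(anchors)}
    shuffled = list(anchors)
    rng.shuffle(shuffled)
    assert {(ia.anchor.gene_a, ia.rank_a, ia.rank_b)
            for ia in sy.index_anchors(shuffled)} == ref


# ------------------------------------------------------------------ chaining

def test_forward_and_reverse_blocks():
    fwd = sy.chain_collinear(sy.index_anchors(_from_permutation([0, 1, 2, 3])))
    assert len(fwd) == 1 and fwd[0].orientation == "forward" and fwd[0].n_anchors == 4
    rev = sy.chain_collinear(sy.index_anchors(_from_permutation([3, 2, 1, 0])))
    assert len(rev) == 1 and rev[0].orientation == "reverse"


def _blocks_as_runs(blocks):
    return sorted(
        (min(a.rank_a for a in b.anchors), max(a.rank_a for a in b.anchors),
         b.orientation)
        for b in blocks
    )


def _check_against_oracle(perm):
    idx = sy.index_anchors(_from_permutation(perm))
    blocks = sy.chain_collinear(idx, gap=0, min_anchors=2)
    assert _blocks_as_runs(blocks) == sorted(brute_force_monotone_runs(list(perm), 2))


def test_chaining_equals_oracle_exhaustive_small():
    for n in range(1, 7):
        for perm in permutations(range(n)):
            _check_against_oracle(perm)


@given(perm=st.permutations(list(range(12))))
def test_chaining_equals_oracle_property(perm):
    _check_against_oracle(perm)


def test_anchors_in_at_most_one_block(rng):
    perm = list(rng.permutation(200))
    blocks = sy.chain_collinear(
        sy.index_anchors(_from_permutation(perm)), gap=0, min_anchors=2
    )
    seen = set()
    for b in blocks:
        for a in b.anchors:
            assert a.anchor.gene_a not in seen
            seen.add(a.anchor.gene_a)


def test_gap_allows_skips():
    # rank_b sequence 0,1,5,2 -> with gap 0 the run breaks at 5; the
    # singleton 5 cannot seed a block of 2
    perm = [0, 1, 5, 2, 3, 4]
    blocks0 = sy.chain_collinear(
        sy.index_anchors(_from_permutation(perm)), gap=0, min_anchors=2
    )
    assert max(b.n_anchors for b in blocks0) == 3  # 2,3,4 run
    blocks1 = sy.chain_collinear(
        sy.index_anchors(_from_permutation(perm)), gap=1, min_anchors=2
    )
    assert max(b.n_anchors for b in blocks1) >= 3


# ---------------------------------------------------------------- templates

def _pipeline(n_genes, events, seed=0):
    anchors, truth = sim.simulate_rearrangements(n_genes, events, seed=seed)
    idx = sy.index_anchors(anchors)
    blocks = sy.chain_collinear(idx)
    return sy.classify_rearrangements(blocks, idx), truth, blocks


def test_identity_no_events():
    events, _, blocks = _pipeline([40] * 5, [])
    assert events == []
    # self-consistency: one forward block per chromosome covering all anchors
    assert len(blocks) == 5
    assert all(b.orientation == "forward" and b.n_anchors == 40 for b in blocks)


def test_single_fission_detected():
    events, truth, _ = _pipeline([40] * 3, [sim.fission("chrB02", 17)])
    assert [e.type for e in events] == ["fusion_fission"]
    assert events[0].chroms_a == ("chrA02",)


def test_fusion_maps_two_a_chroms_to_one_b():
    events, _, blocks = _pipeline([40] * 3, [sim.fusion("chrB01", "chrB02")])
    assert [e.type for e in events] == ["fusion_fission"]
    fused_pairs = {(b.chrom_a, b.chrom_b) for b in blocks}
    assert ("chrA01", "chrB04") in fused_pairs and ("chrA02", "chrB04") in fused_pairs


def test_reciprocal_translocation_detected():
    events, _, _ = _pipeline(
        [50] * 4, [sim.reciprocal_translocation("chrB01", 20, "chrB03", 30)]
    )
    assert [e.type for e in events] == ["reciprocal_translocation"]
    assert events[0].chroms_a == ("chrA01", "chrA03")


def test_inversion_reported_as_intra_shift():
    events, _, blocks = _pipeline([60], [sim.inversion("chrB01", 20, 40)])
    assert [e.type for e in events] == ["intra_shift"]
    assert Counter(b.orientation for b in blocks) == {"forward": 2, "reverse": 1}


def test_low_coverage_refused():
    anchors, _ = sim.simulate_rearrangements([30], [], seed=0)
    idx = sy.index_anchors(anchors)
    with pytest.raises(ValidationError, match="refused"):
        sy.classify_rearrangements([], idx)


def test_multi_event_multiset_recovered():
    """Three fission/fusion plus two reciprocal translocations recovered."""
    planted = [
        sim.fission("chrB01", 25), sim.fission("chrB02", 20),
        sim.fission("chrB03", 30),
        sim.reciprocal_translocation("chrB04", 20, "chrB05", 25),
        sim.reciprocal_translocation("chrB06", 15, "chrB07", 30),
    ]
    events, truth, _ = _pipeline([50] * 8, planted, seed=4)
    assert Counter(e.type for e in events) == Counter(
        e.detected_type for e in truth.events
    )


# ------------------------------------------------------------------- exports

def test_dotplot_segments():
    fwd = sy.chain_collinear(sy.index_anchors(_from_permutation([0, 1, 2, 3])))
    df = sy.dotplot_table(fwd)
    assert (df.loc[0, "rank_a_start"], df.loc[0, "rank_b_start"]) == (0, 0)
    assert (df.loc[0, "rank_a_end"], df.loc[0, "rank_b_end"]) == (3, 3)
    rev = sy.chain_collinear(sy.index_anchors(_from_permutation([3, 2, 1, 0])))
    dr = sy.dotplot_table(rev)
    # negative slope: B coordinates swapped
    assert (dr.loc[0, "rank_b_start"], dr.loc[0, "rank_b_end"]) == (3, 0)


def test_ribbon_round_trip(tmp_path):
    anchors, _ = sim.simulate_rearrangements([20] * 2, [sim.fission("chrB01", 8)])
    idx = sy.index_anchors(anchors)
    blocks = sy.chain_collinear(idx)
    df = sy.ribbon_table(blocks)
    p = tmp_path / "ribbons.tsv"
    df.to_csv(p, sep="\t", index=False)
    back = pd.read_csv(p, sep="\t")
    spans = {(b.chrom_a, *b.span_a, b.chrom_b, *b.span_b) for b in blocks}
    assert {
        (r.chrom_a, r.start_a, r.end_a, r.chrom_b, r.start_b, r.end_b)
        for r in back.itertuples()
    } == spans


def test_bed_export_half_open():
    blocks = sy.chain_collinear(sy.index_anchors(_from_permutation([0, 1, 2])))
    bed = sy.blocks_to_bed(blocks)
    assert (bed.loc[0, "start"], bed.loc[0, "end"]) == (99, 300)
    assert bed.loc[0, "strand"] == "+"
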