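"""Chain collinear blocks between two genomes and classify rearrangements.

Plants three fission/fusion events and two reciprocal translocations in one
genome of a pair, then recovers them from the ortholog anchor table alone.
"""

from collections import Counter

from karyoscope.simulate import fission, reciprocal_translocation, simulate_rearrangements
from karyoscope.synteny import chain_collinear, classify_rearrangements, index_anchors

events = [
    fission("chrB01", 25), fission("chrB02", 20), fission("chrB03", 30),
    reciprocal_translocation("chrB04", 20, "chrB05", 25),
    reciprocal_translocation("chrB06", 15, "chrB07", 30),
]
anchors, truth = simulate_rearrangements([50] * 12, events, seed=1)

indexed = index_anchors(anchors)
blocks = chain_collinear(indexed, gap=0, min_anchors=3)
detected = classify_rearrangements(blocks, indexed)

print(f"anchors           : {len(anchors)}")
print(f"collinear blocks  : {len(blocks)}")
print(f"planted events    : {Counter(e.detected_type for e in truth.events)}")
print(f"detected events   : {Counter(e.type for e in detected)}")
for e in detected:
    print(f"  {e.type}: {'+'.join(e.chroms_a)} | {'+'.join(e.chroms_b)}")

# A fusion/fission joins one chromosome of genome A to two of genome B in
# the block graph; a reciprocal translocation forms a 4-cycle with blocks at
# chromosome ends. Matching multisets mean every planted event was recovered.
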