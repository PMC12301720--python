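"""Telomere-array detection and telomere-to-telomere (T2T) completeness.

Chromosome ends are scanned for tandem runs of the plant-type telomere unit
family T{3,5}AGG — hexamer TTTAGG through octamer TTTTTAGG — in its forward
orientation at the 3' end and reverse-complement orientation (CCTA{3,5}) at
the 5' end. An end is "capped" when the terminal search window contains a
tandem run of at least ``min_copies`` units; a chromosome is T2T when both
ends are capped.

Runs may mix unit lengths (the unit spectrum reports counts per length).
Interstitial telomere-like repeats outside the terminal windows are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import ChromosomeSeq, revcomp

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

#: default unit grammar: 3 to 5 thymines followed by AGG
DEFAULT_UNIT = r"T{3,5}AGG"
DEFAULT_WINDOW = 500
DEFAULT_MIN_COPIES = 3


@dataclass
class EndStatus:
    """Motif evidence for one chromosome end."""

    chrom_id: str
    end: str  # five_prime | three_prime
    capped: bool
    n_units: int
    unit_spectrum: dict[int, int] = field(default_factory=dict)
    array_span: tuple[int, int] | None = None  # 1-based closed, original coords


@dataclass
class TelomereReport:
    """Genome-wide telomere completeness summary."""

    ends: list[EndStatus]
    t2t: dict[str, bool]

    @property
    def genome_t2t_fraction(self) -> float:
        if not self.t2t:
            return 0.0
        return sum(self.t2t.values()) / len(self.t2t)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.ends:
            rows.append(
                {
                    "chrom": e.chrom_id,
                    "end": e.end,
                    "capped": e.capped,
                    "n_units": e.n_units,
                    "unit_spectrum": ";".join(
                        f"{k}:{v}" for k, v in sorted(e.unit_spectrum.items())
                    ),
                    "array_start": e.array_span[0] if e.array_span else "",
                    "array_end": e.array_span[1] if e.array_span else "",
                    "t2t": self.t2t[e.chrom_id],
                }
            )
        return pd.DataFrame(rows)


def _best_run(window_seq: str, unit: str) -> tuple[int, list[int], tuple[int, int]] | None:
    """Longest tandem run of ``unit`` in ``window_seq`` (forward orientation).

    Returns (n_units, unit lengths in order, 0-based half-open span) or None.
    """
    best = None
    for m in re.finditer(f"(?:{unit})+", window_seq):
        units = re.findall(unit, m.group(0))
        if best is None or len(units) > best[0]:
            best = (len(units), [len(u) for u in units], (m.start(), m.end()))
    return best


def scan_end(
    seq: str,
    end: str,
    chrom_id: str = "",
    search_window: int = DEFAULT_WINDOW,
    min_copies: int = DEFAULT_MIN_COPIES,
    unit: str = DEFAULT_UNIT,
) -> EndStatus:
    """Scan one chromosome end for a tandem telomere-unit run.

    The 5' end is scanned by reverse-complementing its terminal window so a
    single forward unit grammar serves both ends; reported coordinates are
    mapped back to the original sequence (1-based closed).
    """
    if not seq:
        raise ValidationError("scan_end: empty sequence")
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValidationError(f"scan_end: unknown end label {end!r}")
    w = min(search_window, len(seq))
    if end == THREE_PRIME:
        window_seq = seq[len(seq) - w :].upper()
        offset = len(seq) - w  # 0-based index of window start
        run = _best_run(window_seq, unit)
        if run:
            n, lengths, (s, e) = run
            span = (offset + s + 1, offset + e)
    else:
        window_seq = revcomp(seq[:w].upper())
        run = _best_run(window_seq, unit)
        if run:
            n, lengths, (s, e) = run
            # map reverse-complement coords back: rc index i -> original w-1-i
            span = (w - e + 1, w - s)
    if not run:
        return EndStatus(chrom_id, end, capped=False, n_units=0)
    n, lengths, _ = run
    capped = n >= min_copies
    spectrum: dict[int, int] = {}
    for ln in lengths:
        spectrum[ln] = spectrum.get(ln, 0) + 1
    return EndStatus(
        chrom_id, end,
        capped=capped,
        n_units=n,
        unit_spectrum=spectrum,
        array_span=span if capped else None,
    )


def t2t_report(
    genome: Sequence[ChromosomeSeq],
    search_window: int = DEFAULT_WINDOW,
    min_copies: int = DEFAULT_MIN_COPIES,
    unit: str = DEFAULT_UNIT,
) -> TelomereReport:
    """Scan both ends of every chromosome and aggregate T2T completeness."""
    if not genome:
        raise ValidationError("t2t_report: empty genome")
    ends: list[EndStatus] = []
    t2t: dict[str, bool] = {}
    for chrom in genome:
        e5 = scan_end(chrom.sequence, FIVE_PRIME, chrom.chrom_id, search_window, min_copies, unit)
        e3 = scan_end(chrom.sequence, THREE_PRIME, chrom.chrom_id, search_window, min_copies, unit)
        ends.extend([e5, e3])
        t2t[chrom.chrom_id] = e5.capped and e3.capped
    return TelomereReport(ends=ends, t2t=t2t)
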