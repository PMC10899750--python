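"""Cleavage-product localization and mode/site classification.

Each cleaved product (CP) is located within its barcode-assigned
substrate by local alignment, yielding coordinates (x, y): x is the
alignment start minus one (the last retained 5'-side position; the cut
falls between x and x+1) and y the alignment end, both 1-based.

Classification rules (C = 72 by default):

* DC at x        if 19 <= x <= 23 and y == C - x
* Other at x     if 19 <= x <= 23 and 49 <= y <= 53 and y != C - x
* 5'-SC at x     if 19 <= x <= 23 and 68 <= y <= 72
* 3'-SC at C - y if 0 <= x <= 4 and 49 <= y <= 53
* unclassified otherwise, precedence DC > Other > 3'-SC > 5'-SC.

The published "Other" y-range (68..72) duplicates the 5'-SC range and
leaves its y != C - x clause vacuous; the default here uses 49..53, the
only range where y == C - x is attainable.  ``rules_as_printed=True``
applies the published ranges verbatim (first-match order DC, Other,
5'-SC, 3'-SC), under which 5'-SC can never fire.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align

from .synthetic_data import MODE_DC, MODE_OTHER, MODE_SC3, MODE_SC5, MODE_UNCLASSIFIED

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2
DEFAULT_MIN_LEN = 15


@dataclass(frozen=True)
class AlignmentCoords:
    """1-based cut coordinates: alignment start - 1 and alignment end."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if not 0 <= self.x < self.y:
            raise ValueError(f"invalid coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class CleavageCall:
    mode: str
    site: int | None

    def __post_init__(self) -> None:
        if (self.site is None) != (self.mode == MODE_UNCLASSIFIED):
            raise ValueError("site must be defined iff the mode is classified")


def make_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def locate_product(
    cp: str,
    flos: str,
    aligner: Align.PairwiseAligner | None = None,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[AlignmentCoords | None, str | None]:
    """Best local alignment of a cleaved product within its substrate.

    Returns (coords, None) on success or (None, reason) when the read
    is discarded: products longer than the substrate, alignments
    spanning fewer than ``min_len`` substrate positions, or ties between
    distinct best-scoring spans.
    """
    if len(cp) > len(flos):
        return None, "cp_longer_than_substrate"
    if not cp:
        return None, "empty_product"
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(flos, cp)
    try:
        best = alignments[0]
    except IndexError:
        return None, "no_alignment"
    blocks = best.aligned[0]
    start, end = int(blocks[0][0]), int(blocks[-1][-1])
    if end - start < min_len:
        return None, "alignment_too_short"
    if len(alignments) > 1:
        second = alignments[1]
        blocks2 = second.aligned[0]
        span2 = (int(blocks2[0][0]), int(blocks2[-1][-1]))
        if span2 != (start, end):
            return None, "ambiguous_alignment"
    return AlignmentCoords(x=start, y=end), None


def classify_cleavage(
    coords: AlignmentCoords, C: int = 72, rules_as_printed: bool = False
) -> CleavageCall:
    """Resolve (x, y) to a cleavage mode and site (see module docstring)."""
    x, y = coords.x, coords.y
    dc_x = 19 <= x <= 23
    other_y = (68 <= y <= 72) if rules_as_printed else (49 <= y <= 53)
    if dc_x and y == C - x:
        return CleavageCall(MODE_DC, x)
    if dc_x and other_y and y != C - x:
        return CleavageCall(MODE_OTHER, x)
    if rules_as_printed:
        # published order: DC, Other, 5'-SC, 3'-SC (first match wins)
        if dc_x and 68 <= y <= 72:
            return CleavageCall(MODE_SC5, x)
        if 0 <= x <= 4 and 49 <= y <= 53:
            return CleavageCall(MODE_SC3, C - y)
        return CleavageCall(MODE_UNCLASSIFIED, None)
    if 0 <= x <= 4 and 49 <= y <= 53:
        return CleavageCall(MODE_SC3, C - y)
    if dc_x and 68 <= y <= 72:
        return CleavageCall(MODE_SC5, x)
    return CleavageCall(MODE_UNCLASSIFIED, None)


def site_counts(
    calls,
) -> dict[str, Counter]:
    """Per-variant (mode, site) count matrix from (variant_id, call) pairs.

    Unclassified calls are tallied under (unclassified, None) so totals
    are conserved.
    """
    out: dict[str, Counter] = {}
    for variant_id, call in calls:
        out.setdefault(variant_id, Counter())[(call.mode, call.site)] += 1
    return out
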