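"""Motif-score applications to pre-miRNA hairpins.

Locates the DICER cleavage site from mature-arm annotations, assigns
positional mWCU/YCR scores from score tables, screens SNPs for large
score changes, computes upstream-window motif enrichment, and
classifies isomiR reads into DCx registers.

All coordinates are 1-based positions on the hairpin sequence.  The
nucleotide-pair registry of a hairpin is the dot-bracket pairing table
augmented with symmetric-mismatch partners (see
``structure_annotation.extended_partner_map``); bulged and
asymmetrically looped nt have no partner and break motif windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .structure_annotation import annotate_structure, extended_partner_map

#: pair positions screened for motifs (potential mWCU/YCR positions)
MOTIF_POSITIONS = tuple(range(17, 23))

#: upstream window lengths (nt from the cleavage site towards the 5' end);
#: "1 nt from the site" is the position immediately 5' of the cut.
YCR_WINDOW_NT = 5
MWCU_WINDOW_NT = 7

SNP_SELECTION_THRESHOLD = 20.0


@dataclass(frozen=True)
class PreMiRNARecord:
    id: str
    sequence: str
    dotbracket: str
    mature5p: tuple[int, int] | None = None  # 1-based inclusive span
    mature3p: tuple[int, int] | None = None
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError(f"{self.id}: sequence/structure length mismatch")
        for span in (self.mature5p, self.mature3p):
            if span is not None and not (1 <= span[0] <= span[1] <= len(self.sequence)):
                raise ValueError(f"{self.id}: mature span {span} outside sequence")


@dataclass(frozen=True)
class CleavageSite:
    """5'-strand cut coordinate (cut between x and x+1) and provenance."""

    x: int
    source: str  # "3p", "5p" or "both"
    flagged: bool = False


def _partners_1based(dotbracket: str) -> list[int | None]:
    ext = extended_partner_map(dotbracket)
    return [None] + [None if p is None else p + 1 for p in ext]


def find_cleavage_site(record: PreMiRNARecord) -> CleavageSite | None:
    """Cut coordinate on the 5' strand from the mature-arm annotations.

    The 3p mature 5'-end defines the 3'-strand cut; the paired 5'-strand
    coordinate follows 2-nt 3'-overhang geometry through the pair
    registry (unpaired 3p start positions are walked 3'-ward to the
    nearest partnered position).  The 5p mature 3'-end defines the
    5'-strand cut directly.  Disagreeing annotations are flagged.
    Records without any mature annotation are skipped (None).
    """
    x5 = record.mature5p[1] if record.mature5p else None
    x3 = None
    if record.mature3p:
        partners = _partners_1based(record.dotbracket)
        s = record.mature3p[0]
        for k in range(0, len(record.sequence) - s + 1):
            partner = partners[s + k]
            if partner is not None:
                x3 = partner + 2 + k
                break
    if x3 is not None and x5 is not None:
        return CleavageSite(x=x3, source="both", flagged=(x3 != x5))
    if x3 is not None:
        return CleavageSite(x=x3, source="3p")
    if x5 is not None:
        return CleavageSite(x=x5, source="5p")
    return None


def motif_at(record: PreMiRNARecord, position: int) -> str | None:
    """6-character pair motif whose first pair position is ``position``.

    None when any of the three 5'-strand positions lacks a partner in
    the pair registry (bulge or asymmetric loop breaks the triple).
    """
    partners = _partners_1based(record.dotbracket)
    n = len(record.sequence)
    if position < 1 or position + 2 > n:
        return None
    nt5 = []
    nt3 = []
    for p in (position, position + 1, position + 2):
        partner = partners[p]
        if partner is None:
            return None
        nt5.append(record.sequence[p - 1])
        nt3.append(record.sequence[partner - 1])
    return "".join(nt5) + "".join(nt3)


def assign_scores(
    record: PreMiRNARecord,
    tables: Mapping[str, Mapping[str, float]],
    positions: Sequence[int] = MOTIF_POSITIONS,
) -> dict[int, dict[str, float | str | None]]:
    """Positional motif scores for a folded hairpin.

    ``tables`` maps a class name (e.g. ``"mWCU"``) to a motif -> score
    lookup.  Positions whose window triple is broken, or whose motif is
    absent from a table, get None for that class.
    """
    out: dict[int, dict[str, float | str | None]] = {}
    for pos in positions:
        motif = motif_at(record, pos)
        entry: dict[str, float | str | None] = {"motif": motif}
        for name, table in tables.items():
            entry[name] = None if motif is None else _lookup(table, motif)
        out[pos] = entry
    return out


def _lookup(table: Mapping[str, float], motif: str) -> float | None:
    value = table.get(motif)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


@dataclass(frozen=True)
class SnpEvent:
    position: int  # sequence position of the substitution
    ref: str
    alt: str
    motif_position: int
    wt_score: float | None
    snp_score: float | None
    delta: float | None
    selected: bool


def snp_impact(
    wt: PreMiRNARecord,
    snp: PreMiRNARecord,
    motif_position: int,
    table: Mapping[str, float],
    threshold: float = SNP_SELECTION_THRESHOLD,
) -> SnpEvent:
    """Score change caused by a single-nucleotide substitution.

    Selected iff both scores exist and |delta| >= threshold (20 units).
    """
    if len(wt.sequence) != len(snp.sequence):
        raise ValueError("SNP record must be a substitution (equal lengths)")
    diffs = [
        i + 1 for i, (a, b) in enumerate(zip(wt.sequence, snp.sequence)) if a != b
    ]
    if len(diffs) == 0:
        position, ref, alt = 0, "", ""
    elif len(diffs) == 1:
        position = diffs[0]
        ref, alt = wt.sequence[position - 1], snp.sequence[position - 1]
    else:
        raise ValueError(f"expected a single substitution, found {len(diffs)}")
    wt_motif = motif_at(wt, motif_position)
    snp_motif = motif_at(snp, motif_position)
    wt_score = _lookup(table, wt_motif) if wt_motif else None
    snp_score = _lookup(table, snp_motif) if snp_motif else None
    delta = None if wt_score is None or snp_score is None else snp_score - wt_score
    selected = delta is not None and abs(delta) >= threshold
    return SnpEvent(
        position=position,
        ref=ref,
        alt=alt,
        motif_position=motif_position,
        wt_score=wt_score,
        snp_score=snp_score,
        delta=delta,
        selected=selected,
    )


def motif_enrichment(
    records: Iterable[PreMiRNARecord],
    predicate: Callable[[str], bool],
    window_nt: int,
    exclude_ids: Iterable[str] = (),
    by_species: bool = False,
) -> dict[str, float] | float | None:
    """Fraction of pre-miRNAs carrying a class motif in the upstream window.

    A record counts as a carrier when at least one motif whose first
    pair position lies within ``window_nt`` nt 5' of its cleavage site
    (positions x - window_nt + 1 .. x) satisfies ``predicate``.  Records
    without a locatable cleavage site are skipped.  Returns None (or an
    empty dict) when no records qualify.
    """
    excluded = set(exclude_ids)
    totals: dict[str, int] = {}
    carriers: dict[str, int] = {}
    for record in records:
        if record.id in excluded:
            continue
        site = find_cleavage_site(record)
        if site is None:
            continue
        key = record.species if by_species else ""
        totals[key] = totals.get(key, 0) + 1
        has_motif = False
        for pos in range(site.x - window_nt + 1, site.x + 1):
            motif = motif_at(record, pos)
            if motif is not None and predicate(motif):
                has_motif = True
                break
        if has_motif:
            carriers[key] = carriers.get(key, 0) + 1
    if not totals:
        return {} if by_species else None
    freqs = {k: carriers.get(k, 0) / n for k, n in totals.items()}
    return freqs if by_species else freqs[""]


@dataclass(frozen=True)
class IsomirRead:
    """Aggregated 3p small-RNA reads sharing one 5'-end position."""

    start: int  # 1-based hairpin position of the 3p read 5'-end
    count: int
    unmodified_ends: bool = True


@dataclass(frozen=True)
class IsomirCall:
    mirna_id: str
    dcx: int
    reads: int
    dc_proportion: float


def isomir_dcx(
    record: PreMiRNARecord,
    reads: Iterable[IsomirRead],
    min_reads: int = 10,
) -> list[IsomirCall]:
    """DCx classification of 3p isomiR 5'-ends.

    Only reads with unmodified ends and strictly more than ``min_reads``
    raw reads enter.  x is the duplex register of the implied 5'-strand
    cut: the number of base-pair or symmetric-mismatch positions from
    the hairpin 5'-end to the cut, i.e. bulges and asymmetric
    mismatches are not counted.
    """
    profile = annotate_structure(record.dotbracket)
    partners = _partners_1based(record.dotbracket)
    n = len(record.sequence)
    tally: dict[int, int] = {}
    for read in reads:
        if not read.unmodified_ends or read.count <= min_reads:
            continue
        x5 = None
        for k in range(0, n - read.start + 1):
            partner = partners[read.start + k]
            if partner is not None:
                x5 = partner + 2 + k
                break
        if x5 is None or x5 > n:
            continue
        dcx = sum(1 for c in profile.symbols[:x5] if c in ("b", "M"))
        tally[dcx] = tally.get(dcx, 0) + read.count
    total = sum(tally.values())
    return [
        IsomirCall(
            mirna_id=record.id,
            dcx=dcx,
            reads=count,
            dc_proportion=count / total if total else float("nan"),
        )
        for dcx, count in sorted(tally.items())
    ]


def dc21_fold_change(
    calls_wt: Sequence[IsomirCall],
    calls_mut: Sequence[IsomirCall],
    min_fraction: float = 0.05,
) -> float | None:
    """Fold change of the DC21 proportion (mutant / WT).

    Restricted to pre-miRNAs whose WT DC21 isoforms account for strictly
    more than ``min_fraction`` of all DC calls; otherwise None.
    """
    wt = {c.dcx: c.dc_proportion for c in calls_wt}
    mut = {c.dcx: c.dc_proportion for c in calls_mut}
    wt21 = wt.get(21, 0.0)
    if not wt21 > min_fraction:
        return None
    return mut.get(21, 0.0) / wt21
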