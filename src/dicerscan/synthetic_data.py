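"""Synthetic two-loop shRNA library and cleavage simulator.

This module builds the randomized hairpin library (six 3-bp windows over
pair positions 14-21 on a fixed backbone), simulates enzyme-specific
cleavage under a two-motif multinomial site model, and emits OS/DC/SC
FASTQ files together with the ground truth, so the whole downstream
pipeline is testable without any external data.

Coordinate conventions
----------------------
Positions on the full-length substrate (FL-OS) are 1-based.  The 5'-arm
occupies positions ``1..S`` (S = stem length in pairs, 22 by default),
the apical loop follows, and the 3'-arm runs to ``full_len``.  Pair
position ``i`` on the 5' strand is paired with position
``full_len + 1 - i`` on the 3' strand.  A double cleavage at site ``x``
cuts the 5' strand between ``x`` and ``x+1`` and the 3' strand between
``y = C - x`` and ``y + 1`` where ``C`` is ``coord_const`` (72 by
default, i.e. a 2-nt 3' overhang on a 70-nt substrate).

The physical construct carries a secondary loop -- the left delimiter,
a 32-nt random barcode, and the right delimiter -- inserted between
FL-OS positions ``loop_insert_pos`` and ``loop_insert_pos + 1`` inside
the apical loop, so every classifiable cleavage fragment spans it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif_scoring import is_mwcu_pattern, is_ycr_pattern

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: double-cleavage sites modelled throughout the package
SITES = tuple(range(19, 24))

#: cleavage-mode labels
MODE_DC = "DC"
MODE_OTHER = "Other"
MODE_SC5 = "5p_SC"
MODE_SC3 = "3p_SC"
MODE_UNCLASSIFIED = "unclassified"

#: simulator outcome categories (mode, site)
CATEGORIES = tuple(
    (mode, site) for mode in (MODE_DC, MODE_SC5, MODE_SC3) for site in SITES
)

#: enzyme variants and the factor applied to mWCU effects for each
ENZYME_GATES = {"WT": 1.0, "dsRBD_del": 0.0, "R1855A": 0.0, "E1859A": None}

#: offset from the first pair position of a motif to its target DC site
MWCU_SITE_OFFSET = 4
YCR_SITE_OFFSET = 2

DEFAULT_BACKBONE_5P = "GACTCGATCGATCTGCTTGGAC"
DEFAULT_APICAL_LOOP = "CTTCCTATCACTCTCAAGTAGTTAAC"
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DesignError(ValueError):
    """Raised when a LibraryDesign is internally inconsistent."""


@dataclass(frozen=True)
class LibraryDesign:
    """Static layout of the two-loop shRNA construct."""

    backbone_5p: str = DEFAULT_BACKBONE_5P
    apical_loop: str = DEFAULT_APICAL_LOOP
    backbone_3p: str = ""  # derived as revcomp(backbone_5p) when empty
    window_starts: tuple[int, ...] = (14, 15, 16, 17, 18, 19)
    window_len: int = 3
    barcode_len: int = 32
    umi5_len: int = 6  # OS / SC libraries
    umi3_len: int = 4
    dc_umi5_len: int = 4  # DC library uses 4 nt on both ends
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = ""
    loop_delim_left: str = "GCTTGC"
    loop_delim_right: str = "GCAAGC"
    full_len: int = 70
    coord_const: int = 72
    loop_insert_pos: int = 35

    def __post_init__(self) -> None:
        if not self.backbone_3p:
            object.__setattr__(self, "backbone_3p", revcomp(self.backbone_5p))
        if len(self.backbone_5p) != len(self.backbone_3p):
            raise DesignError("5' and 3' backbone arms must have equal length")
        total = len(self.backbone_5p) + len(self.apical_loop) + len(self.backbone_3p)
        if total != self.full_len:
            raise DesignError(
                f"arm/loop lengths sum to {total}, expected full_len={self.full_len}"
            )
        for start in self.window_starts:
            if start < 1 or start + self.window_len - 1 > self.stem_len:
                raise DesignError(
                    f"window at pair position {start} extends outside the backbone stem"
                )
        lo, hi = max(SITES) + 1, self.coord_const - max(SITES) - 1
        if not lo <= self.loop_insert_pos <= hi:
            raise DesignError(
                f"loop_insert_pos must lie in [{lo}, {hi}] so every fragment spans it"
            )
        backbone = self.backbone_5p + self.apical_loop + self.backbone_3p
        for delim in (self.loop_delim_left, self.loop_delim_right):
            if not delim:
                raise DesignError("loop delimiters must be non-empty")
            if delim in backbone:
                raise DesignError(f"delimiter {delim} occurs in the backbone")

    @property
    def stem_len(self) -> int:
        return len(self.backbone_5p)

    def partner(self, pos: int) -> int:
        """3'-strand position paired with 5'-strand pair position ``pos``."""
        return self.full_len + 1 - pos

    def backbone_sequence(self) -> str:
        return self.backbone_5p + self.apical_loop + self.backbone_3p


@dataclass(frozen=True)
class ShRNAVariant:
    """One full-length substrate: a group, its 3-pair window fill, sequence."""

    variant_id: str
    group: int
    window_start: int
    fill5: str
    fill3: str
    sequence: str

    @property
    def fill(self) -> str:
        """6-character motif string: three 5'-strand nt then three 3'-strand nt."""
        return self.fill5 + self.fill3


def variant_sequence(design: LibraryDesign, window_start: int, fill5: str, fill3: str) -> str:
    """FL-OS sequence for a window fill placed on the backbone.

    ``fill3[k]`` is the nt at the 3'-strand partner of pair position
    ``window_start + k`` (i.e. 3' nt are ordered by their 5' partner).
    """
    arm5 = list(design.backbone_5p)
    arm3 = list(design.backbone_3p)
    offset = design.stem_len + len(design.apical_loop)  # positions before arm3
    for k in range(design.window_len):
        pos = window_start + k
        arm5[pos - 1] = fill5[k]
        arm3[design.partner(pos) - offset - 1] = fill3[k]
    return "".join(arm5) + design.apical_loop + "".join(arm3)


def build_variant_library(design: LibraryDesign) -> list[ShRNAVariant]:
    """Enumerate every window fill of every group (4^(2*window_len) each)."""
    variants = []
    n = design.window_len
    for group, start in enumerate(design.window_starts, start=1):
        for combo in itertools.product(DNA, repeat=2 * n):
            fill5 = "".join(combo[:n])
            fill3 = "".join(combo[n:])
            seq = variant_sequence(design, start, fill5, fill3)
            variants.append(
                ShRNAVariant(
                    variant_id=f"g{group}_{fill5}{fill3}",
                    group=group,
                    window_start=start,
                    fill5=fill5,
                    fill3=fill3,
                    sequence=seq,
                )
            )
    return variants


def dedup_reference(
    variants: Iterable[ShRNAVariant],
) -> tuple[list[ShRNAVariant], dict[str, str]]:
    """Collapse variants identical across groups (first occurrence wins).

    Returns the unique variant list and the sequence -> canonical
    variant-id index used for perfect-match assignment.
    """
    unique: list[ShRNAVariant] = []
    index: dict[str, str] = {}
    for v in variants:
        if v.sequence not in index:
            index[v.sequence] = v.variant_id
            unique.append(v)
    return unique, index


def expected_unique_count(design: LibraryDesign) -> int:
    """Closed-form unique-sequence count via inclusion-exclusion.

    Each group's sequence set is determined by which pair positions may
    deviate from the backbone; intersections of groups are the sequences
    supported on the overlap of their windows (16 assignments per pair
    position).
    """
    windows = [
        frozenset(range(s, s + design.window_len)) for s in design.window_starts
    ]
    total = 0
    for r in range(1, len(windows) + 1):
        sign = 1 if r % 2 == 1 else -1
        for subset in itertools.combinations(windows, r):
            overlap = frozenset.intersection(*subset)
            total += sign * 16 ** len(overlap)
    return total


def variant_pairs(design: LibraryDesign, variant: ShRNAVariant) -> dict[int, tuple[str, str]]:
    """(5' nt, 3' nt) at every pair position of a variant."""
    seq = variant.sequence
    return {
        pos: (seq[pos - 1], seq[design.partner(pos) - 1])
        for pos in range(1, design.stem_len + 1)
    }


def design_dotbracket(design: LibraryDesign, variant: ShRNAVariant) -> str:
    """Dot-bracket implied by the design pairing model (WC + GU wobble).

    Stands in for an MFE folder: pair position i is paired iff its two
    nt form a Watson-Crick or wobble pair, everything else is unpaired.
    """
    ok = {"AT", "TA", "GC", "CG", "GT", "TG"}
    pairs = variant_pairs(design, variant)
    db = ["."] * design.full_len
    for pos, (a, b) in pairs.items():
        if a + b in ok:
            db[pos - 1] = "("
            db[design.partner(pos) - 1] = ")"
    return "".join(db)


@dataclass
class CleavageModel:
    """Two-motif multinomial site model.

    Site logits start from ``base_logits`` (DC sites 19-23).  An mWCU
    whose first pair position is N adds its effect to DC(N+4), gated by
    the enzyme's dsRBD status; a YCR at N adds its effect to DC(N+2)
    and subtracts ``ycr_sc_suppression`` from the single-cleavage
    propensity.  Single-cleavage categories share the per-site logits
    shifted by ``sc_logit``.  Per-motif graded effects can be supplied
    via ``mwcu_effects`` / ``ycr_effects`` (6-character fill -> logit);
    otherwise the pattern predicates gate flat ``beta_*`` effects.
    """

    base_logits: Mapping[int, float] = field(
        default_factory=lambda: {19: 0.2, 20: 0.8, 21: 2.0, 22: 1.6, 23: 0.1}
    )
    sc_logit: float = -1.5
    beta_mwcu: float = 0.0
    beta_ycr: float = 0.0
    ycr_sc_suppression: float = 0.0
    enzyme: str = "WT"
    e1859a_attenuation: float = 0.4
    mwcu_effects: Mapping[str, float] | None = None
    ycr_effects: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_GATES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")

    @property
    def dsrbd_gate(self) -> float:
        gate = ENZYME_GATES[self.enzyme]
        return self.e1859a_attenuation if gate is None else gate


def _motif_string(pairs: Mapping[int, tuple[str, str]], pos: int) -> str:
    triple = [pairs[pos + k] for k in range(3)]
    return "".join(p[0] for p in triple) + "".join(p[1] for p in triple)


def simulate_cleavage(
    variant: ShRNAVariant, model: CleavageModel, design: LibraryDesign
) -> dict[tuple[str, int], float]:
    """Probability over (mode, site) categories for one variant."""
    pairs = variant_pairs(design, variant)
    dc_adj = {s: float(model.base_logits.get(s, -np.inf)) for s in SITES}
    sc_shift = model.sc_logit
    gate = model.dsrbd_gate
    for pos in range(1, design.stem_len - 1):
        motif = _motif_string(pairs, pos)
        target = pos + MWCU_SITE_OFFSET
        if target in dc_adj:
            if model.mwcu_effects is not None:
                eff = model.mwcu_effects.get(motif, 0.0)
            else:
                eff = model.beta_mwcu if is_mwcu_pattern(motif) else 0.0
            dc_adj[target] += gate * eff
        target = pos + YCR_SITE_OFFSET
        if target in dc_adj:
            if model.ycr_effects is not None:
                eff = model.ycr_effects.get(motif, 0.0)
            else:
                eff = model.beta_ycr if is_ycr_pattern(motif) else 0.0
            dc_adj[target] += eff
            if is_ycr_pattern(motif):
                sc_shift -= model.ycr_sc_suppression
    logits = np.array(
        [dc_adj[s] for s in SITES]
        + [dc_adj[s] + sc_shift for s in SITES]  # 5'-SC
        + [dc_adj[s] + sc_shift for s in SITES]  # 3'-SC
    )
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    return dict(zip(CATEGORIES, probs))


@dataclass
class GroundTruth:
    """True per-variant site distributions and the emitted read counts."""

    variants: list[ShRNAVariant]
    barcodes: dict[str, list[str]]
    probs: dict[str, dict[tuple[str, int], float]]
    counts: dict[str, dict[tuple[str, int], int]]
    os_reads: int
    seed: int


def simulate_library(
    variants: Sequence[ShRNAVariant],
    model: CleavageModel,
    design: LibraryDesign,
    n_reads: int,
    seed: int,
    os_reads: int = 30,
    n_barcodes: int = 2,
) -> GroundTruth:
    """Draw barcodes and multinomial cleavage-read counts for each variant.

    RNG stream order: variants are visited in list order; for each one
    the barcodes are drawn first, then the multinomial counts.
    """
    rng = np.random.default_rng(seed)
    barcodes: dict[str, list[str]] = {}
    probs: dict[str, dict[tuple[str, int], float]] = {}
    counts: dict[str, dict[tuple[str, int], int]] = {}
    for v in variants:
        barcodes[v.variant_id] = [
            "".join(DNA[i] for i in rng.integers(0, 4, design.barcode_len))
            for _ in range(n_barcodes)
        ]
        p = simulate_cleavage(v, model, design)
        probs[v.variant_id] = p
        pvec = np.array([p[c] for c in CATEGORIES])
        draw = rng.multinomial(n_reads, pvec)
        counts[v.variant_id] = dict(zip(CATEGORIES, (int(k) for k in draw)))
    return GroundTruth(
        variants=list(variants),
        barcodes=barcodes,
        probs=probs,
        counts=counts,
        os_reads=os_reads,
        seed=seed,
    )


def _fragment_bounds(design: LibraryDesign, mode: str, site: int) -> tuple[int, int]:
    if mode == MODE_DC:
        return site + 1, design.coord_const - site
    if mode == MODE_SC5:
        return site + 1, design.full_len
    if mode == MODE_SC3:
        return 1, design.coord_const - site
    raise ValueError(f"cannot emit mode {mode!r}")


def _embed_loop(design: LibraryDesign, flos: str, a: int, b: int, barcode: str) -> str:
    """Substrate fragment [a, b] (1-based inclusive) with the secondary loop."""
    if a < 1 or b > design.full_len:
        raise RuntimeError(f"fragment bounds ({a}, {b}) outside the substrate")
    p = design.loop_insert_pos
    if a <= p and p + 1 <= b:
        return (
            flos[a - 1 : p]
            + design.loop_delim_left
            + barcode
            + design.loop_delim_right
            + flos[p : b]
        )
    return flos[a - 1 : b]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = DNA[rng.integers(0, 4)]
    return "".join(chars)


def emit_reads(
    truth: GroundTruth,
    design: LibraryDesign,
    out_dir: str | Path,
    error_rate: float = 0.0,
) -> dict[str, Path]:
    """Write os.fastq / dc.fastq / sc.fastq for a simulated run.

    Byte-identical for identical ``truth`` (the RNG is re-seeded from
    ``truth.seed``).  Reads are emitted pre-joined: 5' adapter, 5' UMI,
    fragment with the embedded secondary loop, 3' UMI, 3' adapter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed + 1)
    paths = {k: out_dir / f"{k}.fastq" for k in ("os", "dc", "sc")}
    handles = {k: open(p, "w") for k, p in paths.items()}

    def umi(n: int) -> str:
        return "".join(DNA[i] for i in rng.integers(0, 4, n))

    def write(lib: str, rid: str, insert: str, u5: int, u3: int) -> None:
        seq = design.adapter5 + umi(u5) + insert + umi(u3) + design.adapter3
        seq = _mutate(seq, error_rate, rng)
        handles[lib].write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    try:
        for v in truth.variants:
            codes = truth.barcodes[v.variant_id]
            for i in range(truth.os_reads):
                bc = codes[int(rng.integers(0, len(codes)))]
                insert = _embed_loop(design, v.sequence, 1, design.full_len, bc)
                write("os", f"os:{v.variant_id}:{i}", insert, design.umi5_len, design.umi3_len)
            for (mode, site) in CATEGORIES:
                n = truth.counts[v.variant_id].get((mode, site), 0)
                a, b = _fragment_bounds(design, mode, site)
                for i in range(n):
                    bc = codes[int(rng.integers(0, len(codes)))]
                    insert = _embed_loop(design, v.sequence, a, b, bc)
                    if mode == MODE_DC:
                        write(
                            "dc",
                            f"dc:{v.variant_id}:{mode}{site}:{i}",
                            insert,
                            design.dc_umi5_len,
                            design.umi3_len,
                        )
                    else:
                        write(
                            "sc",
                            f"sc:{v.variant_id}:{mode}{site}:{i}",
                            insert,
                            design.umi5_len,
                            design.umi3_len,
                        )
    finally:
        for h in handles.values():
            h.close()
    return paths


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth table (one row per variant x category) as TSV."""
    import pandas as pd

    rows = []
    for v in truth.variants:
        for (mode, site) in CATEGORIES:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "group": v.group,
                    "fill": v.fill,
                    "mode": mode,
                    "site": site,
                    "prob": truth.probs[v.variant_id][(mode, site)],
                    "count": truth.counts[v.variant_id][(mode, site)],
                    "seed": truth.seed,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def graded_motif_effects(
    seed: int,
    motif_class: str,
    spread: float = 1.2,
    pattern_bonus: float = 1.5,
) -> dict[str, float]:
    """Deterministic per-fill effect map for parameter-recovery runs.

    Every 6-character fill receives a uniform effect in [0, spread);
    fills matching the class pattern get ``pattern_bonus`` on top, so
    planted motifs sit above controls while the ordering stays graded.
    """
    predicate = {"mWCU": is_mwcu_pattern, "YCR": is_ycr_pattern}[motif_class]
    rng = np.random.default_rng(seed)
    fills = ["".join(c) for c in itertools.product(DNA, repeat=6)]
    effects = {}
    for fill in fills:
        effects[fill] = float(rng.uniform(0.0, spread))
        if predicate(fill):
            effects[fill] += pattern_bonus
    return effects


def subset_variants(
    variants: Sequence[ShRNAVariant], n: int, seed: int
) -> list[ShRNAVariant]:
    """Seeded sample of ``n`` variants (without replacement)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(variants), size=n, replace=False)
    return [variants[i] for i in sorted(idx)]
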