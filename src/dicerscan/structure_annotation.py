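"""Dot-bracket to 6-symbol positional structure code.

Each position of a single-hairpin structure is annotated with one of
six symbols:

* ``b`` base pair
* ``L`` apical loop
* ``M`` symmetric mismatch (internal loop of equal length on both strands)
* ``A`` asymmetric mismatch (internal loop of unequal, nonzero lengths)
* ``B`` bulge (unpaired on one strand only)
* ``T`` 3'-overhang (trailing unpaired tail)

Unpaired nt preceding the first base pair have no counterpart symbol in
the code; they are annotated ``B`` (one-sided unpaired) here.

The stem length is the number of ``b`` plus ``M`` positions on the
5'-strand from the first base pair of the stem to the apical loop.

Folding itself is delegated: the module consumes dot-bracket strings
from any minimum-free-energy folder (or from the simulator's design
pairing model).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

LOOP = "L"
PAIR = "b"
SYM_MISMATCH = "M"
ASYM_MISMATCH = "A"
BULGE = "B"
TAIL = "T"


class StructureError(ValueError):
    """Unbalanced, pseudoknotted or multi-hairpin input."""


def pair_table(dotbracket: str) -> list[int | None]:
    """0-based partner index per position (None when unpaired)."""
    table: list[int | None] = [None] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError("unbalanced dot-bracket")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise StructureError(f"unsupported notation {c!r} (pseudoknot?)")
    if stack:
        raise StructureError("unbalanced dot-bracket")
    return table


def _check_single_hairpin(dotbracket: str) -> None:
    if "(" not in dotbracket:
        raise StructureError("no base pairs: not a hairpin")
    if len(re.findall(r"\(\.*\)", dotbracket)) != 1:
        raise StructureError("multi-loop structures are unsupported")


@dataclass(frozen=True)
class StructureProfile:
    symbols: str
    stem_len: int
    structure_id: str


def annotate_structure(dotbracket: str, sequence: str | None = None) -> StructureProfile:
    """Convert a single-hairpin dot-bracket into the 6-symbol code."""
    if sequence is not None and len(sequence) != len(dotbracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    _check_single_hairpin(dotbracket)
    pt = pair_table(dotbracket)
    n = len(dotbracket)
    symbols: list[str] = [""] * n
    opens = [i for i in range(n) if dotbracket[i] == "("]
    for i in opens:
        symbols[i] = PAIR
        symbols[pt[i]] = PAIR
    innermost = opens[-1]
    for i in range(innermost + 1, pt[innermost]):
        symbols[i] = LOOP
    for i in range(pt[opens[0]] + 1, n):  # 3' tail
        symbols[i] = TAIL
    for i in range(opens[0]):  # 5' leading unpaired: one-sided
        symbols[i] = BULGE
    for a, b in zip(opens, opens[1:]):
        gap5 = list(range(a + 1, b))
        gap3 = list(range(pt[b] + 1, pt[a]))
        if not gap5 and not gap3:
            continue
        if len(gap5) == len(gap3):
            symbol = SYM_MISMATCH
        elif gap5 and gap3:
            symbol = ASYM_MISMATCH
        else:
            symbol = BULGE
        for i in gap5 + gap3:
            symbols[i] = symbol
    code = "".join(symbols)
    return StructureProfile(
        symbols=code,
        stem_len=stem_length(code),
        structure_id=hashlib.sha1(code.encode()).hexdigest()[:12],
    )


def stem_length(symbols: str) -> int:
    """bp + symmetric mismatches on the 5'-strand, first bp to apical loop."""
    first_b = symbols.find(PAIR)
    loop = symbols.find(LOOP)
    if first_b < 0 or loop < 0 or loop < first_b:
        raise StructureError("profile has no stem or no apical loop")
    return sum(1 for c in symbols[first_b:loop] if c in (PAIR, SYM_MISMATCH))


def select_structures(
    profiles: Mapping[str, str], min_variants: int = 50
) -> dict[str, list[str]]:
    """Group variants by identical symbol strings; keep classes with
    at least ``min_variants`` members."""
    classes: dict[str, list[str]] = {}
    for variant_id, symbols in profiles.items():
        classes.setdefault(symbols, []).append(variant_id)
    return {s: members for s, members in classes.items() if len(members) >= min_variants}


def extended_partner_map(dotbracket: str) -> list[int | None]:
    """Pairing table augmented with symmetric-mismatch partners.

    Base-paired positions keep their dot-bracket partner; positions in
    symmetric internal loops are paired outside-in with their opposite
    run; bulges, asymmetric loops, the apical loop and tails stay
    unpartnered.  Used to read nucleotide-pair motifs off a hairpin.
    """
    _check_single_hairpin(dotbracket)
    pt = pair_table(dotbracket)
    extended = list(pt)
    opens = [i for i in range(len(dotbracket)) if dotbracket[i] == "("]
    for a, b in zip(opens, opens[1:]):
        gap5 = list(range(a + 1, b))
        gap3 = list(range(pt[b] + 1, pt[a]))
        if gap5 and len(gap5) == len(gap3):
            for i, j in zip(gap5, reversed(gap3)):
                extended[i], extended[j] = j, i
    return extended


def annotate_library(
    dotbrackets: Mapping[str, str],
) -> dict[str, StructureProfile]:
    return {vid: annotate_structure(db) for vid, db in dotbrackets.items()}
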