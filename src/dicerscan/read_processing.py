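"""Raw reads to per-variant counts.

Adapter stripping, terminal-UMI trimming, duplicate collapsing, body /
32N-barcode splitting, the unique FL-OS/32N dictionary, and
perfect-match assignment against the enumerated reference.

Reads are consumed pre-joined (pair joining and base-quality filtering
are treated as upstream glue); an optional mean-quality filter is
exposed but off by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as handle:
        for rid, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(rid, seq.upper(), qual)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


class DiscardLog:
    """Per-stage discard tally; keeps reads_in == kept + discarded auditable."""

    def __init__(self) -> None:
        self.counts: Counter[tuple[str, str]] = Counter()

    def discard(self, stage: str, reason: str, n: int = 1) -> None:
        self.counts[(stage, reason)] += n

    def total(self, stage: str | None = None) -> int:
        if stage is None:
            return sum(self.counts.values())
        return sum(n for (s, _), n in self.counts.items() if s == stage)

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "reason": r, "reads": n}
            for (s, r), n in sorted(self.counts.items())
        ]

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_rows(), columns=["stage", "reason", "reads"]).to_csv(
            path, sep="\t", index=False
        )


def strip_adapters(seq: str, adapter3: str = "", adapter5: str = "") -> str:
    """Functional equivalent of cutadapt -a/-g with exact matching.

    The 3' adapter is searched as an exact substring and the read is cut
    at its first occurrence; a 5' adapter prefix is removed when present.
    Reads without the adapter are returned unchanged (the fragment may
    simply not reach it).
    """
    if adapter5 and seq.startswith(adapter5):
        seq = seq[len(adapter5) :]
    if adapter3:
        pos = seq.find(adapter3)
        if pos >= 0:
            seq = seq[:pos]
    return seq


def trim_ends(seq: str, n5: int, n3: int) -> tuple[str, str, str] | None:
    """Remove n5/n3 terminal randomized nt; None when the read is too short.

    Returns (umi5, body, umi3); the body must be non-empty.
    """
    if len(seq) <= n5 + n3:
        return None
    umi5 = seq[:n5]
    umi3 = seq[len(seq) - n3 :] if n3 else ""
    body = seq[n5 : len(seq) - n3] if n3 else seq[n5:]
    return umi5, body, umi3


def dedup_reads(seqs: Iterable[str]) -> list[str]:
    """Collapse identical sequences (terminal UMIs still attached) to one.

    Collapser semantics: one representative per distinct string, counts
    collapsed to 1, input order of first occurrence preserved.
    """
    seen: set[str] = set()
    out: list[str] = []
    for s in seqs:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def split_two_loop(
    body: str,
    left_delim: str = "GCTTGC",
    right_delim: str = "GCAAGC",
    barcode_len: int = 32,
) -> tuple[str, str] | None:
    """Split a body into (shrna_part, barcode32); None -> discard.

    The barcode is the segment between the first ``left_delim`` and the
    first following ``right_delim`` and must be exactly ``barcode_len``
    nt; the shRNA part is the concatenation of the two flanks.  Search
    is exact-match, forward strand only.
    """
    if not left_delim or not right_delim:
        raise ValueError("delimiters must be non-empty")
    i = body.find(left_delim)
    if i < 0:
        return None
    j = body.find(right_delim, i + len(left_delim))
    if j < 0:
        return None
    barcode = body[i + len(left_delim) : j]
    if len(barcode) != barcode_len:
        return None
    return body[:i] + body[j + len(right_delim) :], barcode


def build_os_dictionary(
    pairs: Iterable[tuple[str, str]],
) -> dict[str, tuple[str, int]]:
    """Unique FL-OS/32N dictionary from (FL-OS, barcode) observations.

    Any barcode observed with two or more distinct FL-OS sequences is
    discarded entirely; retained entries keep their read counts.
    """
    flos_by_barcode: dict[str, str] = {}
    counts: Counter[str] = Counter()
    ambiguous: set[str] = set()
    for flos, barcode in pairs:
        if barcode in ambiguous:
            continue
        prev = flos_by_barcode.get(barcode)
        if prev is None:
            flos_by_barcode[barcode] = flos
            counts[barcode] += 1
        elif prev == flos:
            counts[barcode] += 1
        else:
            ambiguous.add(barcode)
            del flos_by_barcode[barcode]
            del counts[barcode]
    return {bc: (flos, counts[bc]) for bc, flos in flos_by_barcode.items()}


def build_reference_index(variants: Sequence) -> dict[str, str]:
    """sequence -> variant_id for a deduplicated variant list."""
    return {v.sequence: v.variant_id for v in variants}


def match_reference(flos: str, reference_index: Mapping[str, str]) -> str | None:
    """Exact full-length match only; anything else is dropped."""
    return reference_index.get(flos)


def mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


@dataclass
class OSResult:
    dictionary: dict[str, tuple[str, int]]
    counts: Counter = field(default_factory=Counter)  # variant_id -> raw count
    barcode_to_variant: dict[str, str] = field(default_factory=dict)
    log: DiscardLog = field(default_factory=DiscardLog)


def process_os_reads(
    reads: Iterable[ReadRecord],
    design,
    reference_index: Mapping[str, str],
    min_mean_quality: float | None = None,
) -> OSResult:
    """OS library -> FL-OS/32N dictionary and per-variant raw counts.

    The raw count of a variant is the sum of dictionary read counts over
    its retained barcodes.
    """
    log = DiscardLog()
    deduped = _preprocess(reads, design, log, min_mean_quality)
    pairs: list[tuple[str, str]] = []
    n_ambiguous_input = 0
    for seq in deduped:
        trimmed = trim_ends(seq, design.umi5_len, design.umi3_len)
        if trimmed is None:
            log.discard("trim", "too_short")
            continue
        split = split_two_loop(
            trimmed[1],
            design.loop_delim_left,
            design.loop_delim_right,
            design.barcode_len,
        )
        if split is None:
            log.discard("split", "no_32N_barcode")
            continue
        pairs.append(split)
    dictionary = build_os_dictionary(pairs)
    retained_barcodes = set(dictionary)
    n_ambiguous_input = sum(
        1 for _, bc in pairs if bc not in retained_barcodes
    )
    if n_ambiguous_input:
        log.discard("dictionary", "ambiguous_barcode", n_ambiguous_input)
    result = OSResult(dictionary=dictionary, log=log)
    for barcode, (flos, count) in dictionary.items():
        variant_id = match_reference(flos, reference_index)
        if variant_id is None:
            log.discard("match", "not_in_reference", count)
            continue
        result.counts[variant_id] += count
        result.barcode_to_variant[barcode] = variant_id
    return result


def _preprocess(
    reads: Iterable[ReadRecord],
    design,
    log: DiscardLog,
    min_mean_quality: float | None,
) -> list[str]:
    """Adapter stripping, optional quality filter, duplicate collapsing."""
    seqs: list[str] = []
    for r in reads:
        if min_mean_quality is not None and r.qual is not None:
            if mean_quality(r.qual) < min_mean_quality:
                log.discard("quality", "low_mean_quality")
                continue
        seqs.append(strip_adapters(r.seq, design.adapter3, design.adapter5))
    unique = dedup_reads(seqs)
    if len(seqs) != len(unique):
        log.discard("dedup", "duplicate_read", len(seqs) - len(unique))
    return unique


def cpm(counts: Mapping[str, float]) -> dict[str, float]:
    """Counts-per-million normalization over one library sample."""
    total = float(sum(counts.values()))
    if total == 0:
        return {k: 0.0 for k in counts}
    scale = 1e6 / total
    return {k: v * scale for k, v in counts.items()}
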