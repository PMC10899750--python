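"""End-to-end glue: FASTQ libraries -> per-variant score tables.

One replicate run consumes an OS library (builds the FL-OS/32N
dictionary and substrate counts) plus DC and SC libraries (cleaved
products), localizes each product in its barcode-assigned substrate,
classifies the cleavage, and produces the score table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import read_processing as rp
from .cleavage_mapping import (
    CleavageCall,
    classify_cleavage,
    locate_product,
    make_aligner,
)
from .scoring import build_score_table
from .synthetic_data import LibraryDesign, MODE_UNCLASSIFIED


@dataclass
class CleavageLibraryResult:
    counts: dict[str, Counter] = field(default_factory=dict)  # variant -> (mode, site) -> n
    log: rp.DiscardLog = field(default_factory=rp.DiscardLog)

    def total_classified(self) -> int:
        return sum(
            n
            for per_variant in self.counts.values()
            for (mode, _), n in per_variant.items()
            if mode != MODE_UNCLASSIFIED
        )


def process_cleavage_reads(
    reads: Iterable[rp.ReadRecord],
    design: LibraryDesign,
    dictionary: Mapping[str, tuple[str, int]],
    barcode_to_variant: Mapping[str, str],
    umi5_len: int,
    umi3_len: int,
    rules_as_printed: bool = False,
    min_mean_quality: float | None = None,
) -> CleavageLibraryResult:
    """One cleavage library (DC or SC) -> per-variant (mode, site) counts.

    Products are assigned to substrates via the 32N barcode, located by
    local alignment (cached per distinct product/substrate pair) and
    classified by the coordinate rules.
    """
    result = CleavageLibraryResult()
    log = result.log
    aligner = make_aligner()
    align_cache: dict[tuple[str, str], tuple] = {}
    deduped = rp._preprocess(reads, design, log, min_mean_quality)
    for seq in deduped:
        trimmed = rp.trim_ends(seq, umi5_len, umi3_len)
        if trimmed is None:
            log.discard("trim", "too_short")
            continue
        split = rp.split_two_loop(
            trimmed[1],
            design.loop_delim_left,
            design.loop_delim_right,
            design.barcode_len,
        )
        if split is None:
            log.discard("split", "no_32N_barcode")
            continue
        cp, barcode = split
        entry = dictionary.get(barcode)
        if entry is None:
            log.discard("assign", "barcode_not_in_dictionary")
            continue
        flos = entry[0]
        variant_id = barcode_to_variant.get(barcode)
        if variant_id is None:
            log.discard("assign", "substrate_not_in_reference")
            continue
        key = (cp, flos)
        if key not in align_cache:
            align_cache[key] = locate_product(cp, flos, aligner=aligner)
        coords, reason = align_cache[key]
        if coords is None:
            log.discard("align", reason)
            continue
        call = classify_cleavage(
            coords, C=design.coord_const, rules_as_printed=rules_as_printed
        )
        result.counts.setdefault(variant_id, Counter())[(call.mode, call.site)] += 1
    return result


@dataclass
class RunResult:
    os_result: rp.OSResult
    dc_result: CleavageLibraryResult
    sc_result: CleavageLibraryResult
    score_table: pd.DataFrame

    def classified_counts(self, variant_id: str) -> Counter:
        """Combined DC+SC library (mode, site) counts for one variant."""
        combined: Counter = Counter()
        for res in (self.dc_result, self.sc_result):
            for key, n in res.counts.get(variant_id, Counter()).items():
                if key[0] != MODE_UNCLASSIFIED:
                    combined[key] += n
        return combined


def process_run(
    os_fastq: str | Path,
    dc_fastq: str | Path,
    sc_fastq: str | Path,
    design: LibraryDesign,
    reference_index: Mapping[str, str],
    rules_as_printed: bool = False,
    min_mean_quality: float | None = None,
) -> RunResult:
    """Process one replicate's three libraries into a score table.

    CPM normalization is per library sample over counted items: matched
    substrates for OS, classified calls for DC and SC.
    """
    os_result = rp.process_os_reads(
        rp.read_fastq(os_fastq), design, reference_index, min_mean_quality
    )
    dc_result = process_cleavage_reads(
        rp.read_fastq(dc_fastq),
        design,
        os_result.dictionary,
        os_result.barcode_to_variant,
        design.dc_umi5_len,
        design.umi3_len,
        rules_as_printed,
        min_mean_quality,
    )
    sc_result = process_cleavage_reads(
        rp.read_fastq(sc_fastq),
        design,
        os_result.dictionary,
        os_result.barcode_to_variant,
        design.umi5_len,
        design.umi3_len,
        rules_as_printed,
        min_mean_quality,
    )
    ns_cpm = rp.cpm(os_result.counts)
    np_cpm = _library_cpm(dc_result, sc_result)
    table = build_score_table(ns_cpm, np_cpm)
    return RunResult(os_result, dc_result, sc_result, table)


def _library_cpm(
    dc_result: CleavageLibraryResult, sc_result: CleavageLibraryResult
) -> dict[str, dict[tuple[str, int | None], float]]:
    out: dict[str, dict[tuple[str, int | None], float]] = {}
    for res in (dc_result, sc_result):
        flat: dict[tuple[str, tuple[str, int | None]], int] = {}
        for variant_id, per_variant in res.counts.items():
            for key, n in per_variant.items():
                if key[0] == MODE_UNCLASSIFIED:
                    continue
                flat[(variant_id, key)] = n
        normalized = rp.cpm(flat)
        for (variant_id, key), v in normalized.items():
            out.setdefault(variant_id, {})[key] = (
                out.get(variant_id, {}).get(key, 0.0) + v
            )
    return out


def enzyme_score_frame(
    score_table: pd.DataFrame, variants: Iterable
) -> pd.DataFrame:
    """Attach group/window/fill metadata to a score table for motif scoring."""
    meta = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "group": [v.group for v in variants],
            "window_start": [v.window_start for v in variants],
            "fill": [v.fill for v in variants],
        }
    )
    return meta.merge(score_table, on="variant_id", how="inner")
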