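"""Efficiency, accuracy and ratio statistics.

All counts entering these formulas are counts-per-million within their
own library sample; 0.1 is the pseudocount throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.1


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def local_efficiency(np_site: float, ns: float) -> float:
    """log2(NP + 0.1) - log2(NS + 0.1) for one cleavage site."""
    _check_nonneg("NP", np_site)
    _check_nonneg("NS", ns)
    return math.log2(np_site + PSEUDOCOUNT) - math.log2(ns + PSEUDOCOUNT)


def total_efficiency(np_list: Iterable[float], ns: float) -> float:
    """log2(sum(NP) + 0.1) - log2(NS + 0.1), one cleavage mode at a time."""
    total = 0.0
    for v in np_list:
        _check_nonneg("NP", v)
        total += v
    _check_nonneg("NS", ns)
    return math.log2(total + PSEUDOCOUNT) - math.log2(ns + PSEUDOCOUNT)


def accuracy(np_by_site: Mapping[int, float]) -> dict[int, float]:
    """NP / sum(NP) per site; empty when the mode has no counts."""
    total = sum(np_by_site.values())
    if total <= 0:
        return {}
    return {site: v / total for site, v in np_by_site.items()}


def log2_dc_sc(np_dc: Iterable[float], np_sc: Iterable[float]) -> float:
    """log2(sum(NP_DC) + 0.1) - log2(sum(NP_SC) + 0.1)."""
    return total_efficiency(np_dc, sum(np_sc))


@dataclass(frozen=True)
class EffectSize:
    m1: float
    m2: float
    sd1: float
    sd2: float
    d: float


def cohens_d(sample1: Sequence[float], sample2: Sequence[float]) -> EffectSize:
    """d = (M1 - M2) / sqrt(SD1^2/2 + SD2^2/2).

    The /2 is fixed regardless of sample sizes; standard deviations use
    n-1 denominators.  d is NaN when the pooled SD is zero.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    m1, m2 = float(a.mean()), float(b.mean())
    sd1, sd2 = float(a.std(ddof=1)), float(b.std(ddof=1))
    pooled = math.sqrt(sd1**2 / 2 + sd2**2 / 2)
    d = (m1 - m2) / pooled if pooled > 0 else float("nan")
    return EffectSize(m1=m1, m2=m2, sd1=sd1, sd2=sd2, d=d)


def replicate_average(values: Iterable[float]) -> float:
    """Mean over available replicates; NaN replicates are excluded.

    Undefined values (e.g. accuracy of a zero-count replicate) are left
    out rather than imputed as 0; all-missing input yields NaN.
    """
    vals = [v for v in values if v is not None and not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def build_score_table(
    ns_cpm: Mapping[str, float],
    np_cpm: Mapping[str, Mapping[tuple[str, int], float]],
    sites: Sequence[int] = tuple(range(19, 24)),
) -> pd.DataFrame:
    """Per-variant score table for one replicate.

    ``ns_cpm``: variant -> OS CPM.  ``np_cpm``: variant -> {(mode, site)
    -> CPM} with modes ``DC``, ``5p_SC``, ``3p_SC`` (``Other`` is carried
    through for audit but enters no formula).  Columns: NP per mode and
    site, local/total efficiencies, per-mode accuracies, log2(DC/SC).
    """
    rows = []
    for variant_id in sorted(set(ns_cpm) | set(np_cpm)):
        ns = float(ns_cpm.get(variant_id, 0.0))
        by_mode: dict[str, dict[int, float]] = {"DC": {}, "5p_SC": {}, "3p_SC": {}}
        for (mode, site), v in np_cpm.get(variant_id, {}).items():
            if mode in by_mode and site in sites:
                by_mode[mode][site] = by_mode[mode].get(site, 0.0) + float(v)
        row: dict[str, float | str] = {"variant_id": variant_id, "ns_cpm": ns}
        dc = by_mode["DC"]
        sc = {
            site: by_mode["5p_SC"].get(site, 0.0) + by_mode["3p_SC"].get(site, 0.0)
            for site in sites
        }
        for site in sites:
            row[f"np_dc_{site}"] = dc.get(site, 0.0)
            row[f"np_sc5_{site}"] = by_mode["5p_SC"].get(site, 0.0)
            row[f"np_sc3_{site}"] = by_mode["3p_SC"].get(site, 0.0)
            row[f"eff_dc_{site}"] = local_efficiency(dc.get(site, 0.0), ns)
        row["total_eff_dc"] = total_efficiency(dc.values(), ns)
        row["total_eff_sc"] = total_efficiency(sc.values(), ns)
        row["log2_dc_sc"] = log2_dc_sc(dc.values(), sc.values())
        acc_dc = accuracy({site: dc.get(site, 0.0) for site in sites})
        acc_sc5 = accuracy({site: by_mode["5p_SC"].get(site, 0.0) for site in sites})
        acc_sc3 = accuracy({site: by_mode["3p_SC"].get(site, 0.0) for site in sites})
        for site in sites:
            row[f"acc_dc_{site}"] = acc_dc.get(site, float("nan"))
            row[f"acc_sc5_{site}"] = acc_sc5.get(site, float("nan"))
            row[f"acc_sc3_{site}"] = acc_sc3.get(site, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Variant-wise mean of numeric columns across replicate score tables.

    NaN cells (undefined accuracies) are excluded from the mean rather
    than imputed.
    """
    stacked = pd.concat(tables, axis=0)
    return stacked.groupby("variant_id").mean(numeric_only=True).reset_index()
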