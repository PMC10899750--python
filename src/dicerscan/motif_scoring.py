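"""mWCU / YCR motif scoring from per-window cleavage accuracies.

A motif is an ordered triple of nucleotide pairs at three consecutive
pair positions, serialized as a 6-character string: the three 5'-strand
nt followed by the three 3'-strand nt (the k-th 3' nt is the partner of
the k-th 5' nt).  Per-window accuracies are min-max rescaled to 0-100
and averaged into the motif score.

Window -> cleavage-site table: mWCU scores use the windows whose first
pair positions are 16, 17 and 18, scored at DC20, DC21 and DC22 (the
motif's mismatch-adjacent site lies 4 positions downstream of its first
position).  YCR scores use windows 18, 19 and 20 at DC20, DC21, DC22
(site = first position + 2); the 20-window does not exist in a library
whose windows start at 14..19, in which case the score falls back to
the mean of the two available windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MWCU_WINDOWS: dict[int, int] = {16: 20, 17: 21, 18: 22}
YCR_WINDOWS: dict[int, int] = {18: 20, 19: 21, 20: 22}
WINDOW_TABLES = {"mWCU": MWCU_WINDOWS, "YCR": YCR_WINDOWS}

_W_PAIRS = {("A", "T"), ("T", "A")}
_RY_PAIRS = {("G", "C"), ("A", "T")}
_PYRIMIDINES = {"C", "T"}


def motif_pairs(motif: str) -> tuple[tuple[str, str], ...]:
    """Split a 6-character motif string into its three (5' nt, 3' nt) pairs."""
    if len(motif) != 6:
        raise ValueError(f"motif must be 6 characters, got {motif!r}")
    return tuple((motif[k], motif[k + 3]) for k in range(3))


def is_mwcu_pattern(motif: str | Sequence[tuple[str, str]]) -> bool:
    """Sequence-pattern predicate for mWCU (U is represented as T).

    First pair a weak Watson-Crick pair (A-T or T-A), second pair the
    C-C mismatch, third pair containing at least one T.
    """
    p1, p2, p3 = motif_pairs(motif) if isinstance(motif, str) else tuple(motif)
    return p1 in _W_PAIRS and p2 == ("C", "C") and "T" in p3


def is_ycr_pattern(motif: str | Sequence[tuple[str, str]]) -> bool:
    """Sequence-pattern predicate for YCR (U is represented as T).

    First pair containing at least one pyrimidine (excludes R-R
    combinations), second pair C-G, third pair an R-Y pair (G-C or A-T).
    """
    p1, p2, p3 = motif_pairs(motif) if isinstance(motif, str) else tuple(motif)
    return bool(_PYRIMIDINES.intersection(p1)) and p2 == ("C", "G") and p3 in _RY_PAIRS


def window_accuracy(
    enzyme_scores: pd.DataFrame,
    window: int,
    site: int,
    motif_class: str,
    stem_ok: set[str] | None = None,
) -> pd.Series:
    """Mean DC accuracy at ``site`` per motif, over one window's variants.

    ``enzyme_scores`` must carry columns ``variant_id``, ``window_start``,
    ``fill`` and ``acc_dc_<site>``.  ``stem_ok`` optionally restricts to
    variants whose predicted structure preserves the reference stem
    length (variants outside it are excluded, which in turn drops any
    motif left without variants).
    """
    table = WINDOW_TABLES[motif_class]
    if table.get(window) != site:
        raise ValueError(
            f"window {window} / site DC{site} is not a defined {motif_class} pairing"
        )
    col = f"acc_dc_{site}"
    sub = enzyme_scores[enzyme_scores["window_start"] == window]
    if stem_ok is not None:
        sub = sub[sub["variant_id"].isin(stem_ok)]
    sub = sub.dropna(subset=[col])
    return sub.groupby("fill")[col].mean()


def minmax_rescale(values: pd.Series | np.ndarray) -> pd.Series:
    """Rescale to [0, 100]; a degenerate (constant) input maps to all 0."""
    s = pd.Series(values, dtype=float)
    lo, hi = s.min(), s.max()
    if not np.isfinite(hi - lo) or hi == lo:
        return pd.Series(0.0, index=s.index)
    return (s - lo) / (hi - lo) * 100.0


def motif_score(window_scores: Iterable[float]) -> float:
    """Mean of the available (non-NaN) rescaled window scores.

    At least two windows are required; with fewer the score is NaN.
    """
    vals = np.asarray([v for v in window_scores if v is not None and not np.isnan(v)])
    if vals.size < 2:
        return float("nan")
    return float(vals.mean())


def compute_motif_scores(
    enzyme_scores: pd.DataFrame,
    motif_class: str,
    stem_ok: set[str] | None = None,
) -> pd.DataFrame:
    """Per-motif rescaled window accuracies and the averaged score.

    Output: one row per motif with a ``<class>_dc<site>`` column per
    available window and a ``score`` column.  Windows absent from the
    input (e.g. the YCR 20-window in a 14..19 library) are skipped and
    the averaging falls back to the windows that exist.
    """
    table = WINDOW_TABLES[motif_class]
    available = set(enzyme_scores["window_start"].unique())
    cols: dict[str, pd.Series] = {}
    for window, site in table.items():
        if window not in available:
            continue
        acc = window_accuracy(enzyme_scores, window, site, motif_class, stem_ok)
        cols[f"{motif_class.lower()}_dc{site}"] = minmax_rescale(acc)
    if not cols:
        raise ValueError(f"no {motif_class} windows present in the score table")
    out = pd.DataFrame(cols)
    out.index.name = "motif"
    out["score"] = out.apply(lambda row: motif_score(row.values), axis=1)
    return out


def top_percentile_motifs(
    scores: pd.Series, percentile: float = 97.0
) -> pd.Index:
    """Motifs with score >= the given percentile value (ties included)."""
    s = scores.dropna()
    if s.empty:
        return pd.Index([])
    cutoff = np.percentile(s.values, percentile)
    return s.index[s.values >= cutoff]


def top_composition(
    scores: pd.Series,
    percentile: float = 97.0,
    display_threshold: float = 0.05,
) -> dict[int, dict[str, float]]:
    """Pair-combination frequencies at each motif position among top motifs.

    For each of the three positions, the 16 ordered 5'-3' nt
    combinations (e.g. ``A-T``) are tallied over the top-percentile
    motifs; combinations below ``display_threshold`` are pooled into
    ``other``.  A combination at exactly the threshold is shown.
    """
    top = top_percentile_motifs(scores, percentile)
    result: dict[int, dict[str, float]] = {}
    n = len(top)
    for k in range(3):
        counts: dict[str, int] = {}
        for motif in top:
            combo = f"{motif[k]}-{motif[k + 3]}"
            counts[combo] = counts.get(combo, 0) + 1
        freqs: dict[str, float] = {}
        other = 0.0
        for combo, c in sorted(counts.items()):
            f = c / n if n else float("nan")
            if f >= display_threshold:
                freqs[combo] = f
            else:
                other += f
        if other > 0:
            freqs["other"] = other
        result[k + 1] = freqs
    return result


@dataclass(frozen=True)
class MotifScore:
    motif: str
    window_scores: tuple[float, ...]
    score: float

    @property
    def n_windows(self) -> int:
        return sum(1 for v in self.window_scores if not np.isnan(v))


def classify_motif(
    motif: str,
    mwcu_scores: pd.Series | None = None,
    ycr_scores: pd.Series | None = None,
    percentile: float = 97.0,
) -> str:
    """Class = membership of the top-percentile set of a score table.

    Returns ``"mWCU"``, ``"YCR"`` or ``"neither"``; mWCU membership is
    checked first when both tables are given.
    """
    if mwcu_scores is not None and motif in set(top_percentile_motifs(mwcu_scores, percentile)):
        return "mWCU"
    if ycr_scores is not None and motif in set(top_percentile_motifs(ycr_scores, percentile)):
        return "YCR"
    return "neither"


def pattern_predicate(motif_class: str) -> Callable[[str], bool]:
    """Secondary sequence-pattern predicate for a motif class."""
    return {"mWCU": is_mwcu_pattern, "YCR": is_ycr_pattern}[motif_class]


def save_score_table(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t")


def load_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="motif")
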