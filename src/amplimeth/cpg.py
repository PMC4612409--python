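"""CpG island prediction with the sliding-window observed/expected statistic.

A window is CpG-island-like when its GC percentage exceeds ``min_gc`` and its
observed/expected CpG ratio

    obs/exp = (#CG dinucleotides × window length) / (#C × #G)

exceeds ``min_oe`` (the Gardiner-Garden & Frommer statistic).  Marked windows
are merged (union of overlapping or book-ended spans) and merged spans of at
least ``min_len`` bases are reported with the mean statistics of their
contributing windows.  Coordinates are 0-based half-open throughout.

N bases count toward window length but not toward any C/G/CpG count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CpGIslandCall",
    "obs_exp_cpg",
    "gc_percent",
    "predict_islands",
    "list_cpg_sites",
]

_VALID = re.compile(r"^[ACGTN]*$")


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid DNA characters: {bad}")
    return seq


@dataclass(frozen=True)
class CpGIslandCall:
    """One predicted island: [start, end) with mean window statistics."""

    start: int
    end: int
    gc_percent: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG ratio of one window; 0 when C or G is absent."""
    window = _check_dna(window)
    if len(window) < 2:
        raise ValueError("window must be at least 2 bases")
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = len(re.findall("(?=CG)", window))
    return n_cg * len(window) / (n_c * n_g)


def gc_percent(window: str) -> float:
    """G+C content of a window in percent (N bases dilute, see module docs)."""
    window = _check_dna(window)
    if not window:
        raise ValueError("empty window")
    return 100.0 * (window.count("C") + window.count("G")) / len(window)


def list_cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CG dinucleotide, ascending."""
    seq = _check_dna(seq)
    return [m.start() for m in re.finditer("(?=CG)", seq)]


def predict_islands(
    seq: str,
    window: int = 100,
    shift: int = 1,
    min_len: int = 200,
    min_gc: float = 50.0,
    min_oe: float = 0.6,
) -> list[CpGIslandCall]:
    """Slide a window along ``seq`` and report merged CpG-island spans.

    Returns calls sorted by start, non-overlapping.  A sequence shorter than
    the window yields an empty list with a warning rather than an error.
    """
    seq = _check_dna(seq)
    if window < 2 or shift < 1 or min_len < 1:
        raise ValueError("window ≥ 2, shift ≥ 1, min_len ≥ 1 required")
    n = len(seq)
    if n < window:
        warnings.warn(f"sequence ({n} nt) shorter than window ({window} nt)")
        return []

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    is_cg[:-1] = is_c[:-1] & is_g[1:]

    # prefix sums give per-window counts in O(1); a CG dinucleotide belongs to
    # the window containing its C, so the last start position is excluded
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, n - window + 1, shift)
    wc = cum_c[starts + window] - cum_c[starts]
    wg = cum_g[starts + window] - cum_g[starts]
    wcg = cum_cg[starts + window - 1] - cum_cg[starts]

    gc = 100.0 * (wc + wg) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((wc > 0) & (wg > 0), wcg * window / (wc * wg), 0.0)
    marked = (gc > min_gc) & (oe > min_oe)

    calls: list[CpGIslandCall] = []
    i = 0
    idx = np.flatnonzero(marked)
    while i < len(idx):
        j = i
        span_start = int(starts[idx[i]])
        span_end = span_start + window
        # absorb windows that overlap or book-end the current span
        while j + 1 < len(idx) and starts[idx[j + 1]] <= span_end:
            j += 1
            span_end = int(starts[idx[j]]) + window
        if span_end - span_start >= min_len:
            members = idx[i : j + 1]
            calls.append(CpGIslandCall(
                start=span_start,
                end=span_end,
                gc_percent=float(gc[members].mean()),
                obs_exp=float(oe[members].mean()),
            ))
        i = j + 1
    return calls
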