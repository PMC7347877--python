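"""Signal quantification at regulatory elements, per-domain aggregation,
log2 fold-changes, and the three-way accessibility classification.

Signal tracks carry depth-normalized coverage in reads per million (rpm) as
piecewise-constant bedGraph segments; biological replicates are averaged with
equal weight before fold-changes are taken.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Domain, GenomicInterval, RegulatoryElement

__all__ = [
    "SignalTrack",
    "window_signal",
    "log2_change",
    "domain_signal",
    "classify_accessibility",
    "correlate",
    "ACCESSIBILITY_THRESHOLD",
]

ACCESSIBILITY_THRESHOLD = 0.585  # |log2FC| band edge, ~1.5-fold


class SignalTrack:
    """Piecewise-constant per-chromosome coverage (bedGraph semantics, rpm).

    Gaps between segments read as 0. Built from a (chrom, start, end, value)
    frame; segments must be sorted and non-overlapping per chromosome.
    """

    def __init__(self, df: pd.DataFrame):
        if (df["value"] < 0).any():
            raise ValueError("signal values must be >= 0")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(int)
            ends = grp["end"].to_numpy(int)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom}")
            self._by_chrom[str(chrom)] = (starts, ends, grp["value"].to_numpy(float))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def mean_over(self, window: GenomicInterval) -> float:
        """Length-weighted mean over the window (gaps count as 0)."""
        if window.chrom not in self._by_chrom:
            raise KeyError(f"chromosome {window.chrom!r} not in track")
        starts, ends, vals = self._by_chrom[window.chrom]
        lo = np.searchsorted(ends, window.start, side="right")
        hi = np.searchsorted(starts, window.end, side="left")
        total = 0.0
        for k in range(lo, hi):
            ov = min(ends[k], window.end) - max(starts[k], window.start)
            if ov > 0:
                total += ov * vals[k]
        return total / len(window)


def window_signal(
    tracks: SignalTrack | Sequence[SignalTrack], window: GenomicInterval
) -> float:
    """Length-weighted mean rpm over the window; replicate tracks averaged
    with equal weight."""
    if isinstance(tracks, SignalTrack):
        tracks = [tracks]
    return float(np.mean([t.mean_over(window) for t in tracks]))


def log2_change(cko: float, ctrl: float, pseudocount: float = 0.1) -> float:
    """log2((cko + pc) / (ctrl + pc)). The pseudocount (rpm) guards empty
    windows; 0.1 is small against typical peak signal."""
    if cko < 0 or ctrl < 0:
        raise ValueError("signal must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((cko + pseudocount) / (ctrl + pseudocount))


def domain_signal(
    domain: Domain,
    elements: Sequence[RegulatoryElement | GenomicInterval],
    tracks: SignalTrack | Sequence[SignalTrack],
) -> float:
    """Unweighted mean of window_signal over all DHS windows whose center lies
    inside the domain; NaN when the domain holds no DHS."""
    means = []
    for el in elements:
        window = el.window if isinstance(el, RegulatoryElement) else el
        if window.chrom != domain.interval.chrom:
            continue
        if domain.interval.contains_point(window.center):
            means.append(window_signal(tracks, window))
    if not means:
        return float("nan")
    return float(np.mean(means))


def classify_accessibility(
    log2fc: float, threshold: float = ACCESSIBILITY_THRESHOLD
) -> str:
    """'increased' iff log2FC > threshold, 'decreased' iff < -threshold, else
    'unchanged'; boundary values fall in 'unchanged' (strict inequalities)."""
    if not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if log2fc > threshold:
        return "increased"
    if log2fc < -threshold:
        return "decreased"
    return "unchanged"


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson's r or Spearman's rho with a two-sided p, after dropping pairs
    with a missing member."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
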