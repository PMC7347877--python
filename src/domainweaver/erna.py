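"""Enhancer-RNA quantification: bidirectional stranded windows at enhancer
DHS centers, gene-exclusion filtering, strand-specific fragment counting,
the low-count filter, and size-factor-normalized fold-changes.

Each eRNA feature is a pair of 2 kb windows flanking a DHS center: the
upstream window counts Crick (-) strand transcription, the downstream window
Watson (+) strand transcription, capturing the bidirectional initiation
signature of active enhancers.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, RegulatoryElement
from .io import GeneRecord, StrandedFragment

__all__ = [
    "ErnaFeature",
    "build_erna_features",
    "count_fragments",
    "filter_low",
    "size_factors",
    "erna_log2fc",
    "WINDOW_BP",
    "EXCLUSION_EXTENSION_BP",
]

log = logging.getLogger(__name__)

WINDOW_BP = 2000
EXCLUSION_EXTENSION_BP = 1000


@dataclass
class ErnaFeature:
    """Bidirectional eRNA window pair centered on a DHS.

    counts maps condition -> per-replicate integer counts (both windows
    summed), e.g. {"ctrl": [12, 15], "cko": [30, 27]}.
    """

    chrom: str
    dhs_center: int
    minus_window: GenomicInterval = field(init=False)
    plus_window: GenomicInterval = field(init=False)
    counts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.dhs_center
        if c < WINDOW_BP:
            raise ValueError("upstream window extends past chromosome start")
        self.minus_window = GenomicInterval(self.chrom, c - WINDOW_BP, c)
        self.plus_window = GenomicInterval(self.chrom, c, c + WINDOW_BP)

    def total_count(self) -> int:
        return sum(sum(v) for v in self.counts.values())


def _exclusion_regions(genes: Sequence[GeneRecord]) -> list[GenomicInterval]:
    """Gene bodies of coding genes and lncRNAs, extended 1 kb beyond both the
    TSS and the TES."""
    out = []
    for g in genes:
        if g.biotype not in ("protein_coding", "lncRNA", "lincRNA"):
            continue
        iv = g.interval
        out.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - EXCLUSION_EXTENSION_BP),
                iv.end + EXCLUSION_EXTENSION_BP,
            )
        )
    return out


def build_erna_features(
    dhs: Sequence[GenomicInterval],
    enhancers: Sequence[RegulatoryElement],
    genes: Sequence[GeneRecord],
) -> list[ErnaFeature]:
    """One feature per enhancer-overlapping DHS center.

    A feature is dropped when either stranded window overlaps a coding gene
    or lncRNA extended by 1 kb past its TSS and TES, or when the upstream
    window would run off the chromosome start.
    """
    exclusions = _exclusion_regions(genes)
    enhancer_anchors = {e.anchor for e in enhancers if e.kind == "enhancer"}
    features: list[ErnaFeature] = []
    for peak in dhs:
        if peak not in enhancer_anchors:
            continue
        center = peak.center
        if center < WINDOW_BP:
            log.info("dropping eRNA feature at %s:%d: window past chromosome start",
                     peak.chrom, center)
            continue
        feat = ErnaFeature(peak.chrom, center)
        if any(
            ex.overlap_len(feat.minus_window) > 0 or ex.overlap_len(feat.plus_window) > 0
            for ex in exclusions
        ):
            continue
        features.append(feat)
    return features


def count_fragments(
    features: Sequence[ErnaFeature],
    fragments_by_rep: dict[str, Sequence[Sequence[StrandedFragment]]],
) -> list[ErnaFeature]:
    """Fill per-replicate counts: a fragment counts for a feature when its
    5' end lies in the minus window with strand '-' or in the plus window
    with strand '+' (5'-end assignment prevents double counting)."""
    # windows are fixed-width, so a 5' position p stabs exactly the windows
    # whose start lies in (p - WINDOW_BP, p]; locate them by binary search
    index: dict[tuple[str, str], tuple[np.ndarray, list[int]]] = {}
    for strand, attr in (("-", "minus_window"), ("+", "plus_window")):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for k, feat in enumerate(features):
            w: GenomicInterval = getattr(feat, attr)
            by_chrom.setdefault(feat.chrom, []).append((w.start, k))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            index[(chrom, strand)] = (
                np.array([p[0] for p in pairs]),
                [p[1] for p in pairs],
            )

    for feat in features:
        feat.counts = {}
    for cond, reps in fragments_by_rep.items():
        for feat in features:
            feat.counts[cond] = [0] * len(reps)
        for r, frags in enumerate(reps):
            for fr in frags:
                key = (fr.interval.chrom, fr.strand)
                if key not in index:
                    continue
                starts, feat_idx = index[key]
                p5 = fr.five_prime
                lo = int(np.searchsorted(starts, p5 - WINDOW_BP, side="right"))
                hi = int(np.searchsorted(starts, p5, side="right"))
                for k in range(lo, hi):
                    features[feat_idx[k]].counts[cond][r] += 1
    return list(features)


def filter_low(
    features: Sequence[ErnaFeature], min_total: int = 10
) -> list[ErnaFeature]:
    """Keep features whose count summed over all replicates and conditions is
    at least ``min_total`` (features with fewer are removed from all
    analyses)."""
    return [f for f in features if f.total_count() >= min_total]


def size_factors(count_matrix: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (features x samples).

    Each sample's factor is the median, over features with a positive
    geometric mean, of the ratio count / geometric-mean.
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("need a non-empty features x samples matrix")
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(counts), axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("no feature has all-positive counts; cannot normalize")
    ratios = np.log(counts[usable]) - loggeo[usable, None]
    return np.exp(np.median(ratios, axis=0))


def erna_log2fc(
    features: Sequence[ErnaFeature],
    ctrl: str = "ctrl",
    cko: str = "cko",
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-feature log2 fold-change of knockout over control.

    Counts are scaled by median-of-ratios size factors across all retained
    features, averaged over replicates within a condition, then
    log2((cko + 0.5) / (ctrl + 0.5)).
    """
    if not features:
        raise ValueError("no retained eRNA features")
    mat = np.array(
        [f.counts[ctrl] + f.counts[cko] for f in features], dtype=float
    )
    n_ctrl = len(features[0].counts[ctrl])
    sf = size_factors(mat)
    normed = mat / sf
    mean_ctrl = normed[:, :n_ctrl].mean(axis=1)
    mean_cko = normed[:, n_ctrl:].mean(axis=1)
    return np.log2((mean_cko + pseudocount) / (mean_ctrl + pseudocount))
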