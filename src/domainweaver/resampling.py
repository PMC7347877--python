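"""Distance-controlled resampling null.

Compares the change in contact frequency at a test set of pixel pairs
(loop-domain boundary-loop anchors) against resampled sets of intra-domain
DHS pairs matched in number and pairwise distance. Distances are matched in
log2-width bins (bin k = [2^k, 2^(k+1)) bp), respecting the distance decay of
contact frequency; each of the N resamples draws, per test pair, one
candidate uniformly from the same distance bin.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .intervals import Domain, GenomicInterval

__all__ = [
    "PairSet",
    "ResamplingResult",
    "enumerate_candidate_pairs",
    "pair_log2fc",
    "distance_matched_resample",
    "empirical_pvalue",
    "resampling_test",
]

log = logging.getLogger(__name__)

PIXEL_PSEUDOCOUNT = 1e-3  # O/E units for per-pixel log2 fold-changes


@dataclass
class PairSet:
    """Positional pairs with distances and (optionally) per-pair values.

    ``pairs`` holds (chrom, pos_a, pos_b) with pos_a < pos_b; ``distances``
    is |pos_b - pos_a| in bp; ``values`` the per-pair log2FC of the O/E pixel
    containing the two positions.
    """

    pairs: pd.DataFrame  # columns: chrom, pos_a, pos_b, distance
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.pairs["distance"] <= 0).any():
            raise ValueError("pair distances must be > 0")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return self.pairs["distance"].to_numpy(int)

    def subset(self, idx: np.ndarray) -> "PairSet":
        return PairSet(
            self.pairs.iloc[idx].reset_index(drop=True),
            None if self.values is None else self.values[idx],
        )


@dataclass
class ResamplingResult:
    test_median: float
    resampled_medians: np.ndarray
    empirical_p: float
    seed: int
    n_resamples: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_resamples = len(self.resampled_medians)

    def p_text(self) -> str:
        if self.empirical_p == 0:
            return f"< {1 / self.n_resamples:g}"
        return f"{self.empirical_p:g}"


def enumerate_candidate_pairs(
    domains: Sequence[Domain], dhs: Sequence[GenomicInterval]
) -> PairSet:
    """All unordered pairs of DHS centers lying within the same domain
    (cross-domain pairs are never formed)."""
    rows = []
    for d in domains:
        iv = d.interval
        centers = sorted(
            p.center for p in dhs if p.chrom == iv.chrom and iv.contains_point(p.center)
        )
        for a, b in combinations(centers, 2):
            rows.append((iv.chrom, a, b, b - a))
    pairs = pd.DataFrame(rows, columns=["chrom", "pos_a", "pos_b", "distance"])
    return PairSet(pairs)


def pair_log2fc(
    pairset: PairSet,
    ctrl: dict[str, ContactMatrix],
    cko: dict[str, ContactMatrix],
    pseudocount: float = PIXEL_PSEUDOCOUNT,
) -> PairSet:
    """Attach per-pair values: log2FC of the O/E pixel containing the two
    positions, knockout over control."""
    vals = np.empty(len(pairset))
    for k, row in enumerate(pairset.pairs.itertuples(index=False)):
        mc, mk = ctrl[row.chrom], cko[row.chrom]
        i, j = row.pos_a // mc.resolution, row.pos_b // mc.resolution
        vals[k] = math.log2(
            (mk.value(i, j) + pseudocount) / (mc.value(i, j) + pseudocount)
        )
    return PairSet(pairset.pairs, vals)


def _dist_bin(d: np.ndarray | int) -> np.ndarray | int:
    return np.floor(np.log2(d)).astype(int) if isinstance(d, np.ndarray) else int(
        math.floor(math.log2(d))
    )


def distance_matched_resample(
    candidates: PairSet,
    test_distances: Sequence[int],
    n: int = 100,
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw ``n`` resampled candidate index sets matching the test set's
    distance histogram over log2-width bins.

    Within one resample, candidates are drawn without replacement; an
    exhausted bin falls back to with-replacement draws (logged). Fully
    determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    test_distances = np.asarray(test_distances, dtype=int)
    cand_bins = _dist_bin(candidates.distances)
    by_bin: dict[int, np.ndarray] = {
        b: np.flatnonzero(cand_bins == b) for b in np.unique(cand_bins)
    }
    need = pd.Series(_dist_bin(test_distances)).value_counts().sort_index()
    for b in need.index:
        if b not in by_bin:
            raise ValueError(
                f"no candidate pairs in distance bin [2^{b}, 2^{b + 1}) bp"
            )
    resamples = []
    for _ in range(n):
        picks: list[np.ndarray] = []
        for b, k in need.items():
            pool = by_bin[b]
            if k <= len(pool):
                picks.append(rng.choice(pool, size=k, replace=False))
            else:
                log.info(
                    "distance bin 2^%d exhausted (%d needed, %d available); "
                    "drawing with replacement", b, k, len(pool)
                )
                picks.append(rng.choice(pool, size=k, replace=True))
        resamples.append(np.concatenate(picks))
    return resamples


def empirical_pvalue(
    test_median: float, resampled_medians: np.ndarray, conservative: bool = False
) -> float:
    """One-sided empirical p: fraction of resampled medians below the test
    median. With ``conservative``, the (k+1)/(N+1) variant."""
    meds = np.asarray(resampled_medians, dtype=float)
    if meds.size == 0:
        raise ValueError("resampled_medians is empty")
    k = int((meds < test_median).sum())
    if conservative:
        return (k + 1) / (meds.size + 1)
    return k / meds.size


def resampling_test(
    test: PairSet,
    candidates: PairSet,
    n: int = 100,
    seed: int = 0,
    conservative: bool = False,
) -> ResamplingResult:
    """Full distance-controlled resampling test.

    Both pair sets must carry values (per-pair contact log2FC); the statistic
    is the median. Returns the test median, the n resampled medians, and the
    one-sided empirical p-value for the null producing a median below the
    test set's.
    """
    if test.values is None or candidates.values is None:
        raise ValueError("pair sets must carry values (use pair_log2fc)")
    idx_sets = distance_matched_resample(candidates, test.distances, n=n, seed=seed)
    meds = np.array([np.median(candidates.values[idx]) for idx in idx_sets])
    test_median = float(np.median(test.values))
    p = empirical_pvalue(test_median, meds, conservative=conservative)
    return ResamplingResult(test_median, meds, p, seed)
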