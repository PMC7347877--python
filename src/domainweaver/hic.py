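"""Sparse O/E KR contact-matrix model and the matrix statistics of the
analysis: domain/loop contact means, boundary insulation, aggregate peak
analysis (APA / P2LL), and the A/B compartment eigenvector.

Matrix values are observed-over-expected, KR-balanced contacts, so 1.0 is the
distance-decay background. Absent sparse entries are zeros (O/E dumps omit
empty pixels); the diagonal is excluded from domain means and insulation
totals because self-bin signal is not an interaction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .intervals import Domain, GenomicInterval, Loop

__all__ = [
    "ContactMatrix",
    "APAResult",
    "CompartmentTrack",
    "read_triples",
    "write_triples",
    "domain_contacts",
    "loop_contacts",
    "insulation_score",
    "apa",
    "compartment_eigenvector",
    "domain_eigenvalue",
]


@dataclass
class ContactMatrix:
    """Per-chromosome upper-triangle sparse map of O/E KR-normalized contacts.

    ``matrix`` is an n_bins x n_bins CSR matrix holding the upper triangle
    (i <= j); ``dense_symmetric`` mirrors it for windowed extraction.
    """

    chrom: str
    resolution: int
    matrix: sp.csr_matrix

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def value(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return float(self.matrix[i, j])

    def dense_symmetric(self) -> np.ndarray:
        a = self.matrix.toarray()
        return a + np.triu(a, 1).T

    def scaled(self, c: float) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.resolution, self.matrix * c)


@dataclass
class APAResult:
    """Aggregate peak analysis output: the mean (2w+1)x(2w+1) submatrix over
    loop-centered windows and the peak-to-lower-left ratio."""

    aggregate: np.ndarray
    p2ll: float
    n_loops_used: int
    n_loops_skipped: int = 0


@dataclass
class CompartmentTrack:
    """Per-bin signed eigenvector entries at a fixed bin size, sign-oriented so
    positive bins (A compartment) correlate with H3K27ac. Dropped bins are NaN."""

    chrom: str
    resolution: int
    eigenvalues: np.ndarray
    oriented: bool = True


def read_triples(path: str | Path, resolution: int, chrom: str) -> ContactMatrix:
    """Parse a contact-triple text file (``pos_i<TAB>pos_j<TAB>value``).

    Positions are bin left-coordinates and must be multiples of the
    resolution; records with i > j are mirrored to the upper triangle;
    duplicate pixels are an integrity error.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            try:
                pi, pj, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record") from exc
            if pi % resolution or pj % resolution:
                raise ValueError(
                    f"{path}:{ln}: position not a multiple of {resolution}"
                )
            bi, bj = pi // resolution, pj // resolution
            if bi > bj:
                bi, bj = bj, bi
            if (bi, bj) in seen:
                raise ValueError(f"{path}:{ln}: duplicate pixel ({pi}, {pj})")
            seen.add((bi, bj))
            rows.append(bi)
            cols.append(bj)
            vals.append(v)
    n = max(cols, default=-1) + 1
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return ContactMatrix(chrom, resolution, mat)


def write_triples(cm: ContactMatrix, path: str | Path) -> Path:
    path = Path(path)
    coo = sp.triu(cm.matrix).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for k in order:
            fh.write(
                f"{coo.row[k] * cm.resolution}\t{coo.col[k] * cm.resolution}\t"
                f"{float(coo.data[k])!r}\n"
            )
    return path


def _inner_bins(iv: GenomicInterval, resolution: int) -> tuple[int, int]:
    """Bin range [lo, hi) of bins lying fully inside the interval."""
    lo = -(-iv.start // resolution)
    hi = iv.end // resolution
    return lo, hi


def _covering_bins(iv: GenomicInterval, resolution: int) -> tuple[int, int]:
    """Bin range [lo, hi) of bins overlapping the interval."""
    return iv.start // resolution, -(-iv.end // resolution)


def domain_contacts(cm: ContactMatrix, d: Domain) -> float:
    """Mean O/E over all off-diagonal bin pairs fully inside the domain."""
    lo, hi = _inner_bins(d.interval, cm.resolution)
    n = hi - lo
    if n < 2:
        raise ValueError(
            f"domain {d.interval} spans {n} bin(s); need >= 2 at {cm.resolution} bp"
        )
    sub = cm.matrix[lo:hi, lo:hi]
    total = sp.triu(sub, k=1).sum()
    npairs = n * (n - 1) // 2
    return float(total) / npairs


def loop_contacts(cm: ContactMatrix, loop: Loop) -> float:
    """Mean O/E over the rectangle (bins of anchor1) x (bins of anchor2)."""
    lo1, hi1 = _covering_bins(loop.anchor1, cm.resolution)
    lo2, hi2 = _covering_bins(loop.anchor2, cm.resolution)
    if hi1 > lo2:
        raise ValueError("loop anchors overlap at this resolution")
    sub = cm.matrix[lo1:hi1, lo2:hi2]
    return float(sub.sum()) / ((hi1 - lo1) * (hi2 - lo2))


def insulation_score(
    cm: ContactMatrix, boundary_bin: int, domain_len_bins: int, eps: float = 1e-6
) -> float:
    """Boundary insulation: -log2 of the fraction of contact signal in the
    window [boundary - L, boundary + L) that crosses the boundary.

    crossing = sum over pairs i < boundary <= j; total = sum over all pairs
    i < j in the window. Higher scores mean stronger insulation.
    """
    if domain_len_bins < 1:
        raise ValueError("domain_len_bins must be >= 1")
    b, L = boundary_bin, domain_len_bins
    lo, hi = b - L, b + L
    if lo < 0 or hi > cm.n_bins:
        raise ValueError(
            f"window [{lo}, {hi}) outside chromosome ({cm.n_bins} bins)"
        )
    sub = cm.matrix[lo:hi, lo:hi].toarray()
    sub = np.triu(sub + np.triu(sub, 1).T, k=1)
    total = float(sub.sum())
    crossing = float(sub[: b - lo, b - lo :].sum())
    if total == 0 and eps == 0:
        raise ValueError("empty window with eps = 0")
    return -math.log2((crossing + eps) / (total + eps))


def apa(
    cm_ctrl: ContactMatrix,
    cm_cko: ContactMatrix,
    loops: list[Loop],
    w: int = 10,
) -> tuple[APAResult, APAResult]:
    """Aggregate peak analysis on both conditions over the same loop list.

    Each loop contributes the (2w+1)^2 window centered on the pixel of its
    anchor midpoints; loops whose window would touch the diagonal or the
    matrix edge are skipped. P2LL divides the aggregate's center by the mean
    of its ceil(w/2)-sized lower-left corner box (larger anchor1 coordinate,
    smaller anchor2 coordinate — the near-diagonal corner).
    """
    results = []
    for cm in (cm_ctrl, cm_cko):
        dense = cm.dense_symmetric()
        acc = np.zeros((2 * w + 1, 2 * w + 1))
        used = skipped = 0
        for lp in loops:
            ci = lp.anchor1.center // cm.resolution
            cj = lp.anchor2.center // cm.resolution
            if ci - w < 0 or cj + w >= cm.n_bins or ci + w >= cj - w:
                skipped += 1
                continue
            acc += dense[ci - w : ci + w + 1, cj - w : cj + w + 1]
            used += 1
        if used == 0:
            raise ValueError("no usable loops for APA (all skipped)")
        acc /= used
        c = math.ceil(w / 2)
        corner = acc[-c:, :c]
        p2ll = float(acc[w, w] / corner.mean())
        results.append(APAResult(acc, p2ll, used, skipped))
    return results[0], results[1]


def compartment_eigenvector(
    cm: ContactMatrix, h3k27ac_bins: np.ndarray
) -> CompartmentTrack:
    """A/B compartment eigenvector from the Pearson correlation matrix of the
    O/E map, sign-oriented so positive entries correlate with H3K27ac.

    Bins with zero marginal contact sum are dropped before the correlation
    and reported as NaN. The leading eigenvector is the one with the largest
    absolute eigenvalue of the correlation matrix.
    """
    h3k27ac_bins = np.asarray(h3k27ac_bins, dtype=float)
    if h3k27ac_bins.shape[0] != cm.n_bins:
        raise ValueError("H3K27ac vector length must equal bin count")
    dense = cm.dense_symmetric()
    keep = dense.sum(axis=1) > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 bins with contact signal")
    sub = dense[np.ix_(keep, keep)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    evals, evecs = np.linalg.eigh(corr)
    lead = int(np.argmax(np.abs(evals)))
    vec = evecs[:, lead]
    ac = h3k27ac_bins[keep]
    if np.std(ac) == 0:
        raise ValueError("zero-variance H3K27ac; cannot orient eigenvector")
    r = np.corrcoef(vec, ac)[0, 1]
    if r < 0:
        vec = -vec
    out = np.full(cm.n_bins, np.nan)
    out[keep] = vec
    return CompartmentTrack(cm.chrom, cm.resolution, out, oriented=True)


def domain_eigenvalue(track: CompartmentTrack, d: Domain) -> float:
    """Mean eigenvector entry of the track bins overlapping the domain (any
    overlap counts; NaN bins excluded). NaN when no spanned bin has a value."""
    lo, hi = _covering_bins(d.interval, track.resolution)
    hi = min(hi, len(track.eigenvalues))
    vals = track.eigenvalues[lo:hi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())
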