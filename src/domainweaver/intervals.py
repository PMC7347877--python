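"""Interval algebra, regulatory-element classification, and merging/classification
of contact domains and chromatin loops.

Coordinates are 0-based half-open (BED convention) throughout. Distances quoted
as "within N kb" are inclusive (<= N bp), matching bin-aligned Juicer-style calls.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "RegulatoryElement",
    "Domain",
    "Loop",
    "reciprocal_overlap",
    "classify_elements",
    "merge_loops",
    "merge_domains",
    "classify_domains",
    "classify_loops",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """bp from a point to the nearest base of the interval; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class RegulatoryElement:
    """A DHS-anchored enhancer or TSS-anchored promoter with its 1 kb
    quantification window."""

    kind: str  # "promoter" | "enhancer"
    anchor: GenomicInterval
    window: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if len(self.window) != 1000:
            raise ValueError("quantification window must be 1000 bp")


@dataclass
class Domain:
    """A contact domain. klass is 'loop' (boundary loop joins the borders) or
    'compartmental' (no such loop); source records which condition called it."""

    interval: GenomicInterval
    klass: str | None = None  # "loop" | "compartmental"
    source: str = "merged"  # "control" | "cko" | "merged"


@dataclass
class Loop:
    """A chromatin loop between two anchors on one chromosome (anchor1 upstream)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    klass: str | None = None  # "boundary" | "intra_domain" | "other"
    source: str = "merged"

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.end > self.anchor2.start:
            raise ValueError("anchor1 must lie upstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> int:
        return self.anchor2.center - self.anchor1.center


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    """True iff the overlap covers at least ``frac`` of BOTH intervals
    (bedtools ``-f frac -r`` semantics). Different chromosomes never overlap."""
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    ov = a.overlap_len(b)
    return ov >= frac * len(a) and ov >= frac * len(b)


def _window_around(chrom: str, center: int, width: int = 1000) -> GenomicInterval:
    half = width // 2
    start = max(0, center - half)
    return GenomicInterval(chrom, start, start + width)


def _any_contains_point(peaks: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(p.chrom == chrom and p.contains_point(pos) for p in peaks)


def classify_elements(
    dhs: Sequence[GenomicInterval],
    h3k27ac: Sequence[GenomicInterval],
    h3k4me1: Sequence[GenomicInterval],
    tss: Sequence[tuple[str, int]],
    frac: float = 0.25,
) -> list[RegulatoryElement]:
    """Classify active promoters and enhancers.

    Promoters: TSS positions lying inside both a DHS and an H3K27ac peak
    (point containment; the 25% reciprocal rule applies only between
    intervals). Enhancers: DHS peaks reciprocally overlapping (>= frac both
    ways) an H3K27ac and an H3K4me1 peak, excluding DHS that contain a
    classified promoter TSS. Each element carries a 1 kb window centered on
    the TSS (promoter) or the DHS midpoint (enhancer).
    """
    elements: list[RegulatoryElement] = []
    promoter_hosts: set[GenomicInterval] = set()
    for chrom, pos in tss:
        host = next(
            (p for p in dhs if p.chrom == chrom and p.contains_point(pos)), None
        )
        if host is None:
            continue
        if not _any_contains_point(h3k27ac, chrom, pos):
            continue
        site = GenomicInterval(chrom, pos, pos + 1)
        elements.append(
            RegulatoryElement("promoter", site, _window_around(chrom, pos))
        )
        promoter_hosts.add(host)
    for peak in dhs:
        if peak in promoter_hosts:
            continue
        has_ac = any(reciprocal_overlap(peak, q, frac) for q in h3k27ac)
        has_me1 = any(reciprocal_overlap(peak, q, frac) for q in h3k4me1)
        if has_ac and has_me1:
            elements.append(
                RegulatoryElement("enhancer", peak, _window_around(peak.chrom, peak.center))
            )
    return elements


def _union(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))


def merge_loops(a: Sequence[Loop], b: Sequence[Loop], tol: int = 10_000) -> list[Loop]:
    """Merge two loop call sets: loops whose anchor midpoints both lie within
    ``tol`` bp collapse into one loop spanning the union of the anchors.
    Greedy nearest match per loop of ``a``; unmatched loops pass through."""
    merged: list[Loop] = []
    used = [False] * len(b)
    for la in a:
        best_j, best_d = -1, math.inf
        for j, lb in enumerate(b):
            if used[j] or la.chrom != lb.chrom:
                continue
            d1 = abs(la.anchor1.center - lb.anchor1.center)
            d2 = abs(la.anchor2.center - lb.anchor2.center)
            if d1 <= tol and d2 <= tol and d1 + d2 < best_d:
                best_j, best_d = j, d1 + d2
        if best_j >= 0:
            lb = b[best_j]
            used[best_j] = True
            merged.append(
                Loop(_union(la.anchor1, lb.anchor1), _union(la.anchor2, lb.anchor2), source="merged")
            )
        else:
            merged.append(replace(la, source=la.source))
    merged.extend(lb for j, lb in enumerate(b) if not used[j])
    return merged


def merge_domains(a: Sequence[Domain], b: Sequence[Domain], tol: int = 20_000) -> list[Domain]:
    """Merge two domain call sets: domains whose start borders differ by <= tol
    AND end borders differ by <= tol collapse into their union interval.
    Greedy nearest match, ties broken toward the smaller start."""
    merged: list[Domain] = []
    used = [False] * len(b)
    for da in a:
        best_j, best_key = -1, (math.inf, math.inf)
        for j, db in enumerate(b):
            if used[j] or da.interval.chrom != db.interval.chrom:
                continue
            ds = abs(da.interval.start - db.interval.start)
            de = abs(da.interval.end - db.interval.end)
            if ds <= tol and de <= tol and (ds + de, db.interval.start) < best_key:
                best_j, best_key = j, (ds + de, db.interval.start)
        if best_j >= 0:
            db = b[best_j]
            used[best_j] = True
            merged.append(Domain(_union(da.interval, db.interval), source="merged"))
        else:
            merged.append(Domain(da.interval, source=da.source))
    merged.extend(Domain(db.interval, source=db.source) for j, db in enumerate(b) if not used[j])
    return merged


def classify_domains(
    domains: Iterable[Domain], loops: Sequence[Loop], tol: int = 25_000
) -> list[Domain]:
    """Set klass='loop' on domains whose two boundaries are each within ``tol``
    of the two anchors of some single loop; otherwise 'compartmental'."""
    out: list[Domain] = []
    for d in domains:
        iv = d.interval
        is_loop = any(
            lp.chrom == iv.chrom
            and lp.anchor1.distance_to_point(iv.start) <= tol
            and lp.anchor2.distance_to_point(iv.end - 1) <= tol
            for lp in loops
        )
        out.append(Domain(iv, "loop" if is_loop else "compartmental", d.source))
    return out


def classify_loops(
    loops: Iterable[Loop], domains: Sequence[Domain], tol: int = 25_000
) -> list[Loop]:
    """Set klass on loops: 'boundary' if the anchors sit within ``tol`` of the
    two boundaries of one domain; 'intra_domain' if both anchors fall strictly
    inside a single domain (and not boundary); 'other' otherwise."""
    out: list[Loop] = []
    for lp in loops:
        klass = "other"
        for d in domains:
            iv = d.interval
            if iv.chrom != lp.chrom:
                continue
            if (
                lp.anchor1.distance_to_point(iv.start) <= tol
                and lp.anchor2.distance_to_point(iv.end - 1) <= tol
            ):
                klass = "boundary"
                break
        if klass != "boundary":
            for d in domains:
                iv = d.interval
                if (
                    iv.chrom == lp.chrom
                    and iv.start < lp.anchor1.start
                    and lp.anchor2.end < iv.end
                ):
                    klass = "intra_domain"
                    break
        out.append(Loop(lp.anchor1, lp.anchor2, klass, lp.source))
    return out
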