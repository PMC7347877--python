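"""Readers and writers for the flat text formats the pipeline consumes.

BED/BEDPE/bedGraph are 0-based half-open; GTF is 1-based inclusive and is
converted to 0-based half-open on read. Contact matrices travel as per-
chromosome tab-separated triples ``start_i<TAB>start_j<TAB>value`` with bin
left coordinates in bp and i <= j (juicer-dump style).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import Domain, GenomicInterval, Loop

__all__ = [
    "read_bed",
    "write_bed",
    "read_bed6",
    "write_bed6",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_gtf",
    "write_gtf",
    "GeneRecord",
    "StrandedFragment",
]

_BED_COLS = ["chrom", "start", "end"]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into intervals (extra columns ignored)."""
    df = _read_table(path, min_cols=3)
    if df.empty:
        return []
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df[0], df[1], df[2])
    ]


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return path


@dataclass(frozen=True)
class StrandedFragment:
    """A strand-specific sequencing fragment; five_prime is the 5'-most base."""

    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"fragment strand must be '+' or '-', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        # half-open: the 5'-most base of a minus-strand fragment is end - 1
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def read_bed6(path: str | Path) -> list[StrandedFragment]:
    df = _read_table(path, min_cols=6)
    if df.empty:
        return []
    return [
        StrandedFragment(GenomicInterval(str(c), int(s), int(e)), str(st))
        for c, s, e, st in zip(df[0], df[1], df[2], df[5])
    ]


def write_bed6(fragments: Iterable[StrandedFragment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for fr in fragments:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{fr.strand}\n")
    return path


def read_bedpe(path: str | Path) -> list[Loop]:
    df = _read_table(path, min_cols=6)
    if df.empty:
        return []
    return [
        Loop(
            GenomicInterval(str(c1), int(s1), int(e1)),
            GenomicInterval(str(c2), int(s2), int(e2)),
        )
        for c1, s1, e1, c2, s2, e2 in zip(df[0], df[1], df[2], df[3], df[4], df[5])
    ]


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t.\t0\t.\t.\n"
            )
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph into a frame (chrom, start, end, value),
    sorted, with overlapping segments rejected."""
    df = _read_table(path, min_cols=4)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "value"]
    df = df.astype({"start": int, "end": int, "value": float})
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for _, grp in df.groupby("chrom", sort=False):
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise ValueError(f"{path}: overlapping bedGraph segments")
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])
    return path


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with biotype; coordinates 0-based half-open, tss/tes are
    the transcription start/end positions respecting strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneRecord]:
    """Read gene features from a GTF (1-based inclusive -> 0-based half-open)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            genes.append(
                GeneRecord(
                    gene_id=attrs.get("gene_id", ""),
                    interval=GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4])),
                    strand=parts[6],
                    biotype=attrs.get("gene_biotype", ""),
                )
            )
    return genes


def write_gtf(genes: Iterable[GeneRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{iv.chrom}\tdomainweaver\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
    return path


def _read_table(path: str | Path, min_cols: int) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.shape[1] < min_cols:
        raise ValueError(f"{path}: expected >= {min_cols} tab-separated columns")
    return df


def domains_to_bed(domains: Sequence[Domain], path: str | Path) -> Path:
    return write_bed([d.interval for d in domains], path)


def bed_to_domains(path: str | Path, source: str = "merged") -> list[Domain]:
    return [Domain(iv, source=source) for iv in read_bed(path)]
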