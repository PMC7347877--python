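"""Two-condition synthetic dataset generator with known planted effects.

Emits, for a control and a knockout condition, everything the pipeline
consumes — peak sets, rpm signal tracks, strand-specific fragments, gene
annotation, and per-chromosome O/E KR contact matrices — together with a
TruthSet of planted per-domain accessibility and contact log2 fold-changes,
loop enrichments, and A/B compartment labels.

Matrices are generated directly as observed-over-expected, KR-balanced
values: background 1.0 with multiplicative log-normal noise, a uniform
within-domain enrichment, planted per-domain multiplicative fold-changes in
the knockout, and loop-pixel enrichment at boundary and intra-domain loops.
Raw counts and matrix balancing are not simulated; the analysis consumes O/E
values only.

Two DHS per domain sit in the domain's first and last matrix bin (mirroring
the CTCF/DHS anchoring of boundary loops), so every boundary-loop span has
intra-domain DHS pairs at the same distance; the remainder spread through
the interior.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hic import ContactMatrix, read_triples, write_triples
from .intervals import GenomicInterval
from .io import (
    GeneRecord,
    StrandedFragment,
    read_bed,
    read_bed6,
    read_bedgraph,
    read_gtf,
    write_bed,
    write_bed6,
    write_bedgraph,
    write_gtf,
)

__all__ = ["SimConfig", "TruthSet", "ConditionBundle", "generate_dataset",
           "write_bundle", "read_bundle", "null_config"]

ASSAYS = ("accessibility", "h3k27ac", "smc1")

# control-condition DHS peak amplitudes, rpm, per assay
_PEAK_AMP = {"accessibility": 5.0, "h3k27ac": 4.0, "smc1": 3.0}
_BASELINE = 0.05  # rpm outside peaks (non-H3K27ac assays)
_H3K27AC_BASE = {"A": 0.5, "B": 0.1}  # compartment-dependent H3K27ac floor
_DHS_WIDTH = 600
_CLASS_MARGIN = 0.05  # planted |log2FC| kept this far from the 0.585 band edge


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions."""

    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chrS1", 10_000_000), ("chrS2", 10_000_000)]
    )
    resolution_bp: int = 10_000
    n_domains: int = 30  # per chromosome
    domain_len_range: tuple[int, int] = (80_000, 300_000)
    frac_loop_domains: float = 0.35
    frac_intra_loops: float = 0.30  # domains carrying an interior loop
    class_probs: tuple[float, float, float] = (0.20, 0.765, 0.035)
    class_means: dict[str, float] = field(
        default_factory=lambda: {"increased": 1.0, "unchanged": 0.0, "decreased": -1.0}
    )
    class_sds: dict[str, float] = field(
        default_factory=lambda: {"increased": 0.25, "unchanged": 0.20, "decreased": 0.25}
    )
    contact_log2fc_slope: float = 0.8
    target_correlation: float | None = 0.6
    loop_enrichment: float = 3.0
    domain_enrichment: float = 2.0
    compartment_period_bp: int = 900_000
    eigen_resolution_bp: int = 150_000
    dhs_per_domain: int = 4
    frac_unmarked_dhs: float = 0.15  # DHS lacking H3K27ac/H3K4me1 (not enhancers)
    erna_mean_count: float = 50.0
    erna_dispersion: float = 0.02
    matrix_noise_sd: float = 0.06  # log2 units, multiplicative
    signal_noise_sd: float = 0.05  # log2 units, per replicate per DHS
    n_replicates: int = 2
    rng_seed: int = 7

    def validate(self) -> None:
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be > 0")
        if self.resolution_bp <= 0:
            raise ValueError("resolution must be > 0")
        if self.compartment_period_bp % self.resolution_bp:
            raise ValueError("resolution must divide the compartment block period")
        if self.compartment_period_bp % self.eigen_resolution_bp:
            raise ValueError("eigen bin size must divide the compartment block period")
        if self.loop_enrichment < 1:
            raise ValueError("loop enrichment factor must be >= 1")
        if self.target_correlation is not None and not (
            -1 <= self.target_correlation <= 1
        ):
            raise ValueError("target_correlation must be in [-1, 1]")
        lo, hi = self.domain_len_range
        if not (0 < lo <= hi):
            raise ValueError("invalid domain length range")
        if abs(sum(self.class_probs) - 1) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if self.dhs_per_domain < 2:
            raise ValueError("need >= 2 DHS per domain")


def null_config(**overrides) -> SimConfig:
    """A zero-effect configuration: all domains unchanged, no contact
    coupling, no loop enrichment."""
    cfg = SimConfig(
        class_probs=(0.0, 1.0, 0.0),
        contact_log2fc_slope=0.0,
        target_correlation=None,
        loop_enrichment=1.0,
        **overrides,
    )
    return cfg


@dataclass
class TruthSet:
    """Planted ground truth for every downstream stage."""

    domains: pd.DataFrame  # chrom,start,end,klass,acc_class,acc_log2fc,contact_log2fc
    loops: pd.DataFrame  # chrom,a1_start,a1_end,a2_start,a2_end,klass,enrichment
    compartments: pd.DataFrame  # chrom,start,end,label (eigen-resolution bins)


@dataclass
class ConditionBundle:
    """All per-condition files-in-memory for one condition."""

    condition: str
    peaks: dict[str, list[GenomicInterval]]  # dhs, h3k27ac, h3k4me1
    signal: dict[str, list[pd.DataFrame]]  # assay -> per-replicate bedGraph frames
    fragments: list[list[StrandedFragment]]  # per replicate
    matrices: dict[str, ContactMatrix]  # quantification resolution
    eigen_matrices: dict[str, ContactMatrix]  # eigen resolution
    genes: list[GeneRecord]


def _sample_class_fc(rng: np.random.Generator, klass: str, cfg: SimConfig) -> float:
    """Rejection-sample a planted log2FC inside its class band (kept a small
    margin from the band edge so zero-noise recovery is exact)."""
    mean, sd = cfg.class_means[klass], cfg.class_sds[klass]
    edge = 0.585
    for _ in range(10_000):
        x = mean + sd * rng.standard_normal() if sd > 0 else mean
        if klass == "increased" and x > edge + _CLASS_MARGIN:
            return x
        if klass == "decreased" and x < -edge - _CLASS_MARGIN:
            return x
        if klass == "unchanged" and abs(x) < edge - _CLASS_MARGIN:
            return x
    raise RuntimeError(f"cannot sample a log2FC in the {klass} band")


def _place_domains(
    rng: np.random.Generator, chrom_len: int, cfg: SimConfig
) -> list[tuple[int, int]]:
    """Non-overlapping bin-aligned domains with >= 3 bins spacing."""
    res = cfg.resolution_bp
    lo_bins = max(2, cfg.domain_len_range[0] // res)
    hi_bins = max(lo_bins, cfg.domain_len_range[1] // res)
    gap = 3
    lengths = rng.integers(lo_bins, hi_bins + 1, size=cfg.n_domains)
    n_bins = chrom_len // res
    needed = int(lengths.sum()) + gap * (cfg.n_domains + 1)
    slack = n_bins - needed
    if slack < 0:
        raise ValueError(
            f"cannot place {cfg.n_domains} domains of {lo_bins}-{hi_bins} bins "
            f"in {n_bins} bins without overlap"
        )
    # distribute the slack randomly over the n_domains + 1 gaps
    extra = rng.multinomial(slack, np.ones(cfg.n_domains + 1) / (cfg.n_domains + 1))
    domains = []
    cursor = gap + int(extra[0])
    for k in range(cfg.n_domains):
        start = cursor
        end = start + int(lengths[k])
        domains.append((start * res, end * res))
        cursor = end + gap + int(extra[k + 1])
    return domains


def _dhs_positions(start: int, end: int, cfg: SimConfig) -> list[int]:
    """DHS centers: one in the first bin, one in the last bin, the rest spread
    over the interior."""
    res = cfg.resolution_bp
    pos = [start + res // 2, end - res // 2]
    n_inner = cfg.dhs_per_domain - 2
    length = end - start
    for k in range(n_inner):
        frac = (k + 1) / (n_inner + 1)
        p = start + int(round(frac * length))
        pos.append(p)
    return sorted(pos)


def _compartment_labels(chrom_len: int, cfg: SimConfig) -> pd.DataFrame:
    res = cfg.eigen_resolution_bp
    n = chrom_len // res
    period_bins = cfg.compartment_period_bp // res
    half = period_bins // 2
    rows = []
    for b in range(n):
        label = "A" if (b // half) % 2 == 0 else "B"
        rows.append((b * res, (b + 1) * res, label))
    return pd.DataFrame(rows, columns=["start", "end", "label"])


def _noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp2(sd * rng.standard_normal(shape))


def _build_matrix(
    rng: np.random.Generator,
    chrom: str,
    n_bins: int,
    res: int,
    domain_rows: list[dict],
    loop_pixels: list[tuple[int, int, float]],
    cfg: SimConfig,
    knockout: bool,
) -> ContactMatrix:
    base = np.ones((n_bins, n_bins))
    for d in domain_rows:
        lo, hi = d["start"] // res, d["end"] // res
        base[lo:hi, lo:hi] *= cfg.domain_enrichment
        if knockout:
            base[lo:hi, lo:hi] *= 2.0 ** d["contact_log2fc"]
    for bi, bj, enr in loop_pixels:
        base[bi, bj] *= enr
    base *= _noise(rng, base.shape, cfg.matrix_noise_sd)
    upper = np.triu(base)
    return ContactMatrix(chrom, res, sp.csr_matrix(upper))


def _build_eigen_matrix(
    rng: np.random.Generator, chrom: str, labels: pd.DataFrame, cfg: SimConfig
) -> ContactMatrix:
    lab = (labels["label"] == "A").to_numpy()
    n = len(lab)
    same = lab[:, None] == lab[None, :]
    base = np.where(same, 1.6, 0.5)
    base = base * _noise(rng, base.shape, cfg.matrix_noise_sd)
    upper = np.triu(base)
    return ContactMatrix(chrom, cfg.eigen_resolution_bp, sp.csr_matrix(upper))


def _signal_frames(
    rng: np.random.Generator,
    chrom_order: list[str],
    chrom_lens: dict[str, int],
    dhs_rows: list[dict],
    compartments: dict[str, pd.DataFrame],
    assay: str,
    condition: str,
    cfg: SimConfig,
) -> list[pd.DataFrame]:
    """Per-replicate bedGraph frames: a flat (or compartment-dependent)
    baseline with 1 kb peak plateaus at DHS centers."""
    frames = []
    for _ in range(cfg.n_replicates):
        rows = []
        for chrom in chrom_order:
            peaks = []
            for d in dhs_rows:
                if d["chrom"] != chrom:
                    continue
                amp = _PEAK_AMP[assay]
                if condition == "cko":
                    amp *= 2.0 ** d["acc_log2fc"]
                amp *= float(_noise(rng, (), cfg.signal_noise_sd))
                c = d["center"]
                peaks.append((c - 500, c + 500, amp))
            peaks.sort()
            if assay == "h3k27ac":
                baseline = [
                    (int(r.start), int(r.end), _H3K27AC_BASE[r.label])
                    for r in compartments[chrom].itertuples(index=False)
                ]
            else:
                baseline = [(0, chrom_lens[chrom], _BASELINE)]
            rows.extend(
                (chrom, s, e, v)
                for s, e, v in _overlay(baseline, peaks)
            )
        frames.append(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))
    return frames


def _overlay(
    baseline: list[tuple[int, int, float]], peaks: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Overlay peak plateaus on a baseline segmentation (peaks replace the
    baseline where they fall; peaks must not overlap each other)."""
    out: list[tuple[int, int, float]] = []
    pi = 0
    for bs, be, bv in baseline:
        cursor = bs
        while pi < len(peaks) and peaks[pi][1] <= cursor:
            pi += 1
        k = pi
        while k < len(peaks) and peaks[k][0] < be:
            ps, pe, pv = peaks[k]
            if ps > cursor:
                out.append((cursor, ps, bv))
            out.append((max(ps, cursor), min(pe, be), pv))
            cursor = min(pe, be)
            k += 1
        if cursor < be:
            out.append((cursor, be, bv))
    # merge zero-length and join abutting equal-valued segments
    merged = [seg for seg in out if seg[1] > seg[0]]
    return merged


def generate_dataset(
    cfg: SimConfig,
) -> tuple[ConditionBundle, ConditionBundle, TruthSet]:
    """Generate the full two-condition dataset plus its TruthSet.

    Identical config (including seed) reproduces identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    res = cfg.resolution_bp
    chrom_order = [c for c, _ in cfg.genome]
    chrom_lens = dict(cfg.genome)

    domain_rows: list[dict] = []
    loop_rows: list[dict] = []
    dhs_rows: list[dict] = []
    compartments: dict[str, pd.DataFrame] = {}
    for chrom, length in cfg.genome:
        comp = _compartment_labels(length, cfg)
        comp.insert(0, "chrom", chrom)
        compartments[chrom] = comp
        for start, end in _place_domains(rng, length, cfg):
            klass = "loop" if rng.random() < cfg.frac_loop_domains else "compartmental"
            acc_class = ["increased", "unchanged", "decreased"][
                int(rng.choice(3, p=cfg.class_probs))
            ]
            acc_fc = _sample_class_fc(rng, acc_class, cfg)
            domain_rows.append(
                dict(chrom=chrom, start=start, end=end, klass=klass,
                     acc_class=acc_class, acc_log2fc=acc_fc, contact_log2fc=0.0)
            )
            for c in _dhs_positions(start, end, cfg):
                marked = rng.random() >= cfg.frac_unmarked_dhs
                dhs_rows.append(
                    dict(chrom=chrom, center=c, acc_log2fc=acc_fc, marked=marked,
                         domain=(chrom, start, end))
                )
            if klass == "loop":
                loop_rows.append(
                    dict(chrom=chrom, a1_start=start, a1_end=start + res,
                         a2_start=end - res, a2_end=end, klass="boundary",
                         enrichment=cfg.loop_enrichment)
                )
            if rng.random() < cfg.frac_intra_loops and end - start >= 8 * res:
                nb = (end - start) // res
                o1, o2 = max(2, round(0.3 * nb)), min(nb - 3, round(0.7 * nb))
                if o2 > o1:
                    loop_rows.append(
                        dict(chrom=chrom, a1_start=start + o1 * res,
                             a1_end=start + (o1 + 1) * res,
                             a2_start=start + o2 * res,
                             a2_end=start + (o2 + 1) * res,
                             klass="intra_domain", enrichment=cfg.loop_enrichment)
                    )

    # planted contact log2FC: linear coupling to accessibility plus noise whose
    # sd is derived from the target Pearson correlation
    acc = np.array([d["acc_log2fc"] for d in domain_rows])
    slope = cfg.contact_log2fc_slope
    if slope == 0 or cfg.target_correlation is None:
        contact = slope * acc
    else:
        r = cfg.target_correlation
        if abs(r) < 1e-9:
            raise ValueError("target_correlation of 0 with nonzero slope is undefined")
        sd_noise = abs(slope) * float(np.std(acc)) * math.sqrt(1 / r**2 - 1)
        contact = slope * acc + sd_noise * rng.standard_normal(len(acc))
    for d, cfc in zip(domain_rows, contact):
        d["contact_log2fc"] = float(cfc)

    genes = _place_genes(domain_rows, chrom_order, chrom_lens)

    # peak sets (identical interval lists in both conditions)
    dhs_peaks = [
        GenomicInterval(d["chrom"], d["center"] - _DHS_WIDTH // 2,
                        d["center"] + _DHS_WIDTH // 2)
        for d in dhs_rows
    ]
    ac_peaks = [
        GenomicInterval(d["chrom"], d["center"] - 500, d["center"] + 500)
        for d in dhs_rows if d["marked"]
    ]
    me1_peaks = [
        GenomicInterval(d["chrom"], d["center"] - 600, d["center"] + 600)
        for d in dhs_rows if d["marked"]
    ]
    peaks = {"dhs": dhs_peaks, "h3k27ac": ac_peaks, "h3k4me1": me1_peaks}

    bundles = {}
    for condition in ("ctrl", "cko"):
        signal = {
            assay: _signal_frames(rng, chrom_order, chrom_lens, dhs_rows,
                                  compartments, assay, condition, cfg)
            for assay in ASSAYS
        }
        matrices = {}
        eigen_matrices = {}
        for chrom, length in cfg.genome:
            d_chr = [d for d in domain_rows if d["chrom"] == chrom]
            lp_chr = [
                (lp["a1_start"] // res, lp["a2_start"] // res, lp["enrichment"])
                for lp in loop_rows if lp["chrom"] == chrom
            ]
            matrices[chrom] = _build_matrix(
                rng, chrom, length // res, res, d_chr, lp_chr, cfg,
                knockout=(condition == "cko"),
            )
            eigen_matrices[chrom] = _build_eigen_matrix(
                rng, chrom, compartments[chrom], cfg
            )
        fragments = _erna_fragments(rng, dhs_rows, chrom_lens, cfg, condition)
        bundles[condition] = ConditionBundle(
            condition=condition, peaks=peaks, signal=signal,
            fragments=fragments, matrices=matrices,
            eigen_matrices=eigen_matrices, genes=genes,
        )

    truth = TruthSet(
        domains=pd.DataFrame(domain_rows)[
            ["chrom", "start", "end", "klass", "acc_class", "acc_log2fc",
             "contact_log2fc"]
        ],
        loops=pd.DataFrame(
            loop_rows,
            columns=["chrom", "a1_start", "a1_end", "a2_start", "a2_end",
                     "klass", "enrichment"],
        ),
        compartments=pd.concat(compartments.values(), ignore_index=True),
    )
    return bundles["ctrl"], bundles["cko"], truth


def _place_genes(
    domain_rows: list[dict], chrom_order: list[str], chrom_lens: dict[str, int]
) -> list[GeneRecord]:
    """A few coding genes and one lncRNA per chromosome, in inter-domain gaps
    so the default dataset keeps every eRNA feature."""
    genes = []
    k = 0
    for chrom in chrom_order:
        bounds = sorted(
            (d["start"], d["end"]) for d in domain_rows if d["chrom"] == chrom
        )
        gaps = []
        prev = 0
        for s, e in bounds:
            if s - prev >= 14_000:
                gaps.append((prev, s))
            prev = e
        if chrom_lens[chrom] - prev >= 14_000:
            gaps.append((prev, chrom_lens[chrom]))
        for g, (gs, ge) in enumerate(gaps[:4]):
            mid = (gs + ge) // 2
            iv = GenomicInterval(chrom, mid - 4000, mid + 4000)
            biotype = "lncRNA" if g == 3 else "protein_coding"
            strand = "+" if g % 2 == 0 else "-"
            genes.append(GeneRecord(f"gene{k}", iv, strand, biotype))
            k += 1
    return genes


def _erna_fragments(
    rng: np.random.Generator,
    dhs_rows: list[dict],
    chrom_lens: dict[str, int],
    cfg: SimConfig,
    condition: str,
) -> list[list[StrandedFragment]]:
    """Negative-binomial per-window per-replicate fragment counts at marked
    (enhancer) DHS, knockout means scaled by the host domain's planted
    accessibility fold-change."""
    frag_len = 100
    reps: list[list[StrandedFragment]] = []
    disp = cfg.erna_dispersion
    nb_n = 1.0 / disp if disp > 0 else None
    for _ in range(cfg.n_replicates):
        frags: list[StrandedFragment] = []
        for d in dhs_rows:
            if not d["marked"]:
                continue
            mu = cfg.erna_mean_count
            if condition == "cko":
                mu *= 2.0 ** d["acc_log2fc"]
            for strand in ("-", "+"):
                if nb_n is None:
                    count = int(rng.poisson(mu))
                else:
                    p = nb_n / (nb_n + mu)
                    count = int(rng.negative_binomial(nb_n, p))
                c = d["center"]
                lo, hi = (c - 2000, c) if strand == "-" else (c, c + 2000)
                p5s = rng.integers(lo, hi, size=count)
                for p5 in p5s:
                    if strand == "+":
                        iv = GenomicInterval(
                            d["chrom"], int(p5),
                            min(int(p5) + frag_len, chrom_lens[d["chrom"]]),
                        )
                    else:
                        iv = GenomicInterval(
                            d["chrom"], max(0, int(p5) - frag_len + 1), int(p5) + 1
                        )
                    frags.append(StrandedFragment(iv, strand))
        reps.append(frags)
    return reps


# ---------------------------------------------------------------------------
# bundle serialization

def write_bundle(bundle: ConditionBundle, directory: str | Path) -> dict[str, Path]:
    """Write a condition bundle to a directory; returns the path map. The
    pipeline's readers round-trip every file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, ivs in bundle.peaks.items():
        paths[f"peaks_{name}"] = write_bed(ivs, directory / f"peaks_{name}.bed")
    for assay, frames in bundle.signal.items():
        for r, df in enumerate(frames, start=1):
            key = f"signal_{assay}_rep{r}"
            paths[key] = write_bedgraph(df, directory / f"{key}.bedgraph")
    for r, frags in enumerate(bundle.fragments, start=1):
        key = f"fragments_rep{r}"
        paths[key] = write_bed6(frags, directory / f"{key}.bed")
    for chrom, cm in bundle.matrices.items():
        key = f"matrix_{chrom}"
        paths[key] = write_triples(cm, directory / f"{key}.txt")
    for chrom, cm in bundle.eigen_matrices.items():
        key = f"eigen_matrix_{chrom}"
        paths[key] = write_triples(cm, directory / f"{key}.txt")
    paths["genes"] = write_gtf(bundle.genes, directory / "genes.gtf")
    return paths


def read_bundle(
    directory: str | Path,
    condition: str,
    genome: list[tuple[str, int]],
    resolution: int,
    eigen_resolution: int,
    n_replicates: int,
) -> ConditionBundle:
    """Read a bundle previously written by write_bundle."""
    directory = Path(directory)
    peaks = {
        name: read_bed(directory / f"peaks_{name}.bed")
        for name in ("dhs", "h3k27ac", "h3k4me1")
    }
    signal = {
        assay: [
            read_bedgraph(directory / f"signal_{assay}_rep{r}.bedgraph")
            for r in range(1, n_replicates + 1)
        ]
        for assay in ASSAYS
    }
    fragments = [
        read_bed6(directory / f"fragments_rep{r}.bed")
        for r in range(1, n_replicates + 1)
    ]
    matrices = {
        chrom: read_triples(directory / f"matrix_{chrom}.txt", resolution, chrom)
        for chrom, _ in genome
    }
    eigen_matrices = {
        chrom: read_triples(
            directory / f"eigen_matrix_{chrom}.txt", eigen_resolution, chrom
        )
        for chrom, _ in genome
    }
    genes = read_gtf(directory / "genes.gtf")
    return ConditionBundle(
        condition=condition, peaks=peaks, signal=signal, fragments=fragments,
        matrices=matrices, eigen_matrices=eigen_matrices, genes=genes,
    )
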