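"""End-to-end orchestration: merge and classify architecture calls, quantify
signal and contacts per domain and loop, eRNA fold-changes, the compartment
eigenvector, the distance-controlled resampling test, and summary tables.

Every threshold lives in PipelineParams with the analysis defaults: 25%
reciprocal overlap, 10/20/25 kb merge/classification tolerances, the 0.585
accessibility band, 1 kb element windows, 2 kb eRNA windows with 1 kb gene
extension, the 10-count eRNA filter, 150 kb eigenvector bins, 10 kb
quantification resolution, and 100 resamples.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erna as erna_mod
from . import hic, quant, resampling
from .intervals import Domain, GenomicInterval, Loop, classify_domains, classify_elements, classify_loops, merge_domains, merge_loops
from .simulate import ConditionBundle, TruthSet

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineReport", "run_pipeline", "summarize_by_class",
           "bin_track"]


@dataclass
class PipelineParams:
    """All analysis constants in one place (units: bp unless noted)."""

    reciprocal_frac: float = 0.25
    loop_merge_tol: int = 10_000
    domain_merge_tol: int = 20_000
    class_tol: int = 25_000
    acc_threshold: float = 0.585  # log2FC band edge
    element_window: int = 1_000
    erna_min_count: int = 10
    resolution: int = 10_000
    eigen_resolution: int = 150_000
    apa_window_bins: int = 10
    n_resamples: int = 100
    pseudocount_rpm: float = 0.1
    pseudocount_oe: float = 1e-3
    seed: int = 7

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name != "seed" and not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"parameter {name} must be positive, got {v!r}")


@dataclass
class PipelineReport:
    domains: pd.DataFrame
    loops: pd.DataFrame
    erna: pd.DataFrame
    correlations: pd.DataFrame
    class_summary: pd.DataFrame
    resampling: resampling.ResamplingResult | None
    apa: dict | None
    counts: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.domains.to_csv(outdir / "domains.tsv", sep="\t", index=False)
        self.loops.to_csv(outdir / "loops.tsv", sep="\t", index=False)
        self.erna.to_csv(outdir / "erna.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        self.class_summary.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
        payload = {"counts": self.counts}
        if self.resampling is not None:
            payload["resampling"] = {
                "test_median": self.resampling.test_median,
                "resampled_medians": self.resampling.resampled_medians.tolist(),
                "empirical_p": self.resampling.empirical_p,
                "empirical_p_text": self.resampling.p_text(),
                "seed": self.resampling.seed,
                "bin_scheme": "log2-width distance bins",
            }
        if self.apa is not None:
            payload["apa"] = {
                k: v for k, v in self.apa.items() if not isinstance(v, np.ndarray)
            }
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)


def bin_track(track: quant.SignalTrack, chrom: str, chrom_len: int,
              resolution: int) -> np.ndarray:
    """Mean signal per fixed-size bin along a chromosome."""
    n = chrom_len // resolution
    return np.array([
        track.mean_over(GenomicInterval(chrom, b * resolution, (b + 1) * resolution))
        for b in range(n)
    ])


def summarize_by_class(
    table: pd.DataFrame, value_col: str, class_col: str = "acc_class"
) -> pd.DataFrame:
    """Per-class n, median, and quartiles of one value column."""
    rows = []
    for klass in ("increased", "unchanged", "decreased"):
        sub = table.loc[table[class_col] == klass, value_col].dropna()
        rows.append({
            "class": klass,
            "n": int((table[class_col] == klass).sum()),
            "median": float(sub.median()) if len(sub) else float("nan"),
            "q25": float(sub.quantile(0.25)) if len(sub) else float("nan"),
            "q75": float(sub.quantile(0.75)) if len(sub) else float("nan"),
        })
    return pd.DataFrame(rows)


def _tracks(bundle: ConditionBundle, assay: str) -> list[quant.SignalTrack]:
    return [quant.SignalTrack(df) for df in bundle.signal[assay]]


def run_pipeline(
    ctrl: ConditionBundle,
    cko: ConditionBundle,
    domain_calls: dict[str, list[Domain]],
    loop_calls: dict[str, list[Loop]],
    params: PipelineParams | None = None,
) -> PipelineReport:
    """Run the full analysis on two condition bundles plus per-condition
    domain and loop call sets (calls are inputs; they are merged across
    conditions, classified, then quantified)."""
    p = params or PipelineParams()
    p.validate()
    counts: dict[str, int] = {}

    # --- architecture: merge per-condition calls, then cross-classify
    domains = merge_domains(
        domain_calls["ctrl"], domain_calls["cko"], tol=p.domain_merge_tol
    )
    loops = merge_loops(loop_calls["ctrl"], loop_calls["cko"], tol=p.loop_merge_tol)
    counts["domains_ctrl"] = len(domain_calls["ctrl"])
    counts["domains_cko"] = len(domain_calls["cko"])
    counts["domains_merged"] = len(domains)
    counts["loops_ctrl"] = len(loop_calls["ctrl"])
    counts["loops_cko"] = len(loop_calls["cko"])
    counts["loops_merged"] = len(loops)
    domains = classify_domains(domains, loops, tol=p.class_tol)
    loops = classify_loops(loops, domains, tol=p.class_tol)
    counts["loop_domains"] = sum(d.klass == "loop" for d in domains)
    counts["compartmental_domains"] = sum(d.klass == "compartmental" for d in domains)

    # --- regulatory elements
    tss = [(g.interval.chrom, g.tss) for g in ctrl.genes]
    elements = classify_elements(
        ctrl.peaks["dhs"], ctrl.peaks["h3k27ac"], ctrl.peaks["h3k4me1"], tss,
        frac=p.reciprocal_frac,
    )
    enhancers = [e for e in elements if e.kind == "enhancer"]
    counts["promoters"] = sum(e.kind == "promoter" for e in elements)
    counts["enhancers"] = len(enhancers)

    # DHS quantification windows (1 kb on the peak center)
    dhs_windows = []
    for peak in ctrl.peaks["dhs"]:
        half = p.element_window // 2
        c = peak.center
        dhs_windows.append(GenomicInterval(peak.chrom, c - half, c + half))

    # --- per-domain signal + contacts + eigenvalue
    assay_tracks = {
        cond.condition: {a: _tracks(cond, a) for a in cond.signal}
        for cond in (ctrl, cko)
    }
    eigen_tracks = {}
    for cond in (ctrl, cko):
        eigen_tracks[cond.condition] = {}
        for chrom, cm in cond.eigen_matrices.items():
            chrom_len = cm.n_bins * cm.resolution
            ac = bin_track(assay_tracks[cond.condition]["h3k27ac"][0], chrom,
                           chrom_len, p.eigen_resolution)
            eigen_tracks[cond.condition][chrom] = hic.compartment_eigenvector(cm, ac)

    rows = []
    for d in domains:
        row: dict = {
            "chrom": d.interval.chrom, "start": d.interval.start,
            "end": d.interval.end, "klass": d.klass,
        }
        for assay in ("accessibility", "h3k27ac", "smc1"):
            v_ctrl = quant.domain_signal(d, dhs_windows, assay_tracks["ctrl"][assay])
            v_cko = quant.domain_signal(d, dhs_windows, assay_tracks["cko"][assay])
            row[f"{assay}_ctrl"] = v_ctrl
            row[f"{assay}_cko"] = v_cko
            row[f"{assay}_log2fc"] = (
                quant.log2_change(v_cko, v_ctrl, p.pseudocount_rpm)
                if np.isfinite(v_ctrl) and np.isfinite(v_cko) else float("nan")
            )
        acc_fc = row["accessibility_log2fc"]
        row["acc_class"] = (
            quant.classify_accessibility(acc_fc, p.acc_threshold)
            if np.isfinite(acc_fc) else "unscored"
        )
        mc = ctrl.matrices[d.interval.chrom]
        mk = cko.matrices[d.interval.chrom]
        c_ctrl = hic.domain_contacts(mc, d)
        c_cko = hic.domain_contacts(mk, d)
        row["contacts_ctrl"] = c_ctrl
        row["contacts_cko"] = c_cko
        row["contacts_log2fc"] = quant.log2_change(c_cko, c_ctrl, p.pseudocount_oe)
        for cond_name in ("ctrl", "cko"):
            row[f"eigen_{cond_name}"] = hic.domain_eigenvalue(
                eigen_tracks[cond_name][d.interval.chrom], d
            )
        row["eigen_delta"] = row["eigen_cko"] - row["eigen_ctrl"]
        rows.append(row)
    domain_table = pd.DataFrame(rows)
    counts["domains_scored"] = int(
        (domain_table["acc_class"] != "unscored").sum()
    )

    # --- per-loop contacts
    lrows = []
    for lp in loops:
        mc = ctrl.matrices[lp.chrom]
        mk = cko.matrices[lp.chrom]
        v_ctrl = hic.loop_contacts(mc, lp)
        v_cko = hic.loop_contacts(mk, lp)
        lrows.append({
            "chrom": lp.chrom,
            "a1_start": lp.anchor1.start, "a1_end": lp.anchor1.end,
            "a2_start": lp.anchor2.start, "a2_end": lp.anchor2.end,
            "klass": lp.klass, "contacts_ctrl": v_ctrl, "contacts_cko": v_cko,
            "contacts_log2fc": quant.log2_change(v_cko, v_ctrl, p.pseudocount_oe),
        })
    loop_table = pd.DataFrame(lrows)

    # --- APA, pooled over chromosomes (loops too close to the diagonal or
    # edge for the window are skipped inside hic.apa)
    apa_out = None
    agg = {"ctrl": None, "cko": None}
    used = skipped = 0
    w = p.apa_window_bins
    for chrom in ctrl.matrices:
        chrom_loops = [lp for lp in loops if lp.chrom == chrom]
        if not chrom_loops:
            continue
        try:
            res_ctrl, res_cko = hic.apa(
                ctrl.matrices[chrom], cko.matrices[chrom], chrom_loops, w=w
            )
        except ValueError as exc:
            log.info("APA skipped on %s: %s", chrom, exc)
            continue
        for name, res in (("ctrl", res_ctrl), ("cko", res_cko)):
            part = res.aggregate * res.n_loops_used
            agg[name] = part if agg[name] is None else agg[name] + part
        used += res_ctrl.n_loops_used
        skipped += res_ctrl.n_loops_skipped
    if used:
        c = -(-w // 2)
        apa_out = {"n_loops_used": used, "n_loops_skipped": skipped}
        for name in ("ctrl", "cko"):
            a = agg[name] / used
            apa_out[f"aggregate_{name}"] = a
            apa_out[f"p2ll_{name}"] = float(a[w, w] / a[-c:, :c].mean())

    # --- eRNA
    features = erna_mod.build_erna_features(ctrl.peaks["dhs"], enhancers, ctrl.genes)
    counts["erna_features_built"] = len(features)
    features = erna_mod.count_fragments(
        features, {"ctrl": ctrl.fragments, "cko": cko.fragments}
    )
    features = erna_mod.filter_low(features, min_total=p.erna_min_count)
    counts["erna_features_retained"] = len(features)
    if features:
        fcs = erna_mod.erna_log2fc(features)
        erna_table = pd.DataFrame({
            "chrom": [f.chrom for f in features],
            "dhs_center": [f.dhs_center for f in features],
            "total_count": [f.total_count() for f in features],
            "log2fc": fcs,
        })
    else:
        erna_table = pd.DataFrame(
            columns=["chrom", "dhs_center", "total_count", "log2fc"]
        )

    # --- distance-controlled resampling: boundary loops of increased domains
    # vs intra-domain DHS pairs of increased domains
    resamp = None
    increased = [
        Domain(GenomicInterval(r.chrom, r.start, r.end), r.klass)
        for r in domain_table.itertuples(index=False) if r.acc_class == "increased"
    ]
    test_loops = [
        lp for lp in loops if lp.klass == "boundary" and any(
            d.interval.chrom == lp.chrom
            and lp.anchor1.distance_to_point(d.interval.start) <= p.class_tol
            and lp.anchor2.distance_to_point(d.interval.end - 1) <= p.class_tol
            for d in increased
        )
    ]
    counts["resampling_test_loops"] = len(test_loops)
    if test_loops and increased:
        test_pairs = pd.DataFrame({
            "chrom": [lp.chrom for lp in test_loops],
            "pos_a": [lp.anchor1.center for lp in test_loops],
            "pos_b": [lp.anchor2.center for lp in test_loops],
        })
        test_pairs["distance"] = test_pairs["pos_b"] - test_pairs["pos_a"]
        test_set = resampling.pair_log2fc(
            resampling.PairSet(test_pairs), ctrl.matrices, cko.matrices,
            pseudocount=p.pseudocount_oe,
        )
        candidates = resampling.enumerate_candidate_pairs(
            increased, ctrl.peaks["dhs"]
        )
        counts["resampling_candidate_pairs"] = len(candidates)
        if len(candidates):
            candidates = resampling.pair_log2fc(
                candidates, ctrl.matrices, cko.matrices,
                pseudocount=p.pseudocount_oe,
            )
            resamp = resampling.resampling_test(
                test_set, candidates, n=p.n_resamples, seed=p.seed
            )
    else:
        log.info("resampling skipped: no increased loop-domain boundary loops")

    # --- correlation panel (domain-level changes, Pearson and Spearman)
    corr_rows = []
    finite = domain_table.dropna(subset=["contacts_log2fc"])
    for col in ("accessibility_log2fc", "h3k27ac_log2fc", "smc1_log2fc"):
        sub = finite.dropna(subset=[col])
        for method in ("pearson", "spearman"):
            try:
                r, pv = quant.correlate(
                    sub[col], sub["contacts_log2fc"], method=method
                )
            except ValueError:
                r, pv = float("nan"), float("nan")
            corr_rows.append({"x": col, "y": "contacts_log2fc",
                              "method": method, "r": r, "p": pv})
    sub = domain_table.dropna(subset=["eigen_delta", "contacts_log2fc"])
    try:
        r, pv = quant.correlate(sub["eigen_delta"], sub["contacts_log2fc"],
                                method="spearman")
    except ValueError:
        r, pv = float("nan"), float("nan")
    corr_rows.append({"x": "eigen_delta", "y": "contacts_log2fc",
                      "method": "spearman", "r": r, "p": pv})
    correlations = pd.DataFrame(corr_rows)

    class_summary = summarize_by_class(domain_table, "contacts_log2fc")

    return PipelineReport(
        domains=domain_table, loops=loop_table, erna=erna_table,
        correlations=correlations, class_summary=class_summary,
        resampling=resamp, apa=apa_out, counts=counts,
    )


def truth_calls(truth: TruthSet) -> tuple[dict[str, list[Domain]], dict[str, list[Loop]]]:
    """Treat the planted truth architecture as the per-condition call sets
    (calls are pipeline inputs; the synthetic generator plants one shared
    architecture for both conditions)."""
    domains = [
        Domain(GenomicInterval(r.chrom, int(r.start), int(r.end)), source="control")
        for r in truth.domains.itertuples(index=False)
    ]
    loops = [
        Loop(
            GenomicInterval(r.chrom, int(r.a1_start), int(r.a1_end)),
            GenomicInterval(r.chrom, int(r.a2_start), int(r.a2_end)),
            source="control",
        )
        for r in truth.loops.itertuples(index=False)
    ]
    return (
        {"ctrl": domains, "cko": [Domain(d.interval, source="cko") for d in domains]},
        {"ctrl": loops, "cko": [Loop(l.anchor1, l.anchor2, source="cko") for l in loops]},
    )
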