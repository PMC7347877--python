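# Methods

`domainweaver` implements a two-condition (control vs knockout) integration
of chromatin architecture and epigenome data: it quantifies how contact-domain
interactions, loop strength, and A/B compartmentalization change together with
regulatory-element accessibility, histone acetylation, cohesin binding, and
enhancer-RNA output, and tests whether boundary-loop interactions change
differently from matched intra-domain contacts. This note documents the model
behind each stage, the tunable parameters, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
open.

## Coordinate and unit conventions

All intervals are 0-based half-open (BED); GTF is converted on read. Signal
is depth-normalized coverage in reads per million (rpm). Contact values are
observed-over-expected (O/E), Knight–Ruiz-balanced contacts, so 1.0 is the
distance-decay background; absent sparse entries are zeros, consistent with
O/E dumps that omit empty pixels. "Within N kb" tolerances are inclusive
(≤ N), since domain and loop calls are bin-aligned and an exclusive rule
would drop exact-boundary matches.

## Architecture: merging and classification

Per-condition contact-domain calls are merged when both borders lie within
20 kb; loop calls are merged when both anchor midpoints lie within 10 kb
(midpoints are used because the reference point inside an anchor is
otherwise ambiguous, and midpoints are symmetric). Matching is greedy
nearest-first with ties broken toward the smaller start; merged records take
the union interval. A merged domain is a **loop domain** when some single
loop places its two anchors within 25 kb of the domain's two boundaries
(distance from the boundary point to the nearest base of the anchor, 0 if
inside), otherwise **compartmental**. A loop is a **boundary** loop when it
anchors the two boundaries of one domain, **intra-domain** when both anchors
fall strictly inside a single domain, and **other** otherwise. These three
rules partition both sets exhaustively on every input.

## Regulatory elements

Active promoters are TSS positions lying inside both a DNaseI peak and an
H3K27ac peak; the TSS is a point, so point containment is used rather than
the 25% rule. Active enhancers are DNaseI peaks reciprocally overlapping
(≥ 25% of both intervals, bedtools `-f 0.25 -r` semantics) an H3K27ac and an
H3K4me1 peak. Each element carries a 1,000 bp quantification window centered
on the TSS or the DHS midpoint (floor division for odd lengths); "1 kb
around" is read as a 1 kb total window (±500 bp).

## Signal quantification and accessibility classes

`window_signal` is the length-weighted mean of a piecewise-constant rpm
track over a window, with biological replicates averaged with equal weight
before fold-changes. Domain-level signal is the unweighted mean over all DHS
windows whose center lies inside the domain (center containment avoids
double-counting boundary-straddling DHS); a domain without DHS is flagged
missing rather than zero. Fold-changes are log2((KO + c)/(ctrl + c)) with a
pseudocount c = 0.1 rpm — small against typical peak signal (several rpm)
and guarding empty windows. Domains are classed by accessibility log2FC as
increased (> 0.585), decreased (< −0.585), or unchanged (the open band
between, i.e. within 1.5-fold); band edges fall in "unchanged" because the
inequalities are strict.

## Contact-matrix statistics

Quantification uses 10 kb bins. Domain contacts are the mean O/E over all
off-diagonal bin pairs fully inside the domain; the diagonal is excluded
because self-bin signal is not an interaction. Loop contacts are the mean
over the rectangle of anchor-1 bins × anchor-2 bins. Boundary insulation in
a window of L bins (the domain length) on each side of a boundary b is
−log2((crossing + ε)/(total + ε)) with ε = 1e−6, where crossing sums pairs
i < b ≤ j and total sums all pairs i < j in the window; on a uniform matrix
this reduces to −log2(L/(2L−1)), e.g. 0.585 at L = 2, which the tests verify
by enumeration for L = 1..10.

Aggregate peak analysis (APA) averages the (2w+1)×(2w+1) O/E submatrix
centered on each loop's anchor-midpoint pixel (default w = 10 bins); loops
whose window would touch the diagonal or matrix edge are skipped and
counted. P2LL divides the aggregate center by the mean of its ⌈w/2⌉-sized
lower-left corner box — the near-diagonal corner (larger anchor-1
coordinate, smaller anchor-2 coordinate), following the usual
aggregate-peak-analysis convention.

The A/B compartment eigenvector is computed at 150 kb from the Pearson
correlation matrix of the O/E map after dropping bins with zero marginal
contact sum (reported as missing); the leading eigenvector is the one with
the largest absolute eigenvalue, its sign oriented so that positive entries
correlate positively with per-bin H3K27ac (ties in degenerate spectra break
toward positive H3K27ac correlation). Output is invariant to uniform matrix
scaling. A domain's eigenvalue is the mean over the 150 kb bins it overlaps
(any overlap counts, missing bins excluded).

## Enhancer RNA

Each enhancer-overlapping DHS center defines a bidirectional feature: a
2 kb window upstream counting Crick (−) strand fragments and a 2 kb window
downstream counting Watson (+) strand fragments. A fragment is assigned by
its 5′ end (preventing one fragment counting in both windows); strandless
fragments are an input error. A feature is dropped entirely when **either**
window overlaps a protein-coding gene or lncRNA body extended 1 kb beyond
its TSS and TES — dropping whole features avoids half-features with
incomparable counts — or when the upstream window would run off the
chromosome start. Features with fewer than 10 counts summed over all
replicates and conditions are removed. Fold-changes normalize counts by
median-of-ratios size factors computed across all retained features,
average replicates within condition, and take log2 with a 0.5 pseudocount.
Differential significance testing (dispersion estimation, Wald tests) is
deliberately out of scope; the size-factor normalization matches the family
of methods used for such count data.

## Distance-controlled resampling

To compare contact changes at loop-domain boundary loops against
intra-domain contacts, all unordered DHS-center pairs within each
increased-accessibility domain form the candidate pool; each pair's value is
the log2FC of the O/E pixel containing the two centers (pseudocount 1e−3
O/E units). Pairwise distances are binned in log2-width bins
([2^k, 2^(k+1)) bp) — geometric bins respect the distance decay of contact
frequency; the width is configurable. Each of N = 100 resamples draws, for
every test-pair distance, one candidate uniformly from the same bin without
replacement within the resample (falling back to with-replacement when a
bin is exhausted, logged), so every resample matches the test set in both
number and distance histogram. The empirical p-value is the fraction of
resampled medians below the test median (one-sided, null-below-test),
computed with denominator N so that 1 of 100 gives exactly 0.01; a
conservative (k+1)/(N+1) variant is available behind a flag. p = 0 is
rendered "< 1/N" in text while the numeric field stores 0. Under the null
(test set drawn from the pool), the p-value distribution is approximately
uniform, verified by a Kolmogorov–Smirnov check over 200 seeded runs.

## Synthetic data generator

The generator emits everything the pipeline consumes with planted effects:

- **Genome**: two 10 Mb chromosomes at 10 kb resolution — large enough for
  60 domains (30 per chromosome) with realistic lengths while keeping a full
  run in seconds.
- **Domains**: lengths uniform in 80–300 kb, bin-aligned, non-overlapping
  with ≥ 3 bins spacing (avoids ambiguous truth classifications); 35% are
  loop domains (matching the roughly one-third loop-domain share of merged
  domain calls in brain Hi-C), each with a boundary loop anchored in its
  first and last bin; 30% of domains additionally carry an intra-domain loop
  at ~30%/70% of their length.
- **Accessibility classes**: 20% increased / 76.5% unchanged / 3.5%
  decreased (the approximate proportions observed for cerebellar domains);
  planted log2FCs are drawn from class-specific normals (means ±1.0 and 0,
  sd 0.25/0.20) rejection-sampled to stay 0.05 away from the ±0.585 band
  edge, so the zero-noise limit recovers every class exactly.
- **Contact coupling**: planted domain-contact log2FC = slope ×
  accessibility log2FC + Gaussian noise, with the noise sd derived from the
  target Pearson correlation r as sd = |slope|·sd(acc)·sqrt(1/r² − 1)
  (defaults slope 0.8, r = 0.6); slope 0 or r = 1 give exactly zero noise.
- **Matrices**: O/E background 1.0 with multiplicative log-normal noise
  (sd 0.06 in log2), within-domain pixels ×2.0, loop pixels ×3.0 (the
  planted enrichment APA must recover), knockout within-domain pixels
  additionally scaled by 2^(planted contact log2FC). Raw counts and KR
  balancing are not simulated: the analysis consumes O/E values only.
- **Compartments**: alternating A/B blocks of 900 kb; separate 150 kb
  matrices with same-label pixels 1.6 and cross-label 0.5; the H3K27ac track
  baseline is compartment-dependent (0.5 vs 0.1 rpm) so sign orientation has
  signal to work with.
- **Signal tracks**: per-replicate bedGraphs (2 replicates/condition) with
  1 kb peak plateaus at DHS centers (amplitudes 5/4/3 rpm for
  accessibility/H3K27ac/Smc1), knockout amplitudes scaled by the domain's
  planted accessibility fold-change, per-replicate log-normal noise
  (sd 0.05 in log2). 15% of DHS lack H3K27ac/H3K4me1 marks and so are not
  enhancers.
- **eRNA fragments**: negative-binomial counts per stranded window per
  replicate (mean 50 per window, dispersion 0.02 — near-Poisson replicate
  noise so that rank recovery of a planted fold-change vector is limited by
  counting noise, not by simulated biological dispersion), knockout means
  scaled by the host domain's accessibility fold-change; fragment 5′ ends
  uniform in the window.
- **DHS placement**: two DHS sit in the domain's first and last bin
  (mirroring the CTCF/DHS anchoring of boundary loops) and the rest spread
  through the interior. This guarantees every boundary-loop span has an
  intra-domain DHS pair at the same distance, so the resampling null's
  distance bins are never empty on planted data.
- **Genes**: a few coding genes and one lncRNA per chromosome placed in
  inter-domain gaps, clear of all eRNA windows, so the default dataset keeps
  every feature; the exclusion rule is exercised by dedicated fixtures.

Identical configuration (including the seed, default 7) reproduces
byte-identical output files.

What the generator does **not** emulate: read-level noise, replicate-level
Hi-C variation, KR balancing artifacts, distance-dependent contact decay
within domains, peak-calling uncertainty (peak sets are identical across
conditions), condition-dependent architecture (the same domains and loops
are planted in both conditions), and correlated multi-assay noise. Passing
tests therefore demonstrate that the estimators recover planted effects
under clean two-condition structure, not that they are robust to the full
noise structure of real sequencing data.

## Problem sizes

The default synthetic run (2 × 10 Mb, 60 domains, ~200 eRNA features,
100 resamples) completes in a few seconds; the test suite and the
acceptance script each run the full pipeline a handful of times plus
1,000-case brute-force oracle sweeps on ≤ 50-bin matrices and a 200-run
resampling calibration.

## Known limitations

- Merging is greedy nearest-first, not globally optimal assignment; for
  bin-aligned calls with tolerances far below typical domain sizes the
  difference is immaterial, but pathological overlapping call sets could
  merge differently than a Hungarian matching would.
- The O(n²)-per-chromosome merge is fine for real call-set sizes (~10⁴)
  but not for millions of records.
- The insulation score follows the domain-length-window, crossing-over-total
  definition; it is not the sliding-square insulation profile used by
  boundary callers.
- Compartment eigenvectors on very small matrices (< ~20 bins) can mix the
  compartment signal with other variance components; the 150 kb default and
  block-structured tests stay well away from this regime.
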