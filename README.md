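# domainweaver

Two-condition integration of 3D genome architecture and epigenome data.

When a chromatin regulator is knocked out, interactions inside Hi-C contact
domains, the strength of chromatin loops, A/B compartmentalization, enhancer
accessibility and acetylation, cohesin binding, and enhancer-RNA (eRNA)
output can all shift together. `domainweaver` is a library + CLI for
quantifying those coupled changes between a control and a knockout
condition from processed genomics files, for genomicists who already have
domain/loop calls, peak sets, coverage tracks, and O/E KR-normalized
contact matrices and want the downstream integration analysis:

- merge per-condition Arrowhead-style domain calls (borders within 20 kb)
  and HiCCUPS-style loop calls (anchor midpoints within 10 kb), and classify
  **loop domains** (boundaries anchored by a loop within 25 kb) vs
  **compartmental domains**, and **boundary** / **intra-domain** / other loops;
- classify active promoters (TSS in DHS ∩ H3K27ac) and enhancers (DHS with
  ≥ 25% reciprocal overlap of H3K27ac and H3K4me1 peaks), each with a 1 kb
  quantification window;
- quantify rpm signal per element and per domain, and class domains by
  accessibility log2FC as increased (> 0.585), unchanged, or decreased
  (< −0.585);
- compute domain contacts (mean O/E over within-domain bin pairs), loop
  contacts (anchor-rectangle mean), boundary insulation
  (−log2 crossing/total in a domain-length window), aggregate peak analysis
  with P2LL, and the H3K27ac-oriented A/B compartment eigenvector at 150 kb
  with per-domain eigenvalues;
- count strand-specific eRNA fragments in bidirectional 2 kb windows at
  enhancer DHS centers (gene-proximal windows excluded, < 10-count features
  removed) and estimate fold-changes with median-of-ratios size factors;
- test whether boundary-loop contact changes differ from intra-domain
  changes with a distance-controlled resampling null (100 resamples matched
  in pair number and log2-binned distance; empirical one-sided p-value).

A built-in synthetic-data generator plants known per-domain accessibility
and contact fold-changes, loop enrichments, and compartment labels, so every
stage has a ground-truth recovery test.

## Worked example

Run the whole pipeline on the default synthetic dataset (two 10 Mb
chromosomes, 60 domains, seed 7):

```
$ domainweaver run-all --out demo/
{
  "domains_merged": 60,
  "loops_merged": 37,
  "loop_domains": 19,
  "compartmental_domains": 41,
  "enhancers": 201,
  "erna_features_built": 201,
  "erna_features_retained": 201,
  "resampling_test_loops": 4,
  ...
}
resampling: test median 0.8761, empirical p 0.01
```

The 60 merged domains split into 19 loop domains and 41 compartmental
domains (the planted split), all 201 enhancer DHS yield eRNA features and
all survive the 10-count filter at the default sequencing depth. The
correlation panel (`demo/correlations.tsv`) reports a domain-level Pearson
r = 0.647 between accessibility log2FC and contact log2FC — recovering the
generator's target coupling of 0.6 — and `demo/class_summary.tsv` shows the
contact changes stratified by accessibility class:

```
class      n   median   q25     q75
increased  9   1.051    0.911   1.114
unchanged  50  0.044   -0.405   0.361
decreased  1  -1.343   -1.343  -1.343
```

i.e. domains that gain accessibility gain internal contacts (~2-fold median
increase here, by construction of the planted coupling). The resampling line
says the median boundary-loop contact change sat above exactly 1 of 100
distance-matched intra-domain resamples (empirical p = 0.01, one-sided,
null-below-test).

The same stages are importable as functions:

```python
from domainweaver import SimConfig, generate_dataset, run_pipeline
from domainweaver.pipeline import truth_calls, PipelineParams

ctrl, cko, truth = generate_dataset(SimConfig())
domain_calls, loop_calls = truth_calls(truth)
report = run_pipeline(ctrl, cko, domain_calls, loop_calls, PipelineParams())
report.domains.head()     # per-domain signals, contacts, classes, eigenvalues
report.resampling.p_text()
```

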