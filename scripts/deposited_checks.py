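#!/usr/bin/env python
"""Verify the published architecture counts on the study's deposited data.

Merging the per-condition Arrowhead contact-domain lists at 20 kb and the
per-condition HiCCUPS loop lists at 10 kb, then classifying domains against
loop anchors at 25 kb, must reproduce 7,796 merged domains, 11,525 merged
loops, and a 2,752 loop-domain / 5,044 compartmental-domain split.

This needs the processed domain/loop calls from GEO accession GSE138822
(control and Chd4 cKO cerebellum Hi-C): download them manually, convert to
plain BED (domains: chrom/start/end) and BEDPE (loops: both anchors), and
pass the four files below. Network access is required only for the download;
the check itself is local.

Usage:
  python scripts/deposited_checks.py \
      --domains-ctrl domains_ctrl.bed --domains-cko domains_cko.bed \
      --loops-ctrl loops_ctrl.bedpe --loops-cko loops_cko.bedpe
"""
from __future__ import annotations

import argparse
import sys

from domainweaver.intervals import classify_domains, merge_domains, merge_loops
from domainweaver.io import bed_to_domains, read_bedpe

EXPECTED = {
    "domains_merged": 7796,
    "loops_merged": 11525,
    "loop_domains": 2752,
    "compartmental_domains": 5044,
}


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--domains-ctrl", required=True)
    ap.add_argument("--domains-cko", required=True)
    ap.add_argument("--loops-ctrl", required=True)
    ap.add_argument("--loops-cko", required=True)
    args = ap.parse_args()

    domains = merge_domains(
        bed_to_domains(args.domains_ctrl, source="control"),
        bed_to_domains(args.domains_cko, source="cko"),
        tol=20_000,
    )
    loops = merge_loops(
        read_bedpe(args.loops_ctrl), read_bedpe(args.loops_cko), tol=10_000
    )
    domains = classify_domains(domains, loops, tol=25_000)
    got = {
        "domains_merged": len(domains),
        "loops_merged": len(loops),
        "loop_domains": sum(d.klass == "loop" for d in domains),
        "compartmental_domains": sum(d.klass == "compartmental" for d in domains),
    }
    ok = True
    for key, want in EXPECTED.items():
        status = "OK" if got[key] == want else "MISMATCH"
        ok &= got[key] == want
        print(f"{key}: got {got[key]}, expected {want} [{status}]")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
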