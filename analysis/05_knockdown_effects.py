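#!/usr/bin/env python
"""Knockdown effect sizes on domain signal and border elements.

Contrasts each knockdown condition against control: nucleosome-class
midpoint counts inside planted domains (domain signal) and short-fragment
counts inside element footprints (regulatory-element signal), both
per-million normalized and pooled over three replicates.  The planted
regimes are -35%, -20% and -5% on domains and -63% on elements, plus a
mini-domain-restricted increase and a border-element-specific loss.
"""

import argparse
from pathlib import Path

import pandas as pd

from minidomain import (
    AnalysisConfig,
    dhd_fixture,
    generate,
    quantify_regions,
)
from minidomain.fragio import nucleosomal_only, partition_by_size
from minidomain.quantify import Region

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cfg = AnalysisConfig()
    spec = dhd_fixture(seed=args.seed)
    libs = generate(spec)
    conditions = sorted({c for c, _ in libs})
    reps = sorted({r for _, r in libs})
    pooled = {
        c: [f for r in reps for f in libs[(c, r)]] for c in conditions
    }

    # domain signal: nucleosome-class fragments in planted domain intervals
    nuc_sets = {
        c: nucleosomal_only(frags, cfg.short_threshold_bp)
        for c, frags in pooled.items()
    }
    domain_regions = [
        Region(d.name, d.chrom, d.start, d.end) for d in spec.domains
    ]
    domain_quants = quantify_regions(nuc_sets, domain_regions, "control")

    # element signal: short fragments in planted footprints
    short_sets = {
        c: partition_by_size(frags, cfg.short_threshold_bp)[0]
        for c, frags in pooled.items()
    }
    element_regions = [
        Region(e.name, e.chrom, e.center - e.footprint_bp // 2,
               e.center + e.footprint_bp - e.footprint_bp // 2)
        for e in spec.elements
    ]
    element_quants = quantify_regions(short_sets, element_regions, "control")

    rows = []
    for kind, quants in (("domain", domain_quants), ("element", element_quants)):
        for q in quants:
            for cond in conditions:
                if cond == "control":
                    continue
                rows.append({
                    "kind": kind,
                    "region": q.region.name,
                    "condition": cond,
                    "percent_change": None if q.percent_change[cond] is None
                    else round(q.percent_change[cond], 1),
                })
    table = pd.DataFrame(rows)
    table.to_csv(results / "knockdown_effects.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nPlanted: ez_kd -35%, snr1_kd -20%, sin3a_kd/modmdg4_kd -5% on "
          "domains; -63% on elements for ez/snr1/sin3a; modmdg4_kd hits only "
          "the mini-domain borders (-60%); lid_kd raises the mini-domain "
          "(+30%) and spares elements.")


if __name__ == "__main__":
    main()
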