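#!/usr/bin/env python
"""Border/internal classification of element peaks and flank-asymmetry
profiles.

Relates reproducible short-fragment peaks to segmented domains: each summit
is labelled 5' border, 3' border, internal or outside, with the flank
log2-ratio of all-fragment coverage quantifying the asymmetry that
distinguishes borders (signal on one side) from internal elements
(signal on both).  The mini-domain should carry exactly one 5' and one 3'
border peak and nothing internal.
"""

import argparse
from pathlib import Path

import pandas as pd

from minidomain import (
    AnalysisConfig,
    call_short_fragment_peaks,
    classify_peaks,
    coverage,
    dhd_fixture,
    generate,
    partition_by_size,
    profile_matrix,
    reproducible_peaks,
    segment_domains,
)
from minidomain.architecture import BORDER_SLACK_BP

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cfg = AnalysisConfig()
    spec = dhd_fixture(seed=args.seed)
    libs = generate(spec, conditions=["control"])
    reps = sorted(r for c, r in libs)

    per_rep = []
    tracks = {}
    for rep in reps:
        short, allf = partition_by_size(libs[("control", rep)],
                                        cfg.short_threshold_bp)
        per_rep.append(call_short_fragment_peaks(short, spec.genome, cfg))
        tracks[rep] = (coverage(allf, spec.genome, cfg.all_bin_bp),
                       coverage(allf, spec.genome, cfg.domain_bin_bp))
    peaks = reproducible_peaks(per_rep)
    domains = segment_domains(tracks[reps[0]][1], cfg)

    classes = classify_peaks(
        peaks, domains,
        border_slack_bp=BORDER_SLACK_BP + cfg.domain_bin_bp,
        track=tracks[reps[0]][0],
    )
    table = pd.DataFrame({
        "chrom": [c.peak.chrom for c in classes],
        "start": [c.peak.start for c in classes],
        "end": [c.peak.end for c in classes],
        "summit": [c.peak.summit for c in classes],
        "label": [c.label for c in classes],
        "flank_log2_ratio": [round(c.flank_log2_ratio, 3) for c in classes],
    })
    table.to_csv(results / "peak_classes.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    pm = profile_matrix(peaks, tracks[reps[0]][0], cfg)
    pd.DataFrame(pm.matrix, columns=pm.positions).to_csv(
        results / "profile_matrix.tsv", sep="\t", index=False
    )
    print("\n5' borders show positive flank ratios (domain on the 3' side), "
          "3' borders negative, internal peaks near zero.")
    mini = table[(table.summit > 5_311_000) & (table.summit < 5_318_500)]
    print(f"mini-domain peaks: {sorted(mini.label)}")


if __name__ == "__main__":
    main()
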