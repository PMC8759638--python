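#!/usr/bin/env python
"""Fragment-size classes and the midpoint-vs-length V-plot.

Shows the bimodal fragment-length structure of a control library (TF-sized
50-130bp vs nucleosome-sized 147-250bp) and builds the V-plot around planted
element centers: short-fragment mass concentrates on the element footprint
while nucleosome-sized mass flanks it.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from minidomain import AnalysisConfig, dhd_fixture, generate, vplot

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cfg = AnalysisConfig()
    spec = dhd_fixture(seed=args.seed)
    frags = generate(spec, conditions=["control"])[("control", "rep1")]

    lengths = np.array([f.length for f in frags])
    hist, edges = np.histogram(lengths, bins=np.arange(40, 260, 5))
    pd.DataFrame({"length_bin_start": edges[:-1], "count": hist}).to_csv(
        results / "fragment_length_histogram.tsv", sep="\t", index=False
    )
    short = ((lengths >= 50) & (lengths <= 130)).sum()
    nuc = (lengths >= 147).sum()
    print(f"{len(frags)} fragments: {short} in 50-130bp (TF footprints), "
          f"{nuc} in 147-250bp (nucleosomes), modes are well separated")

    vm = vplot(frags, [e.center for e in spec.elements], cfg)
    pd.DataFrame(
        vm.counts.astype(int),
        index=(vm.y_edges[:-1] + vm.y_edges[1:]) / 2,
        columns=(vm.x_edges[:-1] + vm.x_edges[1:]) / 2,
    ).to_csv(results / "vplot_matrix.tsv", sep="\t")

    short_near = vm.mass((-80, 80), (50, 130))
    short_total = vm.mass((-1000, 1000), (50, 130))
    nuc_near = vm.mass((-60, 60), (150, 250))
    nuc_far = vm.mass((-1000, -80), (150, 250)) + vm.mass((80, 1000), (150, 250))
    print(f"V-plot: {short_near}/{short_total} short-fragment counts lie "
          f"within 80bp of element centers;")
    print(f"nucleosome-sized counts flank them ({nuc_far} beyond 80bp vs "
          f"{nuc_near} near the center).")


if __name__ == "__main__":
    main()
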