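#!/usr/bin/env python
"""Post-wound marking changes: MA rescaling and gain/loss calls.

For each mark and time (vs 0 h) every gene gets M/A coordinates; a robust
line fitted on anchor genes (marked at both times) recenters M, and genes
with rescaled |M'| > 0.15 are called gained or lost.  Reports per-mark call
counts and the fraction of wound-induced genes gaining acetylation marks.
"""

import argparse
from pathlib import Path

import pandas as pd

from woundchrom.dynamics import report_fraction
from woundchrom.marking import marking_contrast
from woundchrom.pipeline import PipelineConfig, load_dataset
from woundchrom.states import enrichment_levels, marked_gene_sets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--expression", type=Path,
                    default=Path("results/expression"))
    ap.add_argument("--out", type=Path, default=Path("results/marking"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(data_dir=str(args.data))
    data = load_dataset(args.data, cfg)
    levels = enrichment_levels(data.coverage)
    marked = {t: marked_gene_sets(data.peaks, data.genes, cfg.marks, t)
              for t in data.chip_times}

    tables = []
    for mark in cfg.marks:
        for t in [t for t in data.chip_times if t != 0.0]:
            tab = marking_contrast(levels, mark, t, marked[0.0][mark],
                                   marked[t][mark])
            tables.append(tab.reset_index())
    marking = pd.concat(tables, ignore_index=True)
    marking.to_csv(args.out / "marking_changes.tsv", sep="\t", index=False,
                   float_format="%.6g")

    for mark in cfg.marks:
        sub = marking[marking["mark"] == mark]
        gains = sub.loc[sub["call"] == "gain", "gene_id"].nunique()
        losses = sub.loc[sub["call"] == "loss", "gene_id"].nunique()
        print(f"{mark}: {gains} genes gain, {losses} lose (|M'| > 0.15)")

    induced = set((args.expression / "induced_genes.txt").read_text().split())
    ac_gainers = set(marking.loc[
        (marking["call"] == "gain")
        & marking["mark"].isin(["H3K9_14ac", "H3K27ac", "H3K4me3"]),
        "gene_id"])
    k = len(induced & ac_gainers)
    print(f"{k} of {len(induced)} wound-induced genes "
          f"({report_fraction(k, max(len(induced), 1))}) gain H3K9/14ac, "
          f"H3K27ac and/or H3K4me3")


if __name__ == "__main__":
    main()
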