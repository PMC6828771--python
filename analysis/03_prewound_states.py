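#!/usr/bin/env python
"""Pre-wound chromatin states and their relation to wound responsiveness.

Builds the gene x mark marking-state table (both-replicate peak calls at
0 h, H3-normalized enrichment levels), tallies mark combinations (including
bivalent H3K27me3 + active-mark co-marking), and computes representation
factors of each mark — and each co-mark pair — among induced and repressed
genes, with two-tailed hypergeometric annotation.
"""

import argparse
from pathlib import Path

import pandas as pd

from woundchrom.dynamics import report_fraction
from woundchrom.enrich import comark_enrichment, mark_enrichment
from woundchrom.pipeline import PipelineConfig, load_dataset
from woundchrom.states import build_state_table, combination_table, \
    write_state_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--expression", type=Path,
                    default=Path("results/expression"))
    ap.add_argument("--out", type=Path, default=Path("results/states"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(data_dir=str(args.data))
    data = load_dataset(args.data, cfg)
    state = build_state_table(data.peaks, data.coverage, data.genes)
    write_state_table(state, args.out / "state_table.tsv")

    marked_any = state.marked.any(axis=1)
    universe = {g.gene_id for g in data.genes}
    print(f"{int(marked_any.sum())} of {len(universe)} genes bear >= 1 mark "
          f"before wounding ({report_fraction(int(marked_any.sum()), len(universe))})")
    for m in state.marked.columns:
        print(f"  {m}: {int(state.marked[m].sum())} marked genes")

    combos = combination_table(state.marked)
    pd.DataFrame([{"combination": "+".join(sorted(c.combination)) or "(none)",
                   "count": c.count} for c in combos]) \
        .to_csv(args.out / "combinations.tsv", sep="\t", index=False)
    bivalent = state.marked["H3K27me3"] & state.marked.drop(
        columns="H3K27me3").any(axis=1)
    k27 = int(state.marked["H3K27me3"].sum())
    print(f"bivalent (H3K27me3 + >= 1 active mark): {int(bivalent.sum())} of "
          f"{k27} PRC2-target genes "
          f"({report_fraction(int(bivalent.sum()), max(k27, 1))})")

    induced = set((args.expression / "induced_genes.txt").read_text().split())
    repressed = set((args.expression / "repressed_genes.txt")
                    .read_text().split())
    for name, query in (("induced", induced), ("repressed", repressed)):
        enr = mark_enrichment(state.marked, query, universe)
        enr.to_csv(args.out / f"mark_enrichment_{name}.tsv", sep="\t",
                   float_format="%.6g")
        print(f"mark representation among wound-{name} genes:")
        for m, row in enr.iterrows():
            print(f"  {m}: RF={row['representation_factor']:.2f} "
                  f"{row['stars'] or 'ns'}")
    comark_enrichment(state.marked, induced).to_csv(
        args.out / "comark_enrichment_induced.tsv", sep="\t",
        float_format="%.6g")


if __name__ == "__main__":
    main()
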