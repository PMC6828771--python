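#!/usr/bin/env python
"""Integrate chromatin state with induction timing.

Asks which pre-wound mark predicts how early a gene is induced (rank-LOESS
and PCA), classifies induced genes by their acetylation history, counts
whether H3K9/14ac gains precede H3K4me3 gains, averages temporal mark
profiles per category, and correlates marking changes with expression
changes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from woundchrom.dynamics import (classify_ac_category, loading_angle_deg,
                                 marking_expression_correlation,
                                 precedence_counts, rank_loess_timing,
                                 report_fraction, temporal_profiles,
                                 timing_pca)
from woundchrom.enrich import cluster_category_enrichment
from woundchrom.marking import first_gain_times
from woundchrom.pipeline import PipelineConfig, load_dataset
from woundchrom.states import build_state_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--expression", type=Path,
                    default=Path("results/expression"))
    ap.add_argument("--marking", type=Path, default=Path("results/marking"))
    ap.add_argument("--out", type=Path, default=Path("results/dynamics"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(data_dir=str(args.data))
    data = load_dataset(args.data, cfg)
    state = build_state_table(data.peaks, data.coverage, data.genes)
    clusters = pd.read_csv(args.expression / "clusters.tsv", sep="\t",
                           index_col=0)["cluster"]
    marking = pd.read_csv(args.marking / "marking_changes.tsv", sep="\t")
    induced = pd.Index(sorted(
        (args.expression / "induced_genes.txt").read_text().split()))

    # does the pre-wound level of a mark predict induction timing?
    level0 = state.level_matrix(0.0)
    rhos = {}
    curves = []
    for mark in cfg.marks:
        curve, rho = rank_loess_timing(level0[mark].dropna(), clusters)
        curve.insert(0, "mark", mark)
        curves.append(curve)
        rhos[mark] = rho
        print(f"rank-LOESS Spearman rho({mark} level, timing cluster) = "
              f"{rho:+.3f}")
    pd.concat(curves, ignore_index=True).to_csv(
        args.out / "loess_curve.tsv", sep="\t", index=False,
        float_format="%.6g")
    pd.Series(rhos, name="spearman_rho").rename_axis("mark").to_csv(
        args.out / "loess_rho.tsv", sep="\t")

    pca_vars = level0.loc[induced, list(cfg.marks)].rank()
    pca_vars["timing"] = clusters.loc[induced].astype(float)
    expr0 = data.expression.counts[data.expression.columns_at(0.0)] \
        .mean(axis=1)
    pca_vars["expression_0h"] = expr0.loc[induced].rank()
    loadings, var_frac = timing_pca(pca_vars)
    loadings.to_csv(args.out / "pca_loadings.tsv", sep="\t",
                    float_format="%.6g")
    var_frac.to_frame().to_csv(args.out / "pca_variance.tsv", sep="\t",
                               float_format="%.6g")
    print(f"PCA: PC1/PC2 explain {100 * var_frac['PC1']:.1f}% / "
          f"{100 * var_frac['PC2']:.1f}% of variance; angle(timing, "
          f"H3K9/14ac) = "
          f"{loading_angle_deg(loadings, 'timing', 'H3K9_14ac'):.0f} deg")

    # acetylation categories + precedence
    contrast_times = [t for t in data.chip_times if t != 0.0]
    by_mark = {m: [marking[(marking["mark"] == m) & (marking["time_h"] == t)]
                   .set_index("gene_id") for t in contrast_times]
               for m in ("H3K9_14ac", "H3K4me3")}
    gain_ac = first_gain_times(by_mark["H3K9_14ac"])
    gain_me3 = first_gain_times(by_mark["H3K4me3"])
    ac_cat = classify_ac_category(state.marked.loc[induced, "H3K9_14ac"],
                                  gain_ac, gain_me3,
                                  window_end_h=max(contrast_times))
    ac_cat.to_csv(args.out / "ac_categories.tsv", sep="\t")
    counts = ac_cat["category"].value_counts()
    with_ac = int(counts.get("preac_no_gain", 0)
                  + counts.get("preac_plus_gain", 0)
                  + counts.get("gain_only", 0))
    print(f"{with_ac} of {len(induced)} induced genes "
          f"({report_fraction(with_ac, max(len(induced), 1))}) carry or gain "
          f"H3K9/14ac")

    prec = precedence_counts(gain_ac.loc[induced], gain_me3.loc[induced])
    prec.table.to_csv(args.out / "precedence.tsv", sep="\t",
                      float_format="%.6g")
    pd.DataFrame({"strict": prec.counts,
                  "inclusive": prec.counts_inclusive}).to_csv(
        args.out / "precedence_counts.tsv", sep="\t")
    print(f"precedence: {prec.ac_first} genes gain H3K9/14ac before H3K4me3, "
          f"{prec.me3_first} the reverse")

    cluster_category_enrichment(ac_cat["category"], clusters).to_csv(
        args.out / "cluster_category_enrichment.tsv", sep="\t", index=False,
        float_format="%.6g")

    prof, _ = temporal_profiles(
        state.levels[state.levels["gene_id"].isin(induced)],
        ac_cat["category"])
    prof.to_csv(args.out / "profiles.tsv", sep="\t", index=False,
                float_format="%.6g")

    de = pd.read_csv(args.expression / "de_results.tsv", sep="\t")
    rows = []
    for mark in cfg.marks:
        for t in contrast_times:
            m_prime = marking[(marking["mark"] == mark)
                              & (marking["time_h"] == t)] \
                .set_index("gene_id")["M_rescaled"]
            lfc = de[de["time_h"] == t].set_index("gene_id")["log2FC"]
            r = marking_expression_correlation(m_prime, lfc)
            rows.append({"mark": mark, "time_h": t, "pearson_r": r})
    corr = pd.DataFrame(rows)
    corr.to_csv(args.out / "correlations.tsv", sep="\t", index=False,
                float_format="%.6g")
    best = corr.loc[corr["pearson_r"].idxmax()]
    print(f"strongest marking/expression correlation: {best['mark']} at "
          f"{best['time_h']:g} h (r = {best['pearson_r']:.2f})")


if __name__ == "__main__":
    main()
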