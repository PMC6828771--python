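"""Per-gene H3-normalized enrichment levels, marking-state tables, and
combination (Venn/upset/pie) accounting.

A gene's enrichment level for a mark is mean mark depth / mean H3 depth over
its analysis window (replicates averaged first, pseudo-depth 0.5 on both
sides).  A gene is *marked* at a time point only if a qualifying peak
overlaps its window in both replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genomic
from .genomic import (GeneModel, H3_TRACK, Peak, ValidationError,
                      assign_peaks_to_genes, marked_genes)

PSEUDO_DEPTH = 0.5


def relative_enrichment(coverage: pd.DataFrame, gene_id: str, mark: str,
                        time_h: float, per_replicate: bool = False) -> float:
    """Mark / H3 depth ratio for one gene at one time.

    Replicates are averaged before the ratio by default (``per_replicate=True``
    averages per-replicate ratios instead).  Pseudo-depth 0.5 is added to both
    numerator and denominator.
    """
    sel = (coverage["gene_id"] == gene_id) & (coverage["time_h"] == time_h)
    mark_d = coverage.loc[sel & (coverage["track"] == mark), "mean_depth"]
    h3_d = coverage.loc[sel & (coverage["track"] == H3_TRACK), "mean_depth"]
    if h3_d.empty:
        raise ValidationError(f"no H3 coverage for gene {gene_id} at t={time_h}")
    if mark_d.empty:
        raise ValidationError(f"no {mark} coverage for gene {gene_id} at t={time_h}")
    if per_replicate:
        merged = pd.merge(
            coverage.loc[sel & (coverage["track"] == mark),
                         ["replicate", "mean_depth"]],
            coverage.loc[sel & (coverage["track"] == H3_TRACK),
                         ["replicate", "mean_depth"]],
            on="replicate", suffixes=("_mark", "_h3"))
        return float(np.mean((merged["mean_depth_mark"] + PSEUDO_DEPTH)
                             / (merged["mean_depth_h3"] + PSEUDO_DEPTH)))
    return float((mark_d.mean() + PSEUDO_DEPTH) / (h3_d.mean() + PSEUDO_DEPTH))


def enrichment_levels(coverage: pd.DataFrame,
                      marks: Sequence[str] | None = None) -> pd.DataFrame:
    """Vectorised relative enrichment for every gene x mark x time.

    Returns a long table (gene_id, mark, time_h, level); same arithmetic as
    :func:`relative_enrichment` with replicates averaged first.
    """
    mean_d = (coverage.groupby(["gene_id", "track", "time_h"])["mean_depth"]
              .mean().reset_index())
    h3 = mean_d[mean_d["track"] == H3_TRACK].rename(
        columns={"mean_depth": "h3_depth"})[["gene_id", "time_h", "h3_depth"]]
    mk = mean_d[mean_d["track"] != H3_TRACK]
    if marks is not None:
        mk = mk[mk["track"].isin(marks)]
    merged = mk.merge(h3, on=["gene_id", "time_h"], how="left")
    if merged["h3_depth"].isna().any():
        missing = merged.loc[merged["h3_depth"].isna()].iloc[0]
        raise ValidationError(
            f"no H3 coverage for gene {missing['gene_id']} at t={missing['time_h']}")
    merged["level"] = ((merged["mean_depth"] + PSEUDO_DEPTH)
                       / (merged["h3_depth"] + PSEUDO_DEPTH))
    return (merged.rename(columns={"track": "mark"})
            [["gene_id", "mark", "time_h", "level"]])


@dataclass
class MarkStateTable:
    """Per gene x mark marking calls plus per-time enrichment levels."""

    marked: pd.DataFrame   # genes x marks, bool (both-replicate peak overlap)
    levels: pd.DataFrame   # long: gene_id, mark, time_h, level

    def level_matrix(self, time_h: float) -> pd.DataFrame:
        """genes x marks pivot of levels at one time."""
        sub = self.levels[self.levels["time_h"] == time_h]
        return sub.pivot(index="gene_id", columns="mark", values="level")


def marked_gene_sets(peaks: Mapping[tuple[str, float, int], Sequence[Peak]],
                     genes: Sequence[GeneModel], marks: Sequence[str],
                     time_h: float, promoter_bp: int = 1000,
                     max_distance_bp: int = 0,
                     n_reps: int = 2,
                     min_neg_log10_q: float = 3.0) -> dict[str, set[str]]:
    """Replicate-intersected marked-gene sets per mark at one time point.

    Peaks below the significance filter are excluded even when supplied
    in-memory (file readers apply the same filter on read)."""
    out: dict[str, set[str]] = {}
    for mark in marks:
        assigns = []
        for rep in range(1, n_reps + 1):
            key = (mark, time_h, rep)
            if key not in peaks:
                raise ValidationError(
                    f"missing peak set for mark={mark} t={time_h} rep={rep}")
            qualifying = [p for p in peaks[key]
                          if p.neg_log10_q >= min_neg_log10_q]
            assigns.append(assign_peaks_to_genes(qualifying, genes,
                                                 promoter_bp))
        common = marked_genes(assigns[0], assigns[1], max_distance_bp)
        for extra in assigns[2:]:
            common &= marked_genes(assigns[0], extra, max_distance_bp)
        out[mark] = common
    return out


def build_state_table(peaks: Mapping[tuple[str, float, int], Sequence[Peak]],
                      coverage: pd.DataFrame, genes: Sequence[GeneModel],
                      marks: Sequence[str] = genomic.DEFAULT_MARKS,
                      time_h: float = 0.0, promoter_bp: int = 1000,
                      max_distance_bp: int = 0) -> MarkStateTable:
    """Pre-wound (or per-time) marking state: both-replicate peak calls plus
    H3-normalized enrichment levels at every available time."""
    sets = marked_gene_sets(peaks, genes, marks, time_h, promoter_bp,
                            max_distance_bp)
    gene_ids = [g.gene_id for g in genes]
    marked = pd.DataFrame(
        {m: [gid in sets[m] for gid in gene_ids] for m in marks},
        index=pd.Index(gene_ids, name="gene_id"))
    levels = enrichment_levels(coverage, marks)
    return MarkStateTable(marked, levels)


@dataclass(frozen=True)
class CombinationCount:
    combination: frozenset[str]
    count: int


def combination_table(boolean_table: pd.DataFrame) -> list[CombinationCount]:
    """Exact partition counts over all 2^m feature subsets (m <= 8).

    Each gene contributes to exactly the combination it bears, so counts sum
    to the number of genes.
    """
    features = list(boolean_table.columns)
    if len(features) > 8:
        raise ValidationError(f"{len(features)} features > 8: combination "
                              "explosion guard")
    tallies = boolean_table.astype(bool).groupby(features).size() \
        if features else None
    out: list[CombinationCount] = []
    for combo_bits in itertools.product([False, True], repeat=len(features)):
        combo = frozenset(f for f, b in zip(features, combo_bits) if b)
        if features:
            try:
                count = int(tallies.loc[combo_bits if len(features) > 1
                                        else combo_bits[0]])
            except KeyError:
                count = 0
        else:
            count = len(boolean_table)
        out.append(CombinationCount(combo, count))
    return out


def write_state_table(table: MarkStateTable, path: str | Path) -> None:
    levels = table.levels.pivot_table(index=["gene_id", "mark"],
                                      columns="time_h", values="level")
    levels.columns = [f"level_t{t:g}" for t in levels.columns]
    long_marked = table.marked.stack().rename("marked")
    long_marked.index.names = ["gene_id", "mark"]
    merged = levels.join(long_marked, how="left").reset_index()
    merged.to_csv(path, sep="\t", index=False, float_format="%.6g")
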