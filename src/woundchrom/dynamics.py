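"""Timing-integration analyses linking chromatin state to induction dynamics.

Covers: rank-vs-timing LOESS (does a mark's pre-wound level predict how
early a gene is induced?), PCA of pre-wound mark ranks against timing,
acetylation-category classification, acetylation/H3K4me3 precedence
counting, temporal profile averaging, mark-change/expression correlation,
and the fraction-reporting convention used for headline percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genomic import ValidationError

log = logging.getLogger(__name__)

PRECEDENCE_CATEGORIES = ("ac_first", "me3_first", "simultaneous",
                         "only_ac", "only_me3", "neither")

AC_CATEGORIES = ("preac_no_gain", "preac_plus_gain", "gain_only", "no_ac")


# ---------------------------------------------------------------------------
# rank-LOESS and PCA


def rank_loess_timing(levels: pd.Series, cluster_labels: pd.Series,
                      span: float = 0.3) -> tuple[pd.DataFrame, float]:
    """LOESS of cluster label (1 = earliest) against pre-wound level rank.

    Genes are ranked by level (ties broken by stable input order); the
    response is the numeric cluster label; the smoother is the tricube-
    weighted local linear fit evaluated at every rank.  Also returns the
    Spearman rho between level and label (0, flagged, if either is
    constant).
    """
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    common = [g for g in levels.index if g in cluster_labels.index]
    if len(common) < 50:
        raise ValidationError(f"need >= 50 genes, got {len(common)}")
    lv = levels.loc[common].to_numpy(dtype=float)
    lab = cluster_labels.loc[common].to_numpy(dtype=float)
    order = np.argsort(lv, kind="mergesort")  # stable: ties keep input order
    ranks = np.arange(1, len(common) + 1, dtype=float)
    y = lab[order]
    smoothed = lowess(y, ranks, frac=span, it=0, return_sorted=False)
    if np.ptp(lv) == 0 or np.ptp(lab) == 0:
        log.warning("constant levels or labels: Spearman rho set to 0")
        rho = 0.0
    else:
        rho = float(stats.spearmanr(lv, lab).statistic)
    curve = pd.DataFrame({
        "rank": ranks.astype(int),
        "gene_id": np.asarray(common)[order],
        "level": lv[order],
        "cluster": y,
        "smoothed_cluster": smoothed,
    })
    return curve, rho


def timing_pca(variables: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """PCA on the correlation matrix of per-gene variables.

    ``variables``: genes x variables (e.g. per-mark pre-wound level ranks,
    numeric timing-cluster label, 0 h expression rank).  Variables are
    standardized; constant variables are dropped with a warning.  Returns
    (loadings: variables x PCs, variance-explained fractions).  Sign
    convention: the first variable's PC1 loading is >= 0.
    """
    keep = [c for c in variables.columns if variables[c].nunique() > 1]
    dropped = set(variables.columns) - set(keep)
    if dropped:
        log.warning("dropping constant variables: %s", sorted(dropped))
    X = variables[keep].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.atleast_2d(np.corrcoef(Z, rowvar=False))
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[0, j] < 0:
            eigvec[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(len(keep))]
    loadings = pd.DataFrame(eigvec, index=keep, columns=pcs)
    var_frac = pd.Series(np.clip(eigval, 0, None) / len(keep), index=pcs,
                         name="variance_fraction")
    return loadings, var_frac


def loading_angle_deg(loadings: pd.DataFrame, var_a: str, var_b: str,
                      pcs: tuple[str, str] = ("PC1", "PC2")) -> float:
    """Angle between two variables' loading vectors in a PC plane."""
    va = loadings.loc[var_a, list(pcs)].to_numpy(dtype=float)
    vb = loadings.loc[var_b, list(pcs)].to_numpy(dtype=float)
    cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


# ---------------------------------------------------------------------------
# acetylation categories and precedence


def classify_ac_category(pre_ac_marked: pd.Series, ac_gain_time: pd.Series,
                         me3_gain_time: pd.Series,
                         window_end_h: float = 6.0) -> pd.DataFrame:
    """Acetylation category per gene.

    preac_no_gain: H3K9/14ac marked at 0 h, no gain call within the window;
    preac_plus_gain: marked and gains; gain_only: unmarked but gains;
    no_ac: neither.  ``me3_gain`` flags an H3K4me3 gain independently.
    """
    idx = pre_ac_marked.index
    for s, name in ((ac_gain_time, "ac_gain_time"),
                    (me3_gain_time, "me3_gain_time")):
        missing = idx.difference(s.index)
        if len(missing):
            raise ValidationError(
                f"{len(missing)} genes missing from {name}, e.g. "
                f"{list(missing[:3])}")
    pre = pre_ac_marked.astype(bool)
    gains = ac_gain_time.loc[idx] <= window_end_h
    cat = np.where(pre & ~gains, "preac_no_gain",
                   np.where(pre & gains, "preac_plus_gain",
                            np.where(gains, "gain_only", "no_ac")))
    return pd.DataFrame({
        "category": cat,
        "me3_gain": (me3_gain_time.loc[idx] <= window_end_h).to_numpy(),
    }, index=idx)


@dataclass
class PrecedenceSummary:
    table: pd.DataFrame          # gene_id, t_gain_ac, t_gain_me3, category
    counts: pd.Series            # per category
    #: alternative tally counting single-mark gainers with the mark they gain
    counts_inclusive: pd.Series

    @property
    def ac_first(self) -> int:
        return int(self.counts["ac_first"])

    @property
    def me3_first(self) -> int:
        return int(self.counts["me3_first"])


def precedence_counts(ac_gain_time: pd.Series,
                      me3_gain_time: pd.Series) -> PrecedenceSummary:
    """Order of first H3K9/14ac vs first H3K4me3 gain per gene.

    ``ac_first``/``me3_first`` require both gains within the window (finite
    times); genes gaining only one mark fall into only_ac/only_me3.  The
    inclusive tally folds single-gainers into the corresponding *_first
    group, so either reading of the ordering is recoverable.
    """
    idx = ac_gain_time.index
    t_ac = ac_gain_time.to_numpy(dtype=float)
    t_me3 = me3_gain_time.loc[idx].to_numpy(dtype=float)
    both = np.isfinite(t_ac) & np.isfinite(t_me3)
    cat = np.select(
        [both & (t_ac < t_me3), both & (t_me3 < t_ac), both,
         np.isfinite(t_ac), np.isfinite(t_me3)],
        ["ac_first", "me3_first", "simultaneous", "only_ac", "only_me3"],
        default="neither")
    table = pd.DataFrame({"t_gain_ac": t_ac, "t_gain_me3": t_me3,
                          "category": cat}, index=idx)
    counts = (table["category"].value_counts()
              .reindex(PRECEDENCE_CATEGORIES, fill_value=0))
    inclusive = counts.copy()
    inclusive["ac_first"] += counts["only_ac"]
    inclusive["me3_first"] += counts["only_me3"]
    return PrecedenceSummary(table, counts, inclusive)


# ---------------------------------------------------------------------------
# profiles, correlation, fractions


def temporal_profiles(levels: pd.DataFrame, groups: pd.Series,
                      expression_profiles: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean +/- SD enrichment per (group, mark, time); optional paired mean
    expression trajectory per group.

    ``levels``: long (gene_id, mark, time_h, level); ``groups``: gene ->
    group label.  Empty groups are omitted with a warning.
    """
    sub = levels[levels["gene_id"].isin(groups.index)].copy()
    sub["group"] = groups.loc[sub["gene_id"]].to_numpy()
    prof = (sub.groupby(["group", "mark", "time_h"])["level"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=0), n="size")
            .reset_index())
    present = set(prof["group"])
    for g in groups.unique():
        if g not in present:
            log.warning("group %r has no level data; omitted", g)
    expr = None
    if expression_profiles is not None:
        common = expression_profiles.index.intersection(groups.index)
        ep = expression_profiles.loc[common]
        expr = (ep.groupby(groups.loc[common]).mean()
                .rename_axis(index="group"))
    return prof, expr


def marking_expression_correlation(m_rescaled: pd.Series,
                                   expression_log2fc: pd.Series
                                   ) -> float:
    """Pearson r between mark-level change and expression change (paired on
    gene id; >= 10 genes; undefined for zero variance)."""
    common = m_rescaled.index.intersection(expression_log2fc.index)
    x = m_rescaled.loc[common].to_numpy(dtype=float)
    y = expression_log2fc.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValidationError(f"only {ok.sum()} paired finite values (< 10)")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero variance: Pearson r undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def report_fraction(numerator: int, denominator: int) -> str:
    """Headline percentage formatting: one decimal below 10%, nearest
    integer (half away from zero) otherwise."""
    if denominator <= 0:
        raise ValidationError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValidationError("require 0 <= numerator <= denominator")
    value = 100.0 * numerator / denominator
    if value < 10:
        return f"{value:.1f}%"
    return f"{math.floor(value + 0.5):d}%"
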