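"""MA-based rescaling of mark levels between conditions and gain/loss calls.

For each mark and contrast (time t vs 0 h, or treated vs control), every gene
gets M = log2(level_t / level_0) and A = mean of the two log2 levels.  A
robust line M = a + b*A is fitted on *anchor* genes — genes marked in both
conditions, where no systematic change is expected — and subtracted from all
genes (the anchor-based rescaling at the heart of MAnorm-style
normalisation).  Genes with rescaled |M'| above a liberal 0.15 threshold are
called gained (M' > 0.15) or lost (M' < -0.15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import ValidationError

M_THRESHOLD = 0.15
MIN_ANCHORS = 20


def ma_transform(level_t: np.ndarray | float,
                 level_0: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """(M, A) = (log2 ratio, mean log2 level).  Levels must be positive
    (pseudo-counted upstream)."""
    lt = np.asarray(level_t, dtype=float)
    l0 = np.asarray(level_0, dtype=float)
    if np.any(lt <= 0) or np.any(l0 <= 0):
        raise ValidationError("levels must be > 0 (pseudo-count upstream)")
    m = np.log2(lt / l0)
    a = 0.5 * (np.log2(lt) + np.log2(l0))
    return m, a


def _bisquare_weights(resid: np.ndarray, c: float = 4.685) -> np.ndarray:
    scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if scale <= 0:
        scale = np.std(resid) or 1.0
    u = resid / (c * scale)
    w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    if w.sum() == 0:  # pathological: all points flagged as outliers
        w = np.ones_like(w)
    return w


def robust_line(a: np.ndarray, m: np.ndarray, n_iter: int = 20,
                tol: float = 1e-8) -> tuple[float, float]:
    """Tukey-bisquare IRLS fit of m = intercept + slope * a."""
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    for _ in range(n_iter):
        resid = m - X @ beta
        w = _bisquare_weights(resid)
        Xw = X * w[:, None]
        new_beta = np.linalg.solve(Xw.T @ X, Xw.T @ m)
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
    return float(beta[0]), float(beta[1])


def rescale_ma(m: pd.Series, a: pd.Series,
               anchor_genes: set[str]) -> tuple[pd.Series, float, float]:
    """Rescaled M' = M - (a + b*A) with (a, b) fitted robustly on anchors.

    Anchors are genes marked (both-replicate peaks) in BOTH contrasted
    conditions for the mark at hand; at least 20 are required.
    """
    anchors = [g for g in m.index if g in anchor_genes]
    if len(anchors) < MIN_ANCHORS:
        raise ValidationError(
            f"only {len(anchors)} anchor genes (< {MIN_ANCHORS}); consider "
            "pooling anchors across time points")
    intercept, slope = robust_line(a.loc[anchors].to_numpy(),
                                   m.loc[anchors].to_numpy())
    m_rescaled = m - (intercept + slope * a)
    return m_rescaled, intercept, slope


@dataclass
class DifferentialMarkingCall:
    gene_id: str
    mark: str
    time_h: float
    m_value: float
    a_value: float
    m_rescaled: float
    call: str  # gain | loss | none


def call_marking_changes(m_rescaled: pd.DataFrame,
                         threshold: float = M_THRESHOLD) -> pd.DataFrame:
    """Gain/loss calls from rescaled M values.

    ``m_rescaled``: genes x times (columns = contrast times) for one mark.
    Strict inequality at the boundary.  Returns per-gene calls per time plus
    the first gain and first loss time (inf if none).
    """
    calls = pd.DataFrame("none", index=m_rescaled.index,
                         columns=m_rescaled.columns)
    calls = calls.mask(m_rescaled > threshold, "gain")
    calls = calls.mask(m_rescaled < -threshold, "loss")

    times = np.asarray(m_rescaled.columns, dtype=float)
    gain_mask = (calls == "gain").to_numpy()
    loss_mask = (calls == "loss").to_numpy()

    def first_time(mask: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape[0], np.inf)
        any_row = mask.any(axis=1)
        out[any_row] = times[mask.argmax(axis=1)[any_row]]
        return out

    summary = pd.DataFrame({
        "first_gain_time": first_time(gain_mask),
        "first_loss_time": first_time(loss_mask),
        "differential": gain_mask.any(axis=1) | loss_mask.any(axis=1),
    }, index=m_rescaled.index)
    return calls.join(summary)


def marking_contrast(levels: pd.DataFrame, mark: str, time_h: float,
                     marked_t0: set[str], marked_t: set[str],
                     baseline_time_h: float = 0.0,
                     threshold: float = M_THRESHOLD) -> pd.DataFrame:
    """Full MA pipeline for one mark/time contrast.

    ``levels``: long table (gene_id, mark, time_h, level).  Returns a table
    with M, A, M_rescaled and the gain/loss call per gene.
    """
    sub = levels[levels["mark"] == mark]
    piv = sub.pivot(index="gene_id", columns="time_h", values="level")
    if baseline_time_h not in piv.columns or time_h not in piv.columns:
        raise ValidationError(
            f"levels lack time {baseline_time_h} or {time_h} for {mark}")
    m, a = ma_transform(piv[time_h].to_numpy(), piv[baseline_time_h].to_numpy())
    m = pd.Series(m, index=piv.index)
    a = pd.Series(a, index=piv.index)
    anchors = marked_t0 & marked_t
    m_prime, intercept, slope = rescale_ma(m, a, anchors)
    call = np.where(m_prime > threshold, "gain",
                    np.where(m_prime < -threshold, "loss", "none"))
    return pd.DataFrame({
        "gene_id": piv.index, "mark": mark, "time_h": time_h,
        "M": m.to_numpy(), "A": a.to_numpy(),
        "M_rescaled": m_prime.to_numpy(), "call": call,
        "fit_intercept": intercept, "fit_slope": slope,
    }).set_index("gene_id")


def first_gain_times(contrast_tables: list[pd.DataFrame]) -> pd.Series:
    """First gain time per gene across a mark's time contrasts (inf if none)."""
    merged = pd.concat(contrast_tables)
    gains = merged[merged["call"] == "gain"]
    first = gains.groupby(gains.index)["time_h"].min()
    all_genes = contrast_tables[0].index
    return first.reindex(all_genes).fillna(np.inf).rename("first_gain_time")
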