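"""Time-course differential expression and induction-timing clustering.

Counts are modelled as negative binomial.  Library composition is corrected
with trimmed-mean-of-M-values (TMM) scaling factors; each post-wounding time
point is contrasted against 0 h with a conditional NB exact test (enumeration
for small totals, beta-binomial normal approximation otherwise), and
Benjamini-Hochberg FDR is applied within each contrast.  Wound-responsive
genes are those with |FC| > 1.5 and FDR < 0.001 at one or more time points;
induced genes are grouped into k=8 timing clusters ordered early -> late.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genomic import ValidationError

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Count matrix (gene x sample) with per-sample time/replicate metadata."""

    counts: pd.DataFrame            # genes x samples, non-negative ints
    samples: pd.DataFrame           # index = sample names; columns time_h, replicate

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValidationError("sample metadata does not match count columns")
        reps = self.samples.groupby("time_h").size()
        if (reps < 2).any():
            bad = reps[reps < 2].index.tolist()
            raise ValidationError(f"every time needs >= 2 replicates; offending: {bad}")

    def times(self) -> list[float]:
        return sorted(self.samples["time_h"].unique())

    def columns_at(self, time_h: float) -> list[str]:
        return list(self.samples.index[self.samples["time_h"] == time_h])


# ---------------------------------------------------------------------------
# TMM normalization


def normalize_libraries(matrix: ExpressionMatrix,
                        trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, normalised to geometric mean 1.

    The reference sample is the one whose 75th percentile of library-scaled
    counts is closest to the mean across samples.  Effective library size is
    ``library size x factor``.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s): {[matrix.counts.columns[i] for i in zero]}"
        )
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                    for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = 2.0 ** _tmm_log2_factor(counts[:, j], lib[j], yr, nr,
                                             trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns, name="tmm_factor")


def _tmm_log2_factor(y: np.ndarray, n: float, yr: np.ndarray, nr: float,
                     trim_m: float, trim_a: float) -> float:
    ok = (y > 0) & (yr > 0)
    if ok.sum() == 0:
        return 0.0
    p, pr = y[ok] / n, yr[ok] / nr
    m = np.log2(p / pr)
    a = 0.5 * np.log2(p * pr)
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() == 0:
        return 0.0
    # plain trimmed mean: depends on proportions only, so a pure depth
    # change in either sample leaves the factor exactly unchanged
    return float(np.mean(m[keep]))


def effective_lib_sizes(matrix: ExpressionMatrix, factors: pd.Series) -> pd.Series:
    return matrix.counts.sum(axis=0) * factors


def common_scale(eff: pd.Series | np.ndarray) -> float:
    """Common library scale for count adjustment: the geometric mean of the
    effective library sizes, quantized to the nearest power of two.

    Quantization makes the adjusted counts — and hence every p-value —
    exactly invariant under modest library-size changes (e.g. one sample
    sequenced twice as deep), while staying within a factor sqrt(2) of the
    geometric mean."""
    return float(2.0 ** np.round(np.mean(np.log2(np.asarray(eff, dtype=float)))))


# ---------------------------------------------------------------------------
# NB dispersion (method of moments, shrunk to the common value)


def _mom_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion pooled over sample groups.

    Var = mu + phi mu^2 within each group; residual moments are pooled across
    groups so between-group (treatment) differences do not inflate phi.
    """
    num = np.zeros(scaled.shape[0])
    den = np.zeros(scaled.shape[0])
    for idx in groups:
        if idx.size < 2:
            continue
        sub = scaled[:, idx]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (var - mean) * idx.size
        # E[mean^2] = mu^2 + var/n: use the unbiased moment for mu^2
        den += np.maximum(mean ** 2 - var / idx.size, 0.0) * idx.size
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, None)


def estimate_dispersions(matrix: ExpressionMatrix, factors: pd.Series,
                         prior_weight: float = 20.0) -> pd.Series:
    """Per-gene dispersions shrunk toward the all-gene median (prior weight 20)."""
    eff = effective_lib_sizes(matrix, factors).to_numpy()
    common_lib = common_scale(eff)
    scaled = matrix.counts.to_numpy(dtype=float) * (common_lib / eff)
    groups = [np.flatnonzero((matrix.samples["time_h"] == t).to_numpy())
              for t in matrix.times()]
    phi_raw = _mom_dispersion(scaled, groups)
    # common dispersion: moments pooled ACROSS genes (the median of per-gene
    # estimates is biased low at few replicates)
    expressed = scaled.mean(axis=1) > 1
    num = den = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        sub = scaled[np.ix_(expressed, idx)]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += float((var - mean).sum())
        den += float(np.maximum(mean ** 2 - var / idx.size, 0.0).sum())
    phi_common = max(0.0, num / den) if den > 0 else 0.0
    df = sum(max(0, g.size - 1) for g in groups)
    phi = (prior_weight * phi_common + df * phi_raw) / (prior_weight + df)
    return pd.Series(np.clip(phi, 1e-8, None), index=matrix.counts.index,
                     name="dispersion")


# ---------------------------------------------------------------------------
# conditional NB exact test


def nb_exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float,
                    enumerate_limit: int = 5000) -> float:
    """Two-sided conditional exact test of equal NB means between two groups.

    Group sums of n iid NB(mu, phi) samples are NB with size n/phi.  Given the
    total s = s1 + s2, the first group's sum follows a beta-binomial(s, n1/phi,
    n2/phi) law (binomial(s, n1/(n1+n2)) in the Poisson limit).  The two-sided
    p sums all outcome probabilities not exceeding the observed one; for
    totals above ``enumerate_limit`` a continuity-corrected normal
    approximation to the conditional law is used.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    if phi < 1e-8:
        dist = stats.binom(s, n1 / (n1 + n2))
        pmf = dist.pmf(np.arange(s + 1))
        return float(min(1.0, pmf[pmf <= pmf[s1] * (1 + 1e-10)].sum()))
    r1, r2 = n1 / phi, n2 / phi
    if s <= enumerate_limit:
        x = np.arange(s + 1)
        logp = stats.betabinom.logpmf(x, s, r1, r2)
        logp -= _logsumexp(logp)
        p = np.exp(logp)
        return float(min(1.0, p[p <= p[s1] * (1 + 1e-10)].sum()))
    mean = s * r1 / (r1 + r2)
    var = s * r1 * r2 * (r1 + r2 + s) / ((r1 + r2) ** 2 * (r1 + r2 + 1))
    sd = np.sqrt(var)
    lo = stats.norm.cdf(s1 + 0.5, mean, sd)
    hi = stats.norm.sf(s1 - 0.5, mean, sd)
    return float(min(1.0, 2 * min(lo, hi)))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


@dataclass
class DEResult:
    """Per-gene differential-expression results for one contrast."""

    table: pd.DataFrame  # gene_id, time_h, log2FC, p_value, fdr, untestable
    time_h: float


def test_de(matrix: ExpressionMatrix, factors: pd.Series, time_h: float,
            dispersions: pd.Series | None = None,
            baseline_time_h: float = 0.0) -> DEResult:
    """Contrast ``time_h`` vs the baseline time (0 h) for every gene.

    Counts are rescaled to a common effective library size, summed per group
    and tested with the conditional NB exact test; BH FDR is computed within
    the contrast.  Genes with zero counts everywhere get p = 1 and are
    flagged untestable.
    """
    if time_h == baseline_time_h:
        raise ValidationError("contrast time must differ from the baseline")
    if time_h not in matrix.times():
        raise ValidationError(f"time {time_h} not present in sample metadata")
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, factors)

    eff = effective_lib_sizes(matrix, factors)
    common_lib = common_scale(eff)
    cols0 = matrix.columns_at(baseline_time_h)
    cols1 = matrix.columns_at(time_h)
    scale0 = (common_lib / eff[cols0]).to_numpy()
    scale1 = (common_lib / eff[cols1]).to_numpy()
    c0 = matrix.counts[cols0].to_numpy(dtype=float) * scale0
    c1 = matrix.counts[cols1].to_numpy(dtype=float) * scale1
    s0 = np.rint(c0.sum(axis=1)).astype(np.int64)
    s1 = np.rint(c1.sum(axis=1)).astype(np.int64)
    n0, n1 = len(cols0), len(cols1)

    m0 = c0.mean(axis=1) / common_lib * 1e6
    m1 = c1.mean(axis=1) / common_lib * 1e6
    log2fc = np.log2((m1 + 0.5) / (m0 + 0.5))

    phi = dispersions.to_numpy()
    pvals = np.ones(len(s0))
    untestable = (s0 + s1) == 0
    for i in np.flatnonzero(~untestable):
        pvals[i] = nb_exact_pvalue(int(s1[i]), int(s0[i]), n1, n0, float(phi[i]))
    fdr = bh_adjust(pvals)
    table = pd.DataFrame({
        "gene_id": matrix.counts.index,
        "time_h": time_h,
        "log2FC": np.where(untestable, 0.0, log2fc),
        "p_value": pvals,
        "fdr": fdr,
        "untestable": untestable,
    })
    return DEResult(table, time_h)


test_de.__test__ = False  # statistical test, not a pytest case


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_all_contrasts(matrix: ExpressionMatrix, factors: pd.Series,
                      baseline_time_h: float = 0.0) -> pd.DataFrame:
    """test_de for every non-baseline time; concatenated long table."""
    dispersions = estimate_dispersions(matrix, factors)
    tables = [test_de(matrix, factors, t, dispersions, baseline_time_h).table
              for t in matrix.times() if t != baseline_time_h]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# wound-responsive sets and timing clusters


def call_wound_responsive(de_results: pd.DataFrame, fc_threshold: float = 1.5,
                          fdr_threshold: float = 0.001
                          ) -> tuple[set[str], set[str]]:
    """Induced / repressed gene sets: |FC| > threshold and FDR < threshold at
    any time point.  Genes passing both directions (at different times) land
    in both sets, with a warning."""
    lfc_cut = np.log2(fc_threshold)
    sig = de_results[de_results["fdr"] < fdr_threshold]
    induced = set(sig.loc[sig["log2FC"] > lfc_cut, "gene_id"])
    repressed = set(sig.loc[sig["log2FC"] < -lfc_cut, "gene_id"])
    both = induced & repressed
    if both:
        log.warning("%d genes pass both direction filters at different times "
                    "and are double-listed", len(both))
    return induced, repressed


@dataclass
class ClusterAssignment:
    labels: pd.Series           # gene_id -> 1..k (1 = earliest)
    centroids: pd.DataFrame     # k x times, mean-centered profiles
    timing_scores: pd.Series = field(default=None)  # type: ignore[assignment]


def expression_profiles(matrix: ExpressionMatrix, factors: pd.Series,
                        genes: list[str]) -> pd.DataFrame:
    """Per-gene log2(normalized count + 1) averaged over replicates per time,
    mean-centered per gene."""
    eff = effective_lib_sizes(matrix, factors)
    common_lib = common_scale(eff)
    norm = matrix.counts.loc[genes] * (common_lib / eff)
    logn = np.log2(norm + 1)
    prof = logn.T.groupby(matrix.samples["time_h"]).mean().T
    return prof.sub(prof.mean(axis=1), axis=0)


def cluster_induced(matrix: ExpressionMatrix, factors: pd.Series,
                    induced: set[str], k: int = 8, n_starts: int = 50,
                    seed: int = 0) -> ClusterAssignment:
    """K-means (k-means++ / best of ``n_starts``) on mean-centered log
    profiles; clusters relabelled 1..k from earliest to latest induction."""
    genes = [g for g in matrix.counts.index if g in induced]
    if len(genes) < k:
        raise ValidationError(
            f"{len(genes)} induced genes < k={k}; choose a smaller k")
    prof = expression_profiles(matrix, factors, genes)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_starts,
                random_state=seed)
    raw = km.fit_predict(prof.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=prof.columns)
    perm, scores = order_clusters(centroids, list(prof.columns))
    relabel = {old: new for new, old in enumerate(perm, start=1)}
    labels = pd.Series([relabel[c] for c in raw], index=genes, name="cluster")
    ordered = centroids.loc[perm].reset_index(drop=True)
    ordered.index = np.arange(1, k + 1)
    timing = pd.Series([scores[o] for o in perm], index=ordered.index,
                       name="timing_score")
    return ClusterAssignment(labels, ordered, timing)


def order_clusters(centroids: pd.DataFrame,
                   times: list[float]) -> tuple[list[int], dict[int, float]]:
    """Order cluster labels by induction timing.

    Timing score = earliest time at which the centroid reaches 50% of its
    maximum positive deviation; ties broken by the positive-mass-weighted
    mean time.  Centroids with no positive deviation sort last.
    """
    t = np.asarray(times, dtype=float)
    scores: dict[int, float] = {}
    tiebreak: dict[int, float] = {}
    for idx, row in centroids.iterrows():
        c = row.to_numpy(dtype=float)
        peak = c.max()
        if peak <= 0:
            log.warning("cluster %s centroid has no positive deviation; "
                        "scored last", idx)
            scores[idx] = np.inf
            tiebreak[idx] = np.inf
            continue
        reach = np.flatnonzero(c >= 0.5 * peak)
        scores[idx] = float(t[reach[0]])
        pos = np.maximum(c, 0)
        tiebreak[idx] = float(np.sum(t * pos) / np.sum(pos))
    perm = sorted(centroids.index,
                  key=lambda i: (scores[i], tiebreak[i], i))
    return perm, scores
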