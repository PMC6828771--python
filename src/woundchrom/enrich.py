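"""Representation factors and hypergeometric over/under-representation.

The representation factor of a category within a query set is
(k/n)/(K/N): the observed overlap divided by the overlap expected under
independence within a stated universe.  Both one-sided hypergeometric tails
are reported (they share P[X = k], so p_over + p_under >= 1), with star
annotations on the side the representation factor points to.  The universe
is always an explicit argument — different analyses legitimately use
different universes (all genes, marked genes only, all induced genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import ValidationError

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int          # overlap
    n: int          # query-set size
    K: int          # category size in universe
    N: int          # universe size
    representation_factor: float
    p_over: float   # P[X >= k]
    p_under: float  # P[X <= k]

    @property
    def stars(self) -> str:
        p = self.p_over if self.representation_factor >= 1 else self.p_under
        return "*" * sum(p < t for t in STAR_THRESHOLDS)


def representation_factor(k: int, n: int, K: int, N: int,
                          category: str = "") -> EnrichmentResult:
    """RF = (k/n)/(K/N) with exact hypergeometric tail probabilities."""
    for name, lo, val, hi in (("k<=n", 0, k, n), ("n<=N", 0, n, N),
                              ("k<=K", 0, k, K), ("K<=N", 0, K, N)):
        if not (lo <= val <= hi):
            raise ValidationError(f"constraint {name} violated: "
                                  f"k={k}, n={n}, K={K}, N={N}")
    rf = (k / n) / (K / N) if (n and K) else 0.0
    dist = stats.hypergeom(N, K, n)
    p_over = float(min(1.0, dist.sf(k - 1)))
    p_under = float(min(1.0, dist.cdf(k)))
    return EnrichmentResult(category, k, n, K, N, rf, p_over, p_under)


def _as_set(x: Iterable[str]) -> set[str]:
    return x if isinstance(x, set) else set(x)


def mark_enrichment(marked: pd.DataFrame, query: Iterable[str],
                    universe: Iterable[str]) -> pd.DataFrame:
    """Per-mark representation of the query set among marked genes.

    ``marked``: genes x marks boolean table.  Also reports the percentage of
    each mark's genes falling in the query (100*k/K).
    """
    query, universe = _as_set(query), _as_set(universe)
    missing = query - universe
    if missing:
        raise ValidationError(
            f"{len(missing)} query genes absent from universe, e.g. "
            f"{sorted(missing)[:3]}")
    uni_marked = marked.loc[marked.index.isin(universe)]
    rows = []
    for mark in marked.columns:
        mark_set = set(uni_marked.index[uni_marked[mark]])
        res = representation_factor(len(query & mark_set), len(query),
                                    len(mark_set), len(universe), mark)
        rows.append({
            "category": mark, "k": res.k, "n": res.n, "K": res.K, "N": res.N,
            "representation_factor": res.representation_factor,
            "p_over": res.p_over, "p_under": res.p_under, "stars": res.stars,
            "pct_of_marked_in_query":
                100.0 * res.k / res.K if res.K else np.nan,
        })
    return pd.DataFrame(rows).set_index("category")


def comark_enrichment(marked: pd.DataFrame, query: Iterable[str],
                      pairs: Sequence[tuple[str, str]] | None = None
                      ) -> pd.DataFrame:
    """Co-marking representation among *marked* genes.

    The universe is the set of genes bearing >= 1 mark (as in co-marking
    heat maps); for each mark pair, RF of the pair's co-occurrence among
    query-set marked genes vs among all marked genes.
    """
    bearer = marked.any(axis=1)
    universe = set(marked.index[bearer])
    if not universe:
        raise ValidationError("no marked genes: empty universe")
    query_marked = _as_set(query) & universe
    if pairs is None:
        cols = list(marked.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rows = []
    for a, b in pairs:
        co = set(marked.index[marked[a] & marked[b]]) & universe
        res = representation_factor(len(query_marked & co), len(query_marked),
                                    len(co), len(universe), f"{a}+{b}")
        rows.append({
            "category": res.category, "k": res.k, "n": res.n,
            "K": res.K, "N": res.N,
            "representation_factor": res.representation_factor,
            "p_over": res.p_over, "p_under": res.p_under, "stars": res.stars,
        })
    return pd.DataFrame(rows).set_index("category")


def cluster_category_enrichment(categories: pd.Series,
                                clusters: pd.Series) -> pd.DataFrame:
    """Representation of each category within each timing cluster.

    Universe = all clustered (induced) genes; wedge radius semantics: RF = 1
    is the reference circle, RF > 1 over-represented.
    """
    common = categories.index.intersection(clusters.index)
    missing = clusters.index.difference(categories.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} clustered genes lack a category")
    cat = categories.loc[common]
    clu = clusters.loc[common]
    N = len(common)
    rows = []
    for c in sorted(clu.unique()):
        in_c = set(common[clu == c])
        for g in sorted(cat.unique()):
            in_g = set(common[cat == g])
            res = representation_factor(len(in_c & in_g), len(in_c),
                                        len(in_g), N, str(g))
            rows.append({
                "cluster": c, "category": g, "k": res.k, "n": res.n,
                "K": res.K, "N": res.N,
                "representation_factor": res.representation_factor,
                "p_over": res.p_over, "p_under": res.p_under,
                "stars": res.stars,
            })
    return pd.DataFrame(rows)


def compare_level_distributions(levels: pd.Series, set_a: Iterable[str],
                                set_b: Iterable[str]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of enrichment levels.

    Exact distribution for combined n <= 20, tie-corrected normal
    approximation otherwise.  Sets must be disjoint, each with >= 3 members.
    """
    a, b = _as_set(set_a), _as_set(set_b)
    if a & b:
        raise ValidationError(f"sets overlap in {len(a & b)} genes")
    xa = levels.loc[levels.index.isin(a)].to_numpy()
    xb = levels.loc[levels.index.isin(b)].to_numpy()
    if len(xa) < 3 or len(xb) < 3:
        raise ValidationError("need >= 3 genes per set")
    method = "exact" if len(xa) + len(xb) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def term_enrichment(annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
                    query: Iterable[str],
                    universe: Iterable[str]) -> pd.DataFrame:
    """Generic term (e.g. GO) over-representation with BH correction.

    ``annotation``: gene -> terms mapping, or a 2-column (gene, term) frame.
    Terms with zero overlap are reported with p = 1.
    """
    from .expression import bh_adjust

    if isinstance(annotation, pd.DataFrame):
        gene_col, term_col = annotation.columns[:2]
        mapping: dict[str, set[str]] = {}
        for g, t in zip(annotation[gene_col], annotation[term_col]):
            mapping.setdefault(g, set()).add(t)
    else:
        mapping = {g: set(ts) for g, ts in annotation.items()}
    query, universe = _as_set(query), _as_set(universe)
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in mapping.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for term in sorted(term_genes):
        tg = term_genes[term]
        res = representation_factor(len(query & tg), len(query), len(tg),
                                    len(universe), term)
        rows.append({
            "category": term, "k": res.k, "n": res.n, "K": res.K, "N": res.N,
            "representation_factor": res.representation_factor,
            "p_over": 1.0 if res.k == 0 else res.p_over,
            "p_under": res.p_under,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p_over"].to_numpy())
        table = table.set_index("category")
    return table


def enrichment_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")
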