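"""Exact hypergeometric over/under-representation statistics.

Given a query gene set of size n drawn from a universe of size N containing a
category of size K, the overlap k under the null of uniform draws follows the
hypergeometric distribution.  The enrichment p-value is the exact upper tail
P(X >= k), the depletion p-value the exact lower tail P(X <= k), and the
enrichment factor (k/n) / (K/N) — the observed category fraction in the query
over its fraction in the universe.  Benjamini-Hochberg adjustment is applied
within each analysis batch; raw p-values are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_tails",
    "hypergeom_enrichment",
    "set_overlap_test",
    "bicluster_class_enrichment",
]


@dataclass
class EnrichmentResult:
    """One query-vs-category contingency outcome with exact tail p-values."""

    set_label: str
    category: str
    universe_size: int
    category_size: int
    query_size: int
    overlap: int
    factor: float          # NaN when K = 0 or n = 0
    p_enrichment: float    # upper tail P(X >= k)
    p_depletion: float     # lower tail P(X <= k)
    q_enrichment: float = float("nan")
    q_depletion: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "set": self.set_label,
            "category": self.category,
            "N": self.universe_size,
            "K": self.category_size,
            "n": self.query_size,
            "k": self.overlap,
            "factor": self.factor,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "q_enrichment": self.q_enrichment,
            "q_depletion": self.q_depletion,
        }


def hypergeom_tails(N: int, K: int, n: int, k):
    """Exact hypergeometric tail probabilities (P(X >= k), P(X <= k)).

    ``k`` may be a scalar or an array.  Tails are full sums over the
    hypergeometric pmf, no approximation.
    """
    rv = st.hypergeom(N, K, n)
    k = np.asarray(k)
    return rv.sf(k - 1), rv.cdf(k)


def _one_result(set_label: str, category: str, N: int, K: int, n: int, k: int) -> EnrichmentResult:
    if N <= 0:
        raise ValueError("empty universe")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent contingency: k={k}, K={K}, n={n}")
    if k < max(0, n + K - N):
        raise ValueError(
            f"impossible configuration: overlap {k} below forced minimum {n + K - N} "
            f"(n={n}, K={K}, N={N})"
        )
    up, down = hypergeom_tails(N, K, n, k)
    p_up, p_down = float(up), float(down)
    factor = (k / n) / (K / N) if (K > 0 and n > 0) else float("nan")
    return EnrichmentResult(set_label, category, N, K, n, k,
                            factor, min(p_up, 1.0), min(p_down, 1.0))


def _adjust(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    for attr_p, attr_q in (("p_enrichment", "q_enrichment"), ("p_depletion", "q_depletion")):
        pvals = [getattr(r, attr_p) for r in results]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            setattr(r, attr_q, float(q))
    return results


def hypergeom_enrichment(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    set_label: str = "query",
) -> pd.DataFrame:
    """Exact enrichment/depletion of each category in ``query``.

    The batch of categories is BH-adjusted together (both tails separately).
    Returns one row per category with all :class:`EnrichmentResult` fields.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    results = []
    for label, members in categories.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"category {label!r} has genes outside universe")
        results.append(
            _one_result(set_label, label, len(universe), len(members),
                        len(query), len(query & members))
        )
    _adjust(results)
    return pd.DataFrame([r.as_dict() for r in results])


def set_overlap_test(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> EnrichmentResult:
    """Exact two-set overlap test (both tails), symmetric in A and B."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    for name, s in (("A", a), ("B", b)):
        if not s <= universe:
            raise ValueError(f"set {name} has genes outside universe")
    return _one_result("A_vs_B", "overlap", len(universe), len(b), len(a), len(a & b))


def bicluster_class_enrichment(
    biclusters,
    calls: pd.DataFrame,
    universe: Iterable[str] | None = None,
    target_class: str = "conserved_multicopy",
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-bicluster x per-orthology-class enrichment batch.

    ``calls`` is the per-gene frame of an :class:`~devdup.orthology.OrthologyResults`
    (index gene, column ``class``).  The universe defaults to all genes with
    a call.  All bicluster-class pairs are BH-adjusted as one batch.  The
    summary counts biclusters whose ``target_class`` enrichment q-value is
    below ``q_threshold``.
    """
    universe = set(universe) if universe is not None else set(calls.index)
    class_sets = {
        cls: set(calls.index[calls["class"] == cls]) & universe
        for cls in calls["class"].unique()
    }
    results: list[EnrichmentResult] = []
    for i, bc in enumerate(biclusters):
        genes = set(bc.genes)
        outside = genes - universe
        if outside:
            raise ValueError(
                f"bicluster {i} has genes outside universe: {sorted(outside)[:5]}"
            )
        for cls in sorted(class_sets):
            results.append(
                _one_result(f"bicluster_{i}", cls, len(universe),
                            len(class_sets[cls]), len(genes), len(genes & class_sets[cls]))
            )
    _adjust(results)
    table = pd.DataFrame([r.as_dict() for r in results])
    if len(table):
        target = table[table["category"] == target_class]
        n_sig = int((target["q_enrichment"] < q_threshold).sum())
        n_bc = target["set"].nunique()
    else:
        n_sig, n_bc = 0, 0
    summary = {
        "target_class": target_class,
        "q_threshold": q_threshold,
        "n_biclusters": n_bc,
        "n_significant": n_sig,
    }
    return table, summary
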