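"""Pairwise differential-expression calls and downstream gene sets.

The study's DE caller (Cuffdiff in blind mode) is an external black box; this
module replaces it with a declared, transparent rule: a gene is called up
(+1) in sample j relative to sample i when log2((x_j + c) / (x_i + c)) >= tau,
down (-1) when <= -tau, and 0 otherwise, with genes below an expression floor
in both samples forced to 0.  When replicate groups are supplied, a
two-sample t-test on log2(x + c) with Benjamini-Hochberg control within each
comparison gates the calls.  The downstream computations (ternary matrix,
biclustering, housekeeping/regulated sets) consume only the ternary calls,
so the caller is a pluggable boundary — a precomputed ternary matrix can be
loaded instead.

Orientation convention: for the ordered pair (i, j) with i earlier in sample
file order, +1 means up in j relative to i.  For 10 samples there are 45
ordered pairs, in lexicographic (combinations) order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionTable

__all__ = [
    "DECallConfig",
    "HousekeepingConfig",
    "TernaryDEMatrix",
    "pair_label",
    "call_pairwise_de",
    "housekeeping_genes",
    "regulated_genes",
    "wilcoxon_ranksum_p",
    "stage_specificity_stat",
    "OverviewReport",
    "sample_overview",
]

PAIR_SEP = "|"


@dataclass(frozen=True)
class DECallConfig:
    """Thresholds of the fold-change DE caller (stand-in for Cuffdiff)."""

    fdr_threshold: float = 0.01
    log2fc_threshold: float = 1.0
    pseudocount: float = 1.0
    expression_floor: float = 1.0

    def __post_init__(self):
        for name in ("fdr_threshold", "log2fc_threshold", "pseudocount", "expression_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HousekeepingConfig:
    """Robust-expression floor for the housekeeping rule (FPKM >= 10)."""

    floor: float = 10.0

    def __post_init__(self):
        if self.floor <= 0:
            raise ValueError("floor must be positive")


def pair_label(i: str, j: str) -> str:
    return f"{i}{PAIR_SEP}{j}"


@dataclass
class TernaryDEMatrix:
    """Genes x ordered-sample-pair matrix with entries in {-1, 0, +1}.

    Columns are labelled ``"i|j"`` for the ordered pair (i, j), i before j in
    sample file order; +1 means up in j relative to i.
    """

    data: pd.DataFrame
    samples: list[str]

    def __post_init__(self):
        vals = self.data.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("ternary matrix entries must be in {-1, 0, +1}")
        self.data = self.data.astype(np.int8)
        # columns must be ordered (i, j) pairs, i before j in sample file
        # order, listed in lexicographic combination order (a full matrix
        # over n samples has n*(n-1)/2 of them, 45 for n = 10)
        valid = [pair_label(i, j) for i, j in itertools.combinations(self.samples, 2)]
        pos = {c: k for k, c in enumerate(valid)}
        cols = list(self.data.columns)
        if any(c not in pos for c in cols) or len(set(cols)) != len(cols):
            raise ValueError("ternary matrix columns do not match ordered sample pairs")
        if any(pos[a] >= pos[b] for a, b in zip(cols, cols[1:])):
            raise ValueError("ternary matrix columns out of pair order")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(c.split(PAIR_SEP)) for c in self.data.columns]

    def de_counts(self) -> pd.DataFrame:
        """Symmetric sample x sample matrix of DE-gene counts per pair."""
        n = len(self.samples)
        counts = pd.DataFrame(0, index=self.samples, columns=self.samples, dtype=int)
        nz = (self.data.to_numpy() != 0).sum(axis=0)
        for (i, j), c in zip(self.pairs, nz):
            counts.loc[i, j] = counts.loc[j, i] = int(c)
        return counts

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, samples: Sequence[str] | None = None) -> "TernaryDEMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if samples is None:
            # reconstruct sample order from the first-sample sweep of columns
            seen: list[str] = []
            for col in df.columns:
                i, j = col.split(PAIR_SEP)
                for s in (i, j):
                    if s not in seen:
                        seen.append(s)
            samples = seen
        return cls(df, list(samples))


def call_pairwise_de(
    expr: ExpressionTable,
    cfg: DECallConfig | None = None,
    replicate_groups: Mapping[str, str] | None = None,
) -> TernaryDEMatrix:
    """Ternary DE calls over all ordered sample pairs.

    Without replicate groups each column of ``expr`` is one condition and the
    fold-change rule applies directly.  With ``replicate_groups`` (sample ->
    group label) the conditions are the groups, the fold change is computed
    on group means, and a two-sample t-test on log2(x + c) across replicate
    columns gates the calls at BH-adjusted ``fdr_threshold`` within each
    comparison.
    """
    cfg = cfg or DECallConfig()
    if replicate_groups is None:
        conditions = expr.samples
        cols = {s: [s] for s in conditions}
    else:
        missing = [s for s in expr.samples if s not in replicate_groups]
        if missing:
            raise ValueError(f"replicate_groups does not cover samples: {missing}")
        conditions, cols = [], {}
        for s in expr.samples:
            g = replicate_groups[s]
            if g not in cols:
                conditions.append(g)
                cols[g] = []
            cols[g].append(s)
    if len(conditions) < 2:
        raise ValueError("need at least 2 samples/conditions for pairwise DE")

    X = expr.values
    logx = np.log2(X.to_numpy(dtype=float) + cfg.pseudocount)
    mean_log = {c: logx[:, [X.columns.get_loc(s) for s in cols[c]]].mean(axis=1) for c in conditions}
    mean_raw = {c: X[cols[c]].mean(axis=1).to_numpy() for c in conditions}

    out = {}
    for i, j in itertools.combinations(conditions, 2):
        lfc = mean_log[j] - mean_log[i]
        call = np.where(lfc >= cfg.log2fc_threshold, 1, np.where(lfc <= -cfg.log2fc_threshold, -1, 0))
        low = (mean_raw[i] < cfg.expression_floor) & (mean_raw[j] < cfg.expression_floor)
        call[low] = 0
        if replicate_groups is not None and min(len(cols[i]), len(cols[j])) >= 2:
            a = logx[:, [X.columns.get_loc(s) for s in cols[i]]]
            b = logx[:, [X.columns.get_loc(s) for s in cols[j]]]
            with np.errstate(invalid="ignore", divide="ignore"):
                _, pvals = st.ttest_ind(b, a, axis=1, equal_var=False)
            pvals = np.where(np.isnan(pvals), 1.0, pvals)
            reject, _, _, _ = multipletests(pvals, alpha=cfg.fdr_threshold, method="fdr_bh")[:4]
            call[~reject] = 0
        out[pair_label(i, j)] = call
    df = pd.DataFrame(out, index=X.index)
    return TernaryDEMatrix(df, list(conditions))


def housekeeping_genes(
    expr: ExpressionTable,
    de: TernaryDEMatrix,
    cfg: HousekeepingConfig | None = None,
) -> set[str]:
    """Genes with every expression value >= floor and an all-zero ternary row."""
    cfg = cfg or HousekeepingConfig()
    if set(expr.genes) != set(de.genes):
        raise ValueError("expression table and DE matrix cover different gene universes")
    robust = (expr.values >= cfg.floor).all(axis=1)
    never_de = (de.data.loc[expr.values.index] == 0).all(axis=1)
    return set(expr.values.index[robust & never_de])


def regulated_genes(biclusters: Iterable) -> set[str]:
    """Union of member genes over all biclusters (idempotent)."""
    out: set[str] = set()
    for bc in biclusters:
        out.update(bc.genes)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with exact small-sample null


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p via subset-sum DP over doubled midranks.

    The null is the permutation distribution of the rank sum of the first
    sample over all C(n1+n2, n1) assignments of the pooled (midrank-tied)
    values; p = P(|W - E W| >= |w_obs - E W|).  Doubling the midranks makes
    every rank an integer so the DP and the comparison are exact.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    r2 = np.rint(2.0 * st.rankdata(pooled)).astype(np.int64)  # doubled midranks
    w_obs = int(r2[:n1].sum())
    total = int(r2.sum())
    n = n1 + n2
    max_sum = total
    # dp[m, s] = number of size-m subsets of the pooled doubled ranks with sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for v in r2:
        for m in range(n1, 0, -1):  # descending so each item is used once
            dp[m, v:] += dp[m - 1, : max_sum + 1 - v]
    counts = dp[n1]
    # compare |s*n - n1*total| >= |w*n - n1*total| in exact integer arithmetic
    dev_obs = abs(w_obs * n - n1 * total)
    sums = np.arange(max_sum + 1, dtype=np.int64)
    extreme = np.abs(sums * n - n1 * total) >= dev_obs
    return float(counts[extreme].sum() / comb(n, n1))


def wilcoxon_ranksum_p(x, y, exact_max: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation null (tie-aware, via midranks) when both sides have at
    most ``exact_max`` values; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) <= exact_max and len(y) <= exact_max:
        return _exact_ranksum_p(x, y)
    return float(st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def stage_specificity_stat(
    values_by_sample: Mapping[str, Sequence[float]] | pd.DataFrame,
    stage_groups: Mapping[str, str],
) -> float:
    """Maximum Wilcoxon p over all cross-stage comparisons, in [0, 1].

    ``values_by_sample`` holds the distribution of a gene set's expression in
    each sample (a mapping sample -> values, or a genes x samples frame).
    Values are pooled within each stage group; every pair of stages is
    compared by a two-sided Wilcoxon rank-sum test and the maximum p is
    returned — the statistic is small only when *every* stage differs from
    every other.
    """
    if isinstance(values_by_sample, pd.DataFrame):
        values_by_sample = {s: values_by_sample[s].to_numpy() for s in values_by_sample.columns}
    stages: dict[str, list[float]] = {}
    for sample, vals in values_by_sample.items():
        g = stage_groups.get(sample)
        if g is None:
            raise ValueError(f"sample {sample!r} has no stage group")
        stages.setdefault(g, []).extend(np.asarray(vals, dtype=float).ravel())
    if len(stages) < 2:
        raise ValueError("need at least 2 stage groups")
    for g, vals in stages.items():
        if len(vals) == 0:
            raise ValueError(f"stage {g!r} has zero samples")
    pmax = 0.0
    for a, b in itertools.combinations(sorted(stages), 2):
        pmax = max(pmax, wilcoxon_ranksum_p(stages[a], stages[b]))
    return pmax


# ---------------------------------------------------------------------------
# sample-level overview


@dataclass
class OverviewReport:
    """Sample-level summaries of a timecourse expression experiment.

    spearman: sample x sample Spearman correlations of expression (NaN for
    flagged constant samples); pca_variance_fractions and pca_coords from a
    PCA of samples on (centred) expression of genes passing the positivity
    filter; de_counts and a hierarchical clustering (average linkage on
    Euclidean distances between rows of the DE-count matrix).
    """

    spearman: pd.DataFrame
    constant_samples: list[str]
    pca_variance_fractions: np.ndarray
    pca_coords: pd.DataFrame
    n_genes_pca: int
    de_counts: pd.DataFrame
    linkage: np.ndarray
    dendrogram_newick: str


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = sch.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def sample_overview(
    expr: ExpressionTable,
    de: TernaryDEMatrix,
    pca_gene_filter: str = "all",
) -> OverviewReport:
    """Spearman correlations, PCA and DE-count clustering of the samples.

    ``pca_gene_filter`` selects genes with expression > 0 in ``"all"``
    samples (default) or in ``"any"`` sample before the PCA, mirroring the
    "FPKM > 0" convention of timecourse overviews.
    """
    X = expr.values
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for an overview")
    arr = X.to_numpy(dtype=float)

    constant = [s for k, s in enumerate(X.columns) if np.ptp(arr[:, k]) == 0.0]
    rho = X.corr(method="spearman")
    for s in constant:
        rho.loc[s, :] = np.nan
        rho.loc[:, s] = np.nan

    if pca_gene_filter == "all":
        keep = (arr > 0).all(axis=1)
    elif pca_gene_filter == "any":
        keep = (arr > 0).any(axis=1)
    else:
        raise ValueError("pca_gene_filter must be 'all' or 'any'")
    sub = arr[keep].T  # samples x genes
    centred = sub - sub.mean(axis=0, keepdims=True)
    _, svals, _ = np.linalg.svd(centred, full_matrices=False)
    var = svals**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    u, s_, vt = np.linalg.svd(centred, full_matrices=False)
    coords = u * s_
    n_pc = min(len(frac), X.shape[1] - 1)
    pca_coords = pd.DataFrame(
        coords[:, :n_pc], index=X.columns, columns=[f"PC{i+1}" for i in range(n_pc)]
    )

    counts = de.de_counts()
    dist = ssd.pdist(counts.to_numpy(dtype=float), metric="euclidean")
    Z = sch.linkage(dist, method="average")
    newick = _linkage_to_newick(Z, list(counts.index))
    return OverviewReport(
        spearman=rho,
        constant_samples=constant,
        pca_variance_fractions=frac[:n_pc],
        pca_coords=pca_coords,
        n_genes_pca=int(keep.sum()),
        de_counts=counts,
        linkage=Z,
        dendrogram_newick=newick,
    )
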