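"""SAMBA-style biclustering of a ternary differential-expression matrix.

A bicluster is a gene subset G, a comparison subset C and a sign s_c in
{-1, +1} per included comparison; its additive score is

    score = sum over (g, c) in G x C of  { +a  if x_gc = s_c
                                           -b  if x_gc = 0
                                           -d  if x_gc = -s_c }

with match weight a, zero penalty b and mismatch penalty d.  The search is a
deterministic greedy local search: seeds are (i) every gene pair together
with the comparisons on which the two genes carry equal nonzero entries and
(ii) optionally every single gene with its nonzero comparison set; from each
seed the single best-scoring addition or removal of one gene or one
comparison is applied until no move improves the score.  Local optima with
score >= theta and the size floors survive a redundancy filter (descending
score, drop when the gene-set Jaccard with an already-kept bicluster exceeds
``max_overlap_jaccard``) — surviving biclusters may still overlap, as
developmental modules do.

This scoring is SAMBA-inspired, not SAMBA-identical: the likelihood-derived
edge weights of the original algorithm are replaced by fixed weights, so
full-data benchmark counts from the literature are not exact targets here.
All tie-breaking (seed order, equal-score moves, sign ties) is lexicographic
by gene/comparison position, making the output a pure function of matrix and
config.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import TernaryDEMatrix, stage_specificity_stat
from .formats import ExpressionTable

__all__ = [
    "Bicluster",
    "BiclusterConfig",
    "BiclusterModel",
    "BiclusterResults",
    "score_bicluster",
    "find_biclusters",
    "bicluster_stage_profile",
    "brute_force_best_score",
]


@dataclass(frozen=True)
class BiclusterConfig:
    """Weights, size floors and seed strategy of the greedy search."""

    match_weight: float = 1.0
    zero_penalty: float = 1.0
    mismatch_penalty: float = 2.0
    min_genes: int = 5
    min_comparisons: int = 3
    score_threshold: float = 10.0
    max_overlap_jaccard: float = 0.75
    include_singleton_seeds: bool = True
    prune_contained_seeds: bool = True

    def __post_init__(self):
        if min(self.match_weight, self.zero_penalty, self.mismatch_penalty) <= 0:
            raise ValueError("weights a, b, d must be positive")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if not (0.0 < self.max_overlap_jaccard <= 1.0):
            raise ValueError("max_overlap_jaccard must be in (0, 1]")
        if self.min_genes < 1 or self.min_comparisons < 1:
            raise ValueError("size floors must be >= 1")


@dataclass
class Bicluster:
    """A gene subset, comparison subset, per-comparison signs and a score."""

    genes: list[str]
    comparisons: list[str]
    signs: dict[str, int]
    score: float

    def __post_init__(self):
        missing = [c for c in self.comparisons if c not in self.signs]
        if missing:
            raise ValueError(f"sign vector missing comparisons: {missing}")

    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


def _score_submatrix(sub: np.ndarray, signs: np.ndarray, cfg: BiclusterConfig) -> float:
    """Score of a genes x comparisons block given per-comparison signs."""
    agreed = sub * signs  # +1 match, 0 zero, -1 mismatch
    n_match = int((agreed == 1).sum())
    n_zero = int((agreed == 0).sum())
    n_mis = int((agreed == -1).sum())
    return cfg.match_weight * n_match - cfg.zero_penalty * n_zero - cfg.mismatch_penalty * n_mis


def score_bicluster(matrix: TernaryDEMatrix, bc: Bicluster, cfg: BiclusterConfig | None = None) -> float:
    """Recompute the additive score of ``bc`` on ``matrix``."""
    cfg = cfg or BiclusterConfig()
    df = matrix.data
    missing_g = [g for g in bc.genes if g not in df.index]
    missing_c = [c for c in bc.comparisons if c not in df.columns]
    if missing_g or missing_c:
        raise ValueError(f"bicluster members outside matrix axes: {missing_g + missing_c}")
    sub = df.loc[bc.genes, bc.comparisons].to_numpy()
    signs = np.array([bc.signs[c] for c in bc.comparisons], dtype=np.int8)
    return _score_submatrix(sub, signs, cfg)


class BiclusterModel:
    """Greedy SAMBA-style bicluster search bound to one ternary matrix.

    statsmodels-style usage::

        res = BiclusterModel(ternary, BiclusterConfig()).fit()
        res.summary()
    """

    def __init__(self, matrix: TernaryDEMatrix, config: BiclusterConfig | None = None):
        if matrix.data.shape[0] == 0 or matrix.data.shape[1] == 0:
            raise ValueError("ternary matrix is empty")
        self.matrix = matrix
        self.config = config or BiclusterConfig()
        self._M = matrix.data.to_numpy(dtype=np.int8)
        self._genes = list(matrix.data.index)
        self._comps = list(matrix.data.columns)
        cfg = self.config
        M = self._M
        # per-cell score under each column sign, for O(n) contribution updates
        self._Wp = (cfg.match_weight * (M == 1) - cfg.zero_penalty * (M == 0)
                    - cfg.mismatch_penalty * (M == -1)).astype(float)
        self._Wm = (cfg.match_weight * (M == -1) - cfg.zero_penalty * (M == 0)
                    - cfg.mismatch_penalty * (M == 1)).astype(float)
        self._Mpos = (M == 1)
        self._Mneg = (M == -1)

    # -- greedy local search ------------------------------------------------
    #
    # Search state (all incremental, O(n + m) per iteration):
    #   gene_mask   bool[n]   current gene subset
    #   comp_in     bool[m]   current comparison subset
    #   comp_sign   int8[m]   sign of each included comparison
    #   contrib     float[n]  per-gene score contribution for current comps
    #   col_pos/neg int[m]    counts of +1 / -1 entries over current genes
    #   score       float

    class _State:
        __slots__ = ("gene_mask", "comp_in", "comp_sign", "contrib",
                     "col_pos", "col_neg", "n_cur", "score")

        def copy(self):
            s = BiclusterModel._State()
            s.gene_mask = self.gene_mask.copy()
            s.comp_in = self.comp_in.copy()
            s.comp_sign = self.comp_sign.copy()
            s.contrib = self.contrib.copy()
            s.col_pos = self.col_pos.copy()
            s.col_neg = self.col_neg.copy()
            s.n_cur = self.n_cur
            s.score = self.score
            return s

    def _init_state(self, gene_idx: list[int], comp_idx: list[int], signs: list[int]):
        n, m = self._M.shape
        st = self._State()
        st.gene_mask = np.zeros(n, dtype=bool)
        st.gene_mask[gene_idx] = True
        st.comp_in = np.zeros(m, dtype=bool)
        st.comp_sign = np.zeros(m, dtype=np.int8)
        st.contrib = np.zeros(n, dtype=float)
        for c, s in zip(comp_idx, signs):
            st.comp_in[c] = True
            st.comp_sign[c] = s
            st.contrib += self._Wp[:, c] if s == 1 else self._Wm[:, c]
        st.col_pos = self._Mpos[st.gene_mask].sum(axis=0).astype(np.int64)
        st.col_neg = self._Mneg[st.gene_mask].sum(axis=0).astype(np.int64)
        st.n_cur = int(st.gene_mask.sum())
        st.score = float(st.contrib[st.gene_mask].sum())
        return st

    def _comp_deltas(self, st) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(addition deltas with majority signs, removal deltas) per column."""
        cfg = self.config
        sign = np.where(st.col_pos >= st.col_neg, 1, -1).astype(np.int8)  # ties -> +1
        match = np.where(sign == 1, st.col_pos, st.col_neg)
        mism = np.where(sign == 1, st.col_neg, st.col_pos)
        zero = st.n_cur - st.col_pos - st.col_neg
        add = cfg.match_weight * match - cfg.zero_penalty * zero - cfg.mismatch_penalty * mism
        cur_match = np.where(st.comp_sign == 1, st.col_pos, st.col_neg)
        cur_mism = np.where(st.comp_sign == 1, st.col_neg, st.col_pos)
        rem = -(cfg.match_weight * cur_match - cfg.zero_penalty * zero
                - cfg.mismatch_penalty * cur_mism)
        return add, rem, sign

    def _apply(self, st, move):
        kind = move[0]
        if kind == "+g":
            g = move[1]
            st.gene_mask[g] = True
            st.col_pos += self._Mpos[g]
            st.col_neg += self._Mneg[g]
            st.n_cur += 1
            st.score += st.contrib[g]
        elif kind == "-g":
            g = move[1]
            st.gene_mask[g] = False
            st.col_pos -= self._Mpos[g]
            st.col_neg -= self._Mneg[g]
            st.n_cur -= 1
            st.score -= st.contrib[g]
        elif kind == "+c":
            _, c, s, delta = move
            st.comp_in[c] = True
            st.comp_sign[c] = s
            st.contrib += self._Wp[:, c] if s == 1 else self._Wm[:, c]
            st.score += delta
        else:  # "-c"
            _, c, delta = move
            s = st.comp_sign[c]
            st.comp_in[c] = False
            st.comp_sign[c] = 0
            st.contrib -= self._Wp[:, c] if s == 1 else self._Wm[:, c]
            st.score += delta

    def _best_move(self, st, eps: float = 1e-9):
        """Best strictly-improving single move, or None at a local optimum.

        Candidate order breaks exact ties deterministically: gene addition,
        gene removal, comparison addition, comparison removal, each
        lexicographic by position (argmax returns the first maximum).
        """
        best_delta, best_move = eps, None
        has_comps = st.comp_in.any()
        if has_comps:
            add = np.where(st.gene_mask, -np.inf, st.contrib)
            g = int(np.argmax(add))
            if add[g] > best_delta:
                best_delta, best_move = float(add[g]), ("+g", g)
            rem = np.where(st.gene_mask, -st.contrib, -np.inf)
            g = int(np.argmax(rem))
            if rem[g] > best_delta:
                best_delta, best_move = float(rem[g]), ("-g", g)
        if st.n_cur > 0:
            add_c, rem_c, sign_c = self._comp_deltas(st)
            add_c = np.where(st.comp_in, -np.inf, add_c)
            c = int(np.argmax(add_c))
            if add_c[c] > best_delta:
                best_delta, best_move = float(add_c[c]), ("+c", c, int(sign_c[c]), float(add_c[c]))
            rem_cm = np.where(st.comp_in, rem_c, -np.inf)
            c = int(np.argmax(rem_cm))
            if rem_cm[c] > best_delta:
                best_delta, best_move = float(rem_cm[c]), ("-c", c, float(rem_cm[c]))
        return best_move

    def _descend(self, st):
        while True:
            move = self._best_move(st)
            if move is None:
                return st
            self._apply(st, move)

    def _plateau_candidates(self, st, eps: float = 1e-9):
        """Zero-delta moves at a local optimum, deterministic order."""
        moves = []
        if st.comp_in.any():
            flat = np.flatnonzero(~st.gene_mask & (np.abs(st.contrib) <= eps))
            moves.extend(("+g", int(g)) for g in flat)
        if st.n_cur > 0:
            add_c, _, sign_c = self._comp_deltas(st)
            flat = np.flatnonzero(~st.comp_in & (np.abs(add_c) <= eps))
            moves.extend(("+c", int(c), int(sign_c[c]), 0.0) for c in flat)
        return moves

    def _greedy(self, gene_idx: list[int], comp_idx: list[int], signs: list[int]):
        st = self._descend(self._init_state(gene_idx, comp_idx, signs))
        # plateau escape: a zero-delta addition may unlock strictly better
        # optima (e.g. a gene that only pays off once a further comparison
        # joins); try each in order and keep the first strict improvement
        improved = True
        while improved:
            improved = False
            for move in self._plateau_candidates(st):
                trial = st.copy()
                self._apply(trial, move)
                self._descend(trial)
                if trial.score > st.score + 1e-9:
                    st = trial
                    improved = True
                    break
        comp_idx = np.flatnonzero(st.comp_in).tolist()
        signs = [int(st.comp_sign[c]) for c in comp_idx]
        genes = np.flatnonzero(st.gene_mask).tolist()
        return genes, comp_idx, signs, float(st.score)

    def _seeds(self):
        """Deterministic seed list: singleton seeds then gene-pair seeds."""
        cfg = self.config
        M = self._M
        seeds = []
        if cfg.include_singleton_seeds:
            for g in range(M.shape[0]):
                comps = np.flatnonzero(M[g] != 0)
                if len(comps) >= 1:
                    seeds.append(([g], comps.tolist(), M[g, comps].tolist()))
        # pairwise agreement counts via matmul on sign indicators
        P = (M == 1).astype(np.int32)
        N = (M == -1).astype(np.int32)
        agree = P @ P.T + N @ N.T
        np.fill_diagonal(agree, 0)
        g1s, g2s = np.nonzero(np.triu(agree >= self.config.min_comparisons, k=1))
        for g1, g2 in zip(g1s.tolist(), g2s.tolist()):
            comps = np.flatnonzero((M[g1] == M[g2]) & (M[g1] != 0))
            seeds.append(([g1, g2], comps.tolist(), M[g1, comps].tolist()))
        return seeds

    def fit(self) -> "BiclusterResults":
        cfg = self.config
        optima: list[tuple[list[int], list[int], list[int], float]] = []
        optima_sets: list[tuple[set, set]] = []
        by_gene: dict[int, list[int]] = {}
        seen: set[tuple] = set()
        for gene_idx, comp_idx, signs in self._seeds():
            if cfg.prune_contained_seeds:
                candidates = by_gene.get(gene_idx[0], [])
                contained = any(
                    all(g in optima_sets[i][0] for g in gene_idx)
                    and set(comp_idx) <= optima_sets[i][1]
                    for i in candidates
                )
                if contained:
                    continue
            genes, comps, sg, score = self._greedy(gene_idx, comp_idx, signs)
            key = (tuple(genes), tuple(comps), tuple(sg))
            if key in seen:
                continue
            seen.add(key)
            idx = len(optima)
            optima.append((genes, comps, sg, score))
            optima_sets.append((set(genes), set(comps)))
            for g in genes:
                by_gene.setdefault(g, []).append(idx)
        # filter: score and size floors
        kept = [
            o for o in optima
            if o[3] >= cfg.score_threshold
            and len(o[0]) >= cfg.min_genes
            and len(o[1]) >= cfg.min_comparisons
        ]
        # redundancy filter, descending score; ties lexicographic for determinism
        kept.sort(key=lambda o: (-o[3], o[0], o[1]))
        final: list[Bicluster] = []
        for genes, comps, sg, score in kept:
            gset = set(genes)
            redundant = False
            for prev in final:
                pset = set(self._genes.index(g) for g in prev.genes)
                jac = len(gset & pset) / len(gset | pset)
                if jac > cfg.max_overlap_jaccard:
                    redundant = True
                    break
            if not redundant:
                final.append(
                    Bicluster(
                        genes=[self._genes[g] for g in genes],
                        comparisons=[self._comps[c] for c in comps],
                        signs={self._comps[c]: int(s) for c, s in zip(comps, sg)},
                        score=score,
                    )
                )
        return BiclusterResults(self, final)


@dataclass
class BiclusterResults:
    """Fitted bicluster set with summary and stage-profile diagnostics."""

    model: BiclusterModel
    biclusters: list[Bicluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def regulated_genes(self) -> set[str]:
        out: set[str] = set()
        for bc in self.biclusters:
            out.update(bc.genes)
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "bicluster": i,
                "n_genes": len(bc.genes),
                "n_comparisons": len(bc.comparisons),
                "score": bc.score,
            }
            for i, bc in enumerate(self.biclusters)
        ]
        return pd.DataFrame(rows, columns=["bicluster", "n_genes", "n_comparisons", "score"])

    def to_records(self) -> pd.DataFrame:
        rows = []
        for i, bc in enumerate(self.biclusters):
            rows.append(
                {
                    "bicluster": i,
                    "score": bc.score,
                    "genes": ",".join(bc.genes),
                    "comparisons": ",".join(bc.comparisons),
                    "signs": ",".join(str(bc.signs[c]) for c in bc.comparisons),
                }
            )
        return pd.DataFrame(rows, columns=["bicluster", "score", "genes", "comparisons", "signs"])

    def plot_stage_profile(self, index: int, expr: ExpressionTable, ax=None):
        """Violin plot of member-gene expression per sample (log10(x+1))."""
        import matplotlib.pyplot as plt

        bc = self.biclusters[index]
        genes = [g for g in bc.genes if g in expr.values.index]
        sub = np.log10(expr.values.loc[genes] + 1.0)
        if ax is None:
            _, ax = plt.subplots()
        ax.violinplot([sub[s].to_numpy() for s in expr.samples], showmedians=True)
        ax.set_xticks(range(1, len(expr.samples) + 1), expr.samples, rotation=90)
        ax.set_ylabel("log10(expression + 1)")
        ax.set_title(f"bicluster {index} ({len(genes)} genes)")
        return ax


def find_biclusters(matrix: TernaryDEMatrix, cfg: BiclusterConfig | None = None) -> BiclusterResults:
    """Functional entry point: fit the greedy model on ``matrix``."""
    return BiclusterModel(matrix, cfg).fit()


def bicluster_stage_profile(
    bc: Bicluster, expr: ExpressionTable, stage_groups=None
) -> pd.DataFrame:
    """Per-sample median/quartile summary of member-gene expression.

    The returned frame carries one row per sample (median, q25, q75, stage)
    and the cross-stage specificity statistic in ``frame.attrs["max_wilcoxon_p"]``.
    """
    genes = [g for g in bc.genes if g in expr.values.index]
    if not genes:
        raise ValueError("bicluster genes have empty intersection with expression table")
    sub = expr.values.loc[genes]
    groups = stage_groups or expr.stage_groups
    rows = []
    for s in expr.samples:
        v = sub[s].to_numpy()
        rows.append(
            {
                "sample": s,
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
                "stage": groups.get(s) if groups else None,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    if groups:
        out.attrs["max_wilcoxon_p"] = stage_specificity_stat(sub, groups)
    return out


def brute_force_best_score(matrix: TernaryDEMatrix, cfg: BiclusterConfig | None = None) -> float:
    """Exhaustive maximum score over all (gene set, comparison set, signs).

    Only feasible on tiny matrices; per fixed gene/comparison subsets the
    optimal sign of each column is chosen independently.  Respects the
    config's size floors.  Intended as an independent oracle for tests.
    """
    cfg = cfg or BiclusterConfig()
    M = matrix.data.to_numpy(dtype=np.int8)
    n, m = M.shape
    if n > 16 or m > 16:
        raise ValueError("brute force oracle limited to 16x16")
    a, b, d = cfg.match_weight, cfg.zero_penalty, cfg.mismatch_penalty
    best = -np.inf
    gene_sets = [
        np.array(gs) for r in range(cfg.min_genes, n + 1) for gs in itertools.combinations(range(n), r)
    ]
    for gs in gene_sets:
        sub = M[gs]
        n_pos = (sub == 1).sum(axis=0)
        n_neg = (sub == -1).sum(axis=0)
        n_zero = len(gs) - n_pos - n_neg
        col_plus = a * n_pos - b * n_zero - d * n_neg
        col_minus = a * n_neg - b * n_zero - d * n_pos
        col_best = np.maximum(col_plus, col_minus)
        order = np.sort(col_best)[::-1]
        csum = np.cumsum(order)
        k0 = cfg.min_comparisons
        if k0 <= len(csum):
            best = max(best, float(csum[k0 - 1 :].max()))
    return best
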