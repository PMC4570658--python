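"""Linking phylogeny to expression: paralog profile coherence and
lineage-specific subtree detection.

Two questions motivate this module.  First, do members of a within-species
paralog family retain correlated stage profiles across the timecourse (as
expected if their common ancestor was already developmentally regulated)?
This is measured by within-family pairwise Spearman correlations against a
resampled background of cross-family gene pairs.  Second, do developmentally
regulated genes cluster inside focal-species-specific subtrees of a gene
tree — the signature of lineage-specific duplication?  Maximal all-focal
clades are extracted and their association with the regulated set is
formalised as an exact two-set overlap test (an extension: the original
observation rests on visual inspection and defines no test).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.stats as st

from .enrich import EnrichmentResult, set_overlap_test
from .formats import ExpressionTable, GeneTree

__all__ = [
    "CladeReport",
    "paralog_profile_correlation",
    "lineage_specific_clades",
    "clade_regulation_association",
]


@dataclass
class CladeReport:
    """One maximal focal-species-only clade of a gene tree."""

    clade_id: int
    tips: list[str]
    all_focal: bool
    size: int
    n_regulated: int = 0
    n_one_to_one: int = 0


# ---------------------------------------------------------------------------
# within-family expression coherence


def paralog_profile_correlation(
    expr: ExpressionTable,
    families: pd.Series,
    n_background: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-family Spearman correlations vs a cross-family background.

    ``families`` maps gene -> family/component label.  For every family with
    at least two expressed members, all pairwise Spearman correlations of
    the member profiles are computed and summarised by their median.  The
    background is the Spearman correlation of ``n_background`` randomly
    drawn (seeded) gene pairs from *different* families; each family's
    empirical p is the add-one-corrected fraction of background pairs whose
    correlation reaches its median.  Families with fewer than two expressed
    members are skipped with a notice row (``n_members < 2``, NaN summary).
    """
    genes_with_expr = [g for g in families.index if g in expr.values.index]
    fam = families.loc[genes_with_expr]
    X = expr.values
    rng = np.random.default_rng(seed)

    # background: random cross-family pairs
    gene_arr = np.array(genes_with_expr)
    fam_arr = fam.to_numpy()
    bg: list[float] = []
    if len(gene_arr) >= 2 and pd.Series(fam_arr).nunique() >= 2:
        while len(bg) < n_background:
            i, j = rng.integers(0, len(gene_arr), size=2)
            if i == j or fam_arr[i] == fam_arr[j]:
                continue
            rho = st.spearmanr(X.loc[gene_arr[i]], X.loc[gene_arr[j]]).statistic
            if np.isfinite(rho):
                bg.append(float(rho))
    bg_arr = np.array(bg)

    rows = []
    for family, members in fam.groupby(fam).groups.items():
        members = list(members)
        if len(members) < 2:
            rows.append(
                {
                    "family": family, "n_members": len(members),
                    "n_pairs": 0, "median_rho": float("nan"),
                    "empirical_p": float("nan"), "note": "fewer than 2 expressed members",
                }
            )
            continue
        rhos = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rho = st.spearmanr(X.loc[members[i]], X.loc[members[j]]).statistic
                if np.isfinite(rho):
                    rhos.append(float(rho))
        med = float(np.median(rhos)) if rhos else float("nan")
        if len(bg_arr) and np.isfinite(med):
            p = (1 + int((bg_arr >= med).sum())) / (1 + len(bg_arr))
        else:
            p = float("nan")
        rows.append(
            {
                "family": family, "n_members": len(members),
                "n_pairs": len(rhos), "median_rho": med,
                "empirical_p": p, "note": "",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["background_median"] = float(np.median(bg_arr)) if len(bg_arr) else float("nan")
    out.attrs["n_background"] = len(bg_arr)
    return out


# ---------------------------------------------------------------------------
# lineage-specific clades


def _midpoint_root_between_nonfocal(tree: dendropy.Tree, nonfocal_taxa: list) -> dendropy.Tree:
    """Reroot at the midpoint of the path between the two most distant
    non-focal tips (unit branch lengths where missing)."""
    for e in tree.preorder_edge_iter():
        if e.length is None:
            e.length = 1.0
    pdm = tree.phylogenetic_distance_matrix()
    best, pair = -1.0, None
    for i, t1 in enumerate(nonfocal_taxa):
        for t2 in nonfocal_taxa[i + 1 :]:
            d = pdm.patristic_distance(t1, t2)
            if d > best:
                best, pair = d, (t1, t2)
    if pair is None:
        return tree
    # walk from t1 towards t2 accumulating half the distance
    n1 = tree.find_node_with_taxon_label(pair[0].label)
    n2 = tree.find_node_with_taxon_label(pair[1].label)
    mrca = pdm.mrca(pair[0], pair[1])
    half = best / 2.0

    def path_up(node, stop):
        path = []
        while node is not stop:
            path.append(node)
            node = node.parent_node
        return path

    acc = 0.0
    for node in path_up(n1, mrca) + list(reversed(path_up(n2, mrca))):
        edge = node.edge
        if acc + edge.length >= half:
            tree.reroot_at_edge(edge, length1=max(edge.length - (half - acc), 0.0),
                                length2=max(half - acc, 0.0),
                                update_bipartitions=False)
            return tree
        acc += edge.length
    return tree


def lineage_specific_clades(tree: GeneTree, focal_species: str, reroot: bool = True) -> list[CladeReport]:
    """Maximal clades whose tips are exclusively focal-species, size >= 2.

    Maximality means the parent clade (or the tree root) contains a
    non-focal tip, so every focal tip belongs to at most one reported clade.
    Unrooted input is first rooted at the midpoint of the path between the
    two most distant non-focal tips; with fewer than two non-focal tips the
    input rooting is kept.
    """
    t = tree.tree.clone(depth=1)
    is_focal = {lab: sp == focal_species for lab, sp in tree.tip_species.items()}
    if not any(is_focal.values()):
        return []
    nonfocal = [
        leaf.taxon for leaf in t.leaf_node_iter() if not is_focal[leaf.taxon.label]
    ]
    if reroot and not t.is_rooted and len(nonfocal) >= 2:
        t = _midpoint_root_between_nonfocal(t, nonfocal)

    reports: list[CladeReport] = []

    def visit(node) -> bool:
        """Return True iff every tip under node is focal; emit maximal clades."""
        if node.is_leaf():
            return is_focal[node.taxon.label]
        child_flags = [(child, visit(child)) for child in node.child_nodes()]
        if all(flag for _, flag in child_flags):
            return True
        # node is mixed: each all-focal child is a maximal focal clade
        for child, flag in child_flags:
            if flag:
                tips = sorted(leaf.taxon.label for leaf in child.leaf_iter())
                if len(tips) >= 2:
                    reports.append(
                        CladeReport(len(reports), tips, True, len(tips))
                    )
        return False

    root = t.seed_node
    if visit(root):
        tips = sorted(leaf.taxon.label for leaf in root.leaf_iter())
        if len(tips) >= 2:
            reports.append(CladeReport(len(reports), tips, True, len(tips)))
    return reports


def clade_regulation_association(
    clades: list[CladeReport],
    regulated: set[str],
    universe: set[str],
    one_to_one: set[str] | None = None,
) -> dict:
    """Association between focal-only clade membership and regulation.

    Builds the 2x2 table (inside/outside lineage-specific clades x regulated
    or not) over the tree-tip universe and runs the exact overlap test
    (both tails).  Also reports how many regulated tips carry a one-to-one
    ortholog call — the qualitative expectation is zero when regulation is
    driven by lineage-specific duplicates.  With no focal-only clades the
    association is undefined and flagged.
    """
    if not universe:
        raise ValueError("empty universe")
    one_to_one = one_to_one or set()
    in_clades = set()
    for c in clades:
        in_clades.update(t for t in c.tips if t in universe)
    reg = regulated & universe
    n_reg_one2one = len(reg & one_to_one)
    if not in_clades:
        return {
            "defined": False,
            "result": None,
            "n_in_clades": 0,
            "n_regulated": len(reg),
            "n_regulated_one_to_one": n_reg_one2one,
        }
    res: EnrichmentResult = set_overlap_test(in_clades, reg, universe)
    for c in clades:
        c.n_regulated = len(set(c.tips) & reg)
        c.n_one_to_one = len(set(c.tips) & one_to_one)
    return {
        "defined": True,
        "result": res,
        "n_in_clades": len(in_clades),
        "n_regulated": len(reg),
        "n_regulated_one_to_one": n_reg_one2one,
    }
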