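"""Inparalog-aware reciprocal-best-hit orthology and the five-class partition.

The procedure classifies every gene of a focal species, given all-vs-all
protein similarity hits against a panel of comparison species, into exactly
one of five classes:

``one_to_one``
    best-reciprocal hit with the designated comparison species, accepted
    only if *neither* partner has an inparalog (an intraspecies hit scoring
    strictly above the gene's own best interspecies bitscore — an
    Inparanoid-style veto, since such a paralog post-dates the speciation);
``conserved_multicopy`` / ``conserved_singleton``
    genes with at least one panel hit below the e-value threshold, split by
    membership in a within-species paralog family (connected component of
    the intraspecies hit graph, computed after removing one-to-one genes);
``orphan_multicopy`` / ``orphan_singleton``
    genes without any panel hit, split the same way.

Best hits are ranked by bitscore (database-size independent), ties broken by
smaller e-value then lexicographic subject id.  Genes present in the focal
universe but absent from every hit table are orphan singletons — absence of
hits is the defining evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats import SimilarityGraph

__all__ = [
    "OrthologyConfig",
    "OrthologyModel",
    "OrthologyResults",
    "CLASSES",
    "best_interspecies_scores",
    "find_inparalogs",
    "one_to_one_orthologs",
    "paralog_components",
    "classify_genes",
    "evaluate_against_curated",
]

CLASSES = (
    "one_to_one",
    "conserved_multicopy",
    "conserved_singleton",
    "orphan_multicopy",
    "orphan_singleton",
)


@dataclass(frozen=True)
class OrthologyConfig:
    """Threshold and species roles of the classification procedure."""

    focal_species: str = "Ppa"
    comparison_species: str = "Cel"
    panel_species: tuple = ("Cel",)
    evalue_threshold: float = 0.001
    symmetric_inparalogs: bool = False

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.focal_species in self.panel_species:
            raise ValueError("focal species must not be in the panel")
        if self.comparison_species not in self.panel_species:
            raise ValueError("comparison species must be in the panel")


def best_interspecies_scores(
    hits: SimilarityGraph, cfg: OrthologyConfig, species: str | None = None
) -> pd.DataFrame:
    """Per-gene best hit into the opposite one-to-one species.

    For genes of ``species`` (default: the focal species) the best hit is
    taken over hits to the comparison species; for genes of the comparison
    species, over hits back to the focal species.  Returns a frame indexed
    by gene with columns ``best_subject`` (None when no hit) and
    ``best_bitscore`` (0.0 when no hit).  Ties: higher bitscore, then
    smaller e-value, then lexicographic subject id.
    """
    species = species or cfg.focal_species
    target = cfg.comparison_species if species == cfg.focal_species else cfg.focal_species
    df = hits.interspecies(species, target, cfg.evalue_threshold)
    if len(df) == 0:
        return pd.DataFrame(columns=["best_subject", "best_bitscore"])
    ranked = df.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("query", keep="first")
    out = ranked.set_index("query")[["subject", "bitscore"]]
    out.columns = ["best_subject", "best_bitscore"]
    return out


def find_inparalogs(
    hits: SimilarityGraph, best: pd.DataFrame, cfg: OrthologyConfig, species: str | None = None
) -> tuple[set[str], list[tuple[str, str]]]:
    """Genes of one species that have an inparalog, plus the flagged pairs.

    Gene ``a`` has an inparalog iff some intraspecies hit (a, a') carries a
    bitscore strictly above a's best interspecies bitscore b*(a); genes with
    b*(a) = 0 are never flagged (they cannot enter the reciprocal-best-hit
    stage anyway).  With ``cfg.symmetric_inparalogs`` the pair must beat the
    best interspecies bitscore of *both* members.
    """
    species = species or cfg.focal_species
    intra = hits.intraspecies(species, cfg.evalue_threshold)
    if (len(intra) > 0) and (intra["query_species"] != intra["subject_species"]).any():
        raise ValueError("interspecies hit routed into inparalog detection")
    bstar = best["best_bitscore"] if len(best) else pd.Series(dtype=float)
    flagged: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for row in intra.itertuples(index=False):
        ba = float(bstar.get(row.query, 0.0))
        if ba <= 0.0:
            continue
        if row.bitscore > ba:
            if cfg.symmetric_inparalogs:
                bb = float(bstar.get(row.subject, 0.0))
                if not (bb > 0.0 and row.bitscore > bb):
                    continue
            flagged.add(row.query)
            pairs.append((row.query, row.subject))
    return flagged, sorted(pairs)


def one_to_one_orthologs(
    best_focal: pd.DataFrame,
    best_comparison: pd.DataFrame,
    inparalogs_focal: set[str],
    inparalogs_comparison: set[str],
) -> list[tuple[str, str]]:
    """Best-reciprocal hits with the inparalog veto applied to both sides.

    (a, b) is reported iff b is a's best comparison-species hit, a is b's
    best focal-species hit, and neither a nor b has an inparalog.  Best-hit
    uniqueness guarantees each gene appears in at most one pair.
    """
    pairs = []
    if len(best_focal) == 0 or len(best_comparison) == 0:
        return pairs
    back = best_comparison["best_subject"]
    for a, row in best_focal.iterrows():
        b = row["best_subject"]
        if b is None or b not in back.index:
            continue
        if back.loc[b] != a:
            continue
        if a in inparalogs_focal or b in inparalogs_comparison:
            continue
        pairs.append((a, b))
    return sorted(pairs)


def paralog_components(
    hits: SimilarityGraph,
    cfg: OrthologyConfig,
    genes: list[str] | None = None,
    exclude: set[str] | None = None,
) -> pd.Series:
    """Connected-component labels of the focal intraspecies hit graph.

    An undirected edge joins two focal genes when a hit in either direction
    passes the e-value threshold.  ``genes`` adds isolated vertices for
    hit-less genes; ``exclude`` removes genes (the one-to-one set) before the
    components are extracted.  Returns gene -> integer component id, with
    ids assigned in order of each component's lexicographically smallest
    member.
    """
    exclude = exclude or set()
    g = nx.Graph()
    if genes is not None:
        g.add_nodes_from(gn for gn in genes if gn not in exclude)
    intra = hits.intraspecies(cfg.focal_species, cfg.evalue_threshold)
    for row in intra.itertuples(index=False):
        if row.query in exclude or row.subject in exclude:
            continue
        g.add_edge(row.query, row.subject)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    labels = {}
    for cid, comp in enumerate(comps):
        for gene in comp:
            labels[gene] = cid
    return pd.Series(labels, dtype=int, name="component")


class OrthologyModel:
    """The five-class orthology procedure bound to one hit universe.

    statsmodels-style usage::

        res = OrthologyModel(hits, focal_genes, OrthologyConfig()).fit()
        res.summary()

    ``focal_genes`` is the full focal-species gene universe; genes missing
    from every hit table are classified as orphan singletons.
    """

    def __init__(
        self,
        hits: SimilarityGraph,
        focal_genes: list[str],
        config: OrthologyConfig | None = None,
    ):
        self.hits = hits
        self.config = config or OrthologyConfig()
        if len(set(focal_genes)) != len(focal_genes):
            raise ValueError("duplicate gene ids in focal universe")
        self.focal_genes = list(focal_genes)

    def fit(self) -> "OrthologyResults":
        cfg = self.config
        best_f = best_interspecies_scores(self.hits, cfg, cfg.focal_species)
        best_c = best_interspecies_scores(self.hits, cfg, cfg.comparison_species)
        inpar_f, pairs_f = find_inparalogs(self.hits, best_f, cfg, cfg.focal_species)
        inpar_c, pairs_c = find_inparalogs(self.hits, best_c, cfg, cfg.comparison_species)
        one2one = one_to_one_orthologs(best_f, best_c, inpar_f, inpar_c)
        one2one_focal = {a for a, _ in one2one}
        partner = dict(one2one)

        components = paralog_components(
            self.hits, cfg, genes=self.focal_genes, exclude=one2one_focal
        )
        comp_sizes = components.value_counts()

        panel = self.hits.interspecies(cfg.focal_species, list(cfg.panel_species), cfg.evalue_threshold)
        has_panel_hit = set(panel["query"])

        rows = []
        for gene in self.focal_genes:
            if gene in one2one_focal:
                cls = "one_to_one"
                comp_id, comp_size = -1, 1
            else:
                if gene not in components.index:
                    raise KeyError(f"gene {gene!r} missing from component labelling")
                comp_id = int(components.loc[gene])
                comp_size = int(comp_sizes.loc[comp_id])
                conserved = gene in has_panel_hit
                multicopy = comp_size > 1
                if conserved:
                    cls = "conserved_multicopy" if multicopy else "conserved_singleton"
                else:
                    cls = "orphan_multicopy" if multicopy else "orphan_singleton"
            rows.append(
                {
                    "gene": gene,
                    "class": cls,
                    "component": comp_id,
                    "component_size": comp_size,
                    "partner": partner.get(gene),
                    "has_inparalog": gene in inpar_f,
                    "best_interspecies_bitscore": float(
                        best_f["best_bitscore"].get(gene, 0.0) if len(best_f) else 0.0
                    ),
                }
            )
        calls = pd.DataFrame(rows).set_index("gene")
        return OrthologyResults(
            model=self,
            calls=calls,
            one_to_one_pairs=one2one,
            inparalogs_focal=inpar_f,
            inparalogs_comparison=inpar_c,
            inparalog_pairs_focal=pairs_f,
            inparalog_pairs_comparison=pairs_c,
            components=components,
        )


@dataclass
class OrthologyResults:
    """Per-gene orthology calls plus the supporting evidence structures."""

    model: OrthologyModel
    calls: pd.DataFrame
    one_to_one_pairs: list[tuple[str, str]]
    inparalogs_focal: set[str]
    inparalogs_comparison: set[str]
    inparalog_pairs_focal: list[tuple[str, str]]
    inparalog_pairs_comparison: list[tuple[str, str]]
    components: pd.Series

    def class_counts(self) -> pd.Series:
        return self.calls["class"].value_counts().reindex(CLASSES, fill_value=0)

    def genes_in_class(self, cls: str) -> set[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return set(self.calls.index[self.calls["class"] == cls])

    def summary(self) -> pd.DataFrame:
        counts = self.class_counts()
        total = int(counts.sum())
        return pd.DataFrame(
            {
                "count": counts,
                "fraction": counts / total if total else 0.0,
            }
        )

    def evaluate_against_curated(self, curated: pd.DataFrame) -> dict:
        return evaluate_against_curated(self, curated)


def classify_genes(
    hits: SimilarityGraph, focal_genes: list[str], cfg: OrthologyConfig | None = None
) -> OrthologyResults:
    """Functional entry point: run the full five-class procedure."""
    return OrthologyModel(hits, focal_genes, cfg).fit()


def evaluate_against_curated(results: OrthologyResults, curated: pd.DataFrame) -> dict:
    """Confusion counts of predicted one-to-one calls against a curated set.

    ``curated`` lists comparison-species genes with a manual verdict: columns
    ``gene`` and ``has_one_to_one`` (boolean).  Curated genes absent from the
    hit universe are counted separately as unassessable.
    """
    if not {"gene", "has_one_to_one"} <= set(curated.columns):
        raise ValueError("curated table needs columns 'gene' and 'has_one_to_one'")
    predicted = {b for _, b in results.one_to_one_pairs}
    universe = set(results.model.hits.species)
    tp = fn = tn = fp = unassessable = 0
    for row in curated.itertuples(index=False):
        gene = row.gene
        truth = bool(row.has_one_to_one)
        if gene not in universe:
            unassessable += 1
            continue
        pred = gene in predicted
        if truth and pred:
            tp += 1
        elif truth and not pred:
            fn += 1
        elif not truth and not pred:
            tn += 1
        else:
            fp += 1
    assessed = tp + fn + tn + fp
    return {
        "true_positive": tp,
        "false_negative": fn,
        "true_negative": tn,
        "false_positive": fp,
        "unassessable": unassessable,
        "agreement_positive": tp / (tp + fn) if (tp + fn) else float("nan"),
        "agreement_negative": tn / (tn + fp) if (tn + fp) else float("nan"),
        "agreement_overall": (tp + tn) / assessed if assessed else float("nan"),
    }
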