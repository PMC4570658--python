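"""Synthetic two-species gene families with known orthology and expression truth.

The generator emulates the data regime of a two-nematode comparative
transcriptome study: a focal species with a staged developmental timecourse
(10 samples in 3 stage groups) and a comparison species used for orthology
calls.  Families arise from a single ancestral gene; each lineage then
duplicates independently (copy number = 1 + Poisson(rate)), so every
within-species paralog post-dates the speciation and is an inparalog sensu
the reciprocal-best-hit procedure.  A configurable fraction of families is
"orphan" (no detectable homolog outside the focal lineage).  Developmentally
regulated families share a stage archetype across members (early-high,
dauer-high or late-high) with multiplicative log-normal noise; unregulated
families are flat, housekeeping-like, above a robust-expression floor.
Multicopy families get a configurable multiplicative boost on the odds of
being regulated, planting the duplication/regulation association the
analysis is designed to detect.

Similarity scores are bitscore = S0*exp(-k*t) with t the simulated
divergence time, so scores are strictly decreasing in divergence and any
rank-based rule (best hits, inparalog veto) sees the true topology when
noise is zero.  No sequences, read counts or library-size effects are
simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .formats import ExpressionTable, SimilarityGraph

__all__ = [
    "FamilySimConfig",
    "ScoreParams",
    "TruthTable",
    "CLASSES",
    "ARCHETYPES",
    "simulate_families",
    "simulate_similarity",
    "simulate_expression",
    "simulate_dataset",
    "planted_ternary_matrix",
]

CLASSES = (
    "one_to_one",
    "conserved_multicopy",
    "conserved_singleton",
    "orphan_multicopy",
    "orphan_singleton",
)

#: default sample ids and their rough stage grouping (3 early-ish, 2 dauer,
#: 5 late larvae + adults), mirroring a 10-library nematode timecourse
DEFAULT_STAGES: dict[str, str] = {
    "J2_1": "early", "J2_2": "early", "J3_2": "early",
    "dauer_1": "dauer", "dauer_2": "dauer",
    "J3_1": "late", "J4_1": "late", "J4_2": "late", "A_1": "late", "A_2": "late",
}

#: archetype profiles: stage -> relative expression level (FPKM-like)
ARCHETYPES: dict[str, dict[str, float]] = {
    "early_high": {"early": 100.0, "dauer": 2.0, "late": 2.0},
    "dauer_high": {"early": 2.0, "dauer": 100.0, "late": 2.0},
    "late_high": {"early": 2.0, "dauer": 2.0, "late": 100.0},
}


@dataclass(frozen=True)
class FamilySimConfig:
    """Parameters of the two-species gene-family world.

    Defaults are chosen to echo the genome-scale proportions of the study
    system: ~32% orphan families, ~17% baseline regulated fraction, a 3x
    odds boost of regulation for multicopy families, and duplication rates
    giving roughly half of focal genes a within-species paralog.
    """

    n_families: int = 200
    dup_rate_focal: float = 0.4
    dup_rate_other: float = 0.4
    orphan_fraction: float = 0.32
    regulated_fraction: float = 0.17
    multicopy_regulation_boost: float = 3.0
    n_samples: int = 10
    stage_assignment: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    noise_sigma: float = 0.25
    housekeeping_floor: float = 20.0
    housekeeping_ceiling: float = 200.0
    seed: int = 0
    focal_species: str = "Ppa"
    other_species: str = "Cel"

    def __post_init__(self):
        for name in ("orphan_fraction", "regulated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("dup_rate_focal", "dup_rate_other", "noise_sigma"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.multicopy_regulation_boost < 1.0:
            raise ValueError("multicopy_regulation_boost must be >= 1")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if len(self.stage_assignment) != self.n_samples:
            raise ValueError(
                f"stage_assignment covers {len(self.stage_assignment)} samples, "
                f"expected n_samples={self.n_samples}"
            )

    def with_(self, **kw) -> "FamilySimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScoreParams:
    """Monotone divergence -> similarity score map (bitscore = s0*exp(-k*t))."""

    s0: float = 400.0
    k: float = 1.0
    noise: float = 0.0           # sd of Gaussian noise on log-bitscore
    min_bitscore: float = 50.0   # detectability threshold; weaker hits omitted
    speciation_time: float = 1.0


@dataclass
class TruthTable:
    """Ground truth of a simulated two-species gene-family world.

    ``genes`` has one row per emitted gene: gene id, family id, species,
    birth time of the gene's lineage-specific duplication (0 for the
    ancestral copy), true orthology class (focal genes only), regulated
    flag and archetype id.  ``families`` has one row per family.
    """

    genes: pd.DataFrame
    families: pd.DataFrame
    config: FamilySimConfig

    def focal_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["species"] == self.config.focal_species]

    def class_counts(self) -> pd.Series:
        counts = self.focal_genes()["true_class"].value_counts()
        return counts.reindex(CLASSES, fill_value=0)

    def members(self, family: int) -> list[str]:
        return list(self.genes.loc[self.genes["family"] == family, "gene"])


def _true_class(orphan: bool, k_focal: int, k_other: int) -> str:
    if not orphan and k_focal == 1 and k_other == 1:
        return "one_to_one"
    conserved = not orphan
    multicopy = k_focal > 1
    if conserved:
        return "conserved_multicopy" if multicopy else "conserved_singleton"
    return "orphan_multicopy" if multicopy else "orphan_singleton"


def simulate_families(config: FamilySimConfig) -> TruthTable:
    """Draw family topologies and truth labels.

    Per family: orphan status ~ Bernoulli(orphan_fraction); copy number per
    lineage = 1 + Poisson(dup_rate); duplication times uniform within the
    post-speciation interval.  Regulation is drawn with the multicopy odds
    boost applied (multicopy = focal copy number > 1); regulated families
    pick one stage archetype uniformly.  True classes follow from the
    realised topology.
    """
    rng = np.random.default_rng(config.seed)
    base_odds = (
        config.regulated_fraction / (1.0 - config.regulated_fraction)
        if config.regulated_fraction < 1.0
        else np.inf
    )
    gene_rows, fam_rows = [], []
    for fid in range(config.n_families):
        orphan = bool(rng.random() < config.orphan_fraction)
        k_focal = 1 + int(rng.poisson(config.dup_rate_focal))
        k_other = 0 if orphan else 1 + int(rng.poisson(config.dup_rate_other))
        multicopy = k_focal > 1
        if config.regulated_fraction >= 1.0:
            p_reg = 1.0
        else:
            odds = base_odds * (config.multicopy_regulation_boost if multicopy else 1.0)
            p_reg = odds / (1.0 + odds)
        regulated = bool(rng.random() < p_reg)
        archetype = (
            list(ARCHETYPES)[int(rng.integers(len(ARCHETYPES)))] if regulated else None
        )
        cls = _true_class(orphan, k_focal, k_other)
        hk_level = float(
            np.exp(rng.uniform(np.log(config.housekeeping_floor),
                               np.log(config.housekeeping_ceiling)))
        )
        fam_rows.append((fid, orphan, k_focal, k_other, regulated, archetype, hk_level))
        for sp, k in ((config.focal_species, k_focal), (config.other_species, k_other)):
            # copy 0 is the ancestral lineage; later copies carry their
            # duplication time (fraction of the post-speciation interval)
            dup_times = np.sort(rng.uniform(0.1, 0.9, size=max(k - 1, 0)))
            for i in range(k):
                gene = f"{sp}-f{fid:04d}g{i}"
                t_dup = 0.0 if i == 0 else float(dup_times[i - 1])
                gene_rows.append(
                    (
                        gene, fid, sp, t_dup,
                        cls if sp == config.focal_species else None,
                        regulated, archetype,
                    )
                )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene", "family", "species", "dup_time", "true_class", "regulated", "archetype"],
    )
    families = pd.DataFrame(
        fam_rows,
        columns=["family", "orphan", "k_focal", "k_other", "regulated", "archetype", "hk_level"],
    )
    return TruthTable(genes, families, config)


def simulate_similarity(truth: TruthTable, score_params: ScoreParams | None = None) -> SimilarityGraph:
    """Emit within-family all-vs-all hits with scores monotone in divergence.

    Cross-family pairs are unrelated and produce no hit; hits with bitscore
    below the detectability threshold are omitted.  Both hit directions are
    emitted (BLAST-style), with symmetric scores unless noise is nonzero.
    """
    sp = score_params or ScoreParams()
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    known = set(truth.genes["gene"])
    rows = []
    for fid, grp in truth.genes.groupby("family"):
        members = list(grp.itertuples(index=False))
        for a, b in itertools.combinations(members, 2):
            if a.gene not in known or b.gene not in known:  # pragma: no cover
                raise KeyError(f"unknown gene id {a.gene!r}/{b.gene!r}")
            same = a.species == b.species
            if same:
                # serial-duplication trunk: the pair splits when the earlier
                # duplicate buds off (trunk copies carry dup_time 0), which is
                # always post-speciation, so the score strictly exceeds any
                # cross-species hit of the same family
                positives = [t for t in (a.dup_time, b.dup_time) if t > 0]
                split_forward = min(positives)
                t = sp.speciation_time * (1.0 - split_forward)
            else:
                t = sp.speciation_time
            for q, s in ((a, b), (b, a)):
                log_bs = np.log(sp.s0) - sp.k * t
                if sp.noise > 0:
                    log_bs += rng.normal(0.0, sp.noise)
                bitscore = float(np.exp(log_bs))
                if bitscore < sp.min_bitscore:
                    continue
                evalue = float(10.0 ** (-bitscore / 10.0))
                rows.append((q.gene, s.gene, evalue, bitscore, q.species, s.species))
    df = pd.DataFrame(
        rows, columns=["query", "subject", "evalue", "bitscore", "query_species", "subject_species"]
    )
    species = dict(zip(truth.genes["gene"], truth.genes["species"]))
    return SimilarityGraph(df, species=species)


def simulate_expression(truth: TruthTable, config: FamilySimConfig | None = None) -> ExpressionTable:
    """Stage-structured expression for focal-species genes.

    Regulated families share their archetype profile across members with
    independent multiplicative log-normal noise (sd ``noise_sigma`` on the
    natural-log scale); unregulated (housekeeping) families are flat at a
    family-specific level drawn above ``housekeeping_floor``.
    """
    cfg = config or truth.config
    samples = list(cfg.stage_assignment)
    missing = [s for s in samples if cfg.stage_assignment.get(s) is None]
    if missing:
        raise ValueError(f"stage_assignment does not cover samples: {missing}")
    rng = np.random.default_rng(cfg.seed + 2)
    fam_level = dict(zip(truth.families["family"], truth.families["hk_level"]))
    focal = truth.focal_genes()
    data = np.empty((len(focal), len(samples)))
    for i, row in enumerate(focal.itertuples(index=False)):
        if row.regulated:
            base = np.array(
                [ARCHETYPES[row.archetype][cfg.stage_assignment[s]] for s in samples]
            )
        else:
            base = np.full(len(samples), fam_level[row.family])
        noise = (
            rng.normal(0.0, cfg.noise_sigma, size=len(samples))
            if cfg.noise_sigma > 0
            else np.zeros(len(samples))
        )
        data[i] = base * np.exp(noise)
    df = pd.DataFrame(data, index=list(focal["gene"]), columns=samples)
    return ExpressionTable(df, stage_groups=dict(cfg.stage_assignment))


def simulate_dataset(config: FamilySimConfig, score_params: ScoreParams | None = None):
    """Convenience: (truth, similarity, expression) for one config."""
    truth = simulate_families(config)
    hits = simulate_similarity(truth, score_params)
    expr = simulate_expression(truth)
    return truth, hits, expr


# ---------------------------------------------------------------------------
# planted ternary matrices (for biclustering recovery experiments)


def planted_ternary_matrix(
    n_genes: int = 1000,
    n_comparisons: int = 45,
    n_blocks: int = 5,
    block_genes: int = 40,
    block_comparisons: int = 8,
    agreement: float = 0.9,
    background_rate: float = 0.05,
    seed: int = 0,
):
    """A genes x comparisons ternary matrix with disjoint planted sign blocks.

    Background cells are 0 with probability ``1 - background_rate``, else
    +/-1 equiprobably.  Inside a planted block each cell takes the block's
    per-comparison sign with probability ``agreement`` and a background draw
    otherwise.  Returns ``(DataFrame, blocks)`` where ``blocks`` is a list of
    ``(gene_ids, comparison_ids, signs)`` triples.
    """
    if n_blocks * block_genes > n_genes or n_blocks * block_comparisons > n_comparisons:
        raise ValueError("planted blocks do not fit in the matrix")
    rng = np.random.default_rng(seed)

    def background(shape):
        r = rng.random(shape)
        out = np.zeros(shape, dtype=np.int8)
        nz = r < background_rate
        out[nz] = rng.choice([-1, 1], size=int(nz.sum()))
        return out

    mat = background((n_genes, n_comparisons))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    comps = [f"c{j:02d}" for j in range(n_comparisons)]
    blocks = []
    for b in range(n_blocks):
        gi = np.arange(b * block_genes, (b + 1) * block_genes)
        ci = np.arange(b * block_comparisons, (b + 1) * block_comparisons)
        signs = rng.choice([-1, 1], size=block_comparisons).astype(np.int8)
        cell = np.tile(signs, (block_genes, 1))
        keep = rng.random((block_genes, block_comparisons)) < agreement
        bg = background((block_genes, block_comparisons))
        mat[np.ix_(gi, ci)] = np.where(keep, cell, bg)
        blocks.append(([genes[i] for i in gi], [comps[j] for j in ci], signs))
    df = pd.DataFrame(mat, index=genes, columns=comps)
    return df, blocks
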