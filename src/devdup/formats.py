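"""Readers and writers for the external representations the pipeline touches.

Supported formats: BLAST tabular (``-outfmt 6``) similarity hits, TSV
expression matrices (genes x samples), Newick gene trees with species-tagged
tips, and simple TSV annotation/truth tables.  All readers are total on their
declared formats: malformed input raises a diagnostic :class:`FormatError`
naming the offending line or identifier, never silently truncating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SimilarityGraph",
    "ExpressionTable",
    "GeneTree",
    "species_map_from_prefixes",
    "read_similarity_table",
    "write_similarity_table",
    "read_expression_table",
    "write_expression_table",
    "read_newick",
    "read_gene_sets",
    "read_annotation_table",
]

FLOAT_FMT = "%.6g"  # declared round-trip precision: 6 significant digits


class FormatError(ValueError):
    """Raised for any malformed external input, with a diagnostic message."""


# ---------------------------------------------------------------------------
# species maps


def species_map_from_prefixes(prefixes: Mapping[str, str]) -> Callable[[str], str | None]:
    """Build a gene-id -> species resolver from ``{species: id-prefix}``.

    Longest prefix wins so e.g. ``{"Ppa": "Ppa-", "Ppa2": "Ppa-x"}`` is
    unambiguous.  Returns ``None`` for unresolvable ids (callers decide
    whether that is an error).
    """
    ordered = sorted(prefixes.items(), key=lambda kv: -len(kv[1]))

    def resolve(gene: str) -> str | None:
        for species, prefix in ordered:
            if gene.startswith(prefix):
                return species
        return None

    return resolve


def _as_resolver(species_map) -> Callable[[str], str | None]:
    if callable(species_map):
        return species_map
    if isinstance(species_map, Mapping):
        return lambda g: species_map.get(g)
    raise TypeError("species_map must be a mapping gene->species or a callable")


# ---------------------------------------------------------------------------
# similarity hits


@dataclass
class SimilarityGraph:
    """Typed all-vs-all protein similarity hits across and within species.

    ``hits`` has columns ``query, subject, evalue, bitscore, query_species,
    subject_species``; self-hits are dropped on construction and duplicate
    (query, subject) pairs are collapsed keeping the best bitscore.
    """

    hits: pd.DataFrame
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        df = self.hits
        required = ["query", "subject", "evalue", "bitscore", "query_species", "subject_species"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"similarity hits missing columns: {missing}")
        df = df[df["query"] != df["subject"]]
        # collapse duplicates: best bitscore, then smallest e-value
        df = df.sort_values(
            ["query", "subject", "bitscore", "evalue"],
            ascending=[True, True, False, True],
            kind="mergesort",
        ).drop_duplicates(["query", "subject"], keep="first")
        self.hits = df.reset_index(drop=True)
        if not self.species:
            sp = {}
            for col_g, col_s in (("query", "query_species"), ("subject", "subject_species")):
                sp.update(dict(zip(self.hits[col_g], self.hits[col_s])))
            self.species = sp

    def __len__(self) -> int:
        return len(self.hits)

    def filtered(self, evalue_threshold: float) -> pd.DataFrame:
        """Hits with e-value strictly below ``evalue_threshold``."""
        return self.hits[self.hits["evalue"] < evalue_threshold]

    def intraspecies(self, species: str, evalue_threshold: float | None = None) -> pd.DataFrame:
        df = self.hits if evalue_threshold is None else self.filtered(evalue_threshold)
        return df[(df["query_species"] == species) & (df["subject_species"] == species)]

    def interspecies(
        self, query_species: str, subject_species, evalue_threshold: float | None = None
    ) -> pd.DataFrame:
        df = self.hits if evalue_threshold is None else self.filtered(evalue_threshold)
        if isinstance(subject_species, str):
            subject_species = [subject_species]
        return df[
            (df["query_species"] == query_species)
            & (df["subject_species"].isin(subject_species))
        ]


_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_table(path, species_map) -> SimilarityGraph:
    """Parse a 12-column BLAST ``-outfmt 6`` file into a :class:`SimilarityGraph`.

    ``species_map`` resolves every gene id to a species tag (mapping or
    callable, see :func:`species_map_from_prefixes`).  Rows with unparseable
    numerics are rejected with their line number; genes with no species
    assignment are a hard error listing all offenders.
    """
    resolve = _as_resolver(species_map)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field ({exc})") from None
            if evalue < 0 or bitscore < 0:
                raise FormatError(f"{path}:{lineno}: negative e-value or bitscore")
            rows.append((parts[0], parts[1], evalue, bitscore))
    df = pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])
    genes = pd.unique(pd.concat([df["query"], df["subject"]], ignore_index=True))
    species = {g: resolve(g) for g in genes}
    unresolved = sorted(g for g, s in species.items() if s is None)
    if unresolved:
        raise FormatError(
            "genes with no species assignment: " + ", ".join(unresolved)
        )
    df["query_species"] = df["query"].map(species)
    df["subject_species"] = df["subject"].map(species)
    return SimilarityGraph(df, species=species)


def write_similarity_table(graph: SimilarityGraph, path) -> None:
    """Write hits as outfmt-6-like rows; unused columns get placeholders."""
    with open(path, "w") as fh:
        for row in graph.hits.itertuples(index=False):
            fields = [
                row.query, row.subject, "100.00", "0", "0", "0",
                "0", "0", "0", "0",
                FLOAT_FMT % row.evalue, FLOAT_FMT % row.bitscore,
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionTable:
    """Genes x samples matrix of non-negative expression values (FPKM-like).

    ``stage_groups`` optionally maps each sample id to a developmental stage
    group label (e.g. early / dauer / late).  Values are stored as
    double-precision; FPKM semantics are not enforced beyond non-negativity.
    """

    values: pd.DataFrame
    stage_groups: dict[str, str] | None = None

    def __post_init__(self):
        df = self.values
        if df.index.duplicated().any():
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {', '.join(map(str, dup))}")
        if df.columns.duplicated().any():
            dup = sorted(df.columns[df.columns.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {', '.join(map(str, dup))}")
        arr = df.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            gene = df.index[np.isnan(arr).any(axis=1)][0]
            raise FormatError(f"missing or non-numeric expression value for gene {gene!r}")
        if (arr < 0).any():
            gene = df.index[(arr < 0).any(axis=1)][0]
            raise FormatError(f"negative expression value for gene {gene!r}")
        self.values = df.astype(float)
        if self.stage_groups is not None:
            missing = [s for s in df.columns if s not in self.stage_groups]
            if missing:
                raise FormatError(f"stage_assignment does not cover samples: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def stages(self) -> dict[str, list[str]]:
        """Stage group -> ordered list of member samples."""
        if self.stage_groups is None:
            raise ValueError("no stage groups attached to this table")
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.stage_groups[s], []).append(s)
        return out


def read_expression_table(path, stage_groups: dict[str, str] | None = None) -> ExpressionTable:
    """Load a TSV expression matrix: first column gene id, header of sample ids."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse expression TSV ({exc})") from None
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() and not df.isna().any().any():
        bad = df.columns[numeric.isna().any(axis=0)][0]
        raise FormatError(f"{path}: non-numeric value in column {bad!r}")
    return ExpressionTable(numeric, stage_groups=stage_groups)


def write_expression_table(table: ExpressionTable, path) -> None:
    table.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


# ---------------------------------------------------------------------------
# gene trees


@dataclass
class GeneTree:
    """A gene tree with every tip resolved to exactly one species."""

    tree: dendropy.Tree
    tip_species: dict[str, str]

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def _resolve_tip_species(labels, species_rule) -> dict[str, str]:
    """Assign species per tip label.

    ``species_rule`` is either a mapping label->species (side table), a
    mapping species->token (the token must occur in the label, e.g.
    ``{"Ppa": "Ppa", "Cel": "Cel"}`` for tips like ``a_Ppa``), or a callable
    label->species.
    """
    out: dict[str, str] = {}
    if callable(species_rule):
        for lab in labels:
            sp = species_rule(lab)
            if sp is None:
                raise FormatError(f"tip {lab!r} matches no species rule")
            out[lab] = sp
        return out
    if not isinstance(species_rule, Mapping):
        raise TypeError("species_rule must be a mapping or callable")
    # side table if every label is a key
    if all(lab in species_rule for lab in labels):
        return {lab: species_rule[lab] for lab in labels}
    # otherwise species -> token, longest token first
    tokens = sorted(species_rule.items(), key=lambda kv: -len(kv[1]))
    for lab in labels:
        for species, token in tokens:
            if token in lab:
                out[lab] = species
                break
        else:
            raise FormatError(f"tip {lab!r} contains no species token")
    return out


def read_newick(path_or_string, species_rule) -> GeneTree:
    """Parse a Newick tree and resolve tip species per ``species_rule``."""
    src = str(path_or_string)
    if src.lstrip().startswith("(") or src.rstrip().endswith(";"):
        data = src
    else:
        with open(src) as fh:
            data = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"invalid Newick: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if not labels:
        raise FormatError("tree has no tips")
    return GeneTree(tree, _resolve_tip_species(labels, species_rule))


# ---------------------------------------------------------------------------
# simple TSV tables


def read_gene_sets(path) -> list[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_annotation_table(path) -> pd.DataFrame:
    """gene<TAB>domain-id annotation table -> DataFrame(gene, domain)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene", "domain"]
    return df
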