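"""Genomic phylostratigraphy: phylostratum index and gene-age assignment.

A phylostratum (ps) is a node on the focal species' lineage, numbered from
the root (ps 1, e.g. cellular organisms) to the terminal branch (ps P, the
focal species).  A gene's age is the oldest (numerically smallest) ps at
which a sequence-similarity search still finds a match, computed here from a
tabular hit file produced by an external search tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Phylostratigraphy",
    "GeneAgeMap",
    "build_phylostratum_index",
    "assign_gene_ages",
    "read_node_table",
    "read_taxon_table",
    "read_hit_table",
]


class PhylostratigraphyError(ValueError):
    """Invalid phylostratum index or hit table."""


@dataclass(frozen=True)
class Phylostratigraphy:
    """Ordered phylogenetic nodes plus a taxon -> phylostratum membership map.

    ``nodes`` lists (ps_index, node_name) in root-to-tip order with
    consecutive indices 1..P; ``taxon_map`` assigns every subject taxon the
    ps of the most recent focal-lineage node ancestral to it.
    """

    nodes: tuple[tuple[int, str], ...]
    taxon_map: dict[str, int] = field(repr=False)

    @property
    def n_strata(self) -> int:
        return len(self.nodes)

    def node_name(self, ps: int) -> str:
        return self.nodes[ps - 1][1]

    def taxa_at(self, ps: int) -> list[str]:
        return [t for t, p in self.taxon_map.items() if p == ps]


@dataclass(frozen=True)
class GeneAgeMap:
    """Mapping gene_id -> phylostratum, with assignment provenance.

    Genes whose query returned no self-match are absent; ``n_discarded``
    counts them (among queries that appeared in the hit table).
    """

    ages: pd.Series  # index gene_id, values int ps
    evalue_threshold: float
    n_discarded: int

    def __len__(self) -> int:
        return len(self.ages)

    def __getitem__(self, gene_id: str) -> int:
        return int(self.ages.loc[gene_id])

    def to_tsv(self, path: str | Path) -> None:
        df = self.ages.rename("ps").rename_axis("gene_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, evalue_threshold: float = float("nan"), n_discarded: int = 0
    ) -> "GeneAgeMap":
        df = pd.read_csv(path, sep="\t")
        ages = pd.Series(
            df["ps"].astype(int).values,
            index=pd.Index(df["gene_id"].astype(str).to_numpy()),
        )
        return cls(ages=ages, evalue_threshold=evalue_threshold, n_discarded=n_discarded)


def build_phylostratum_index(
    node_table: pd.DataFrame, taxon_table: pd.DataFrame
) -> Phylostratigraphy:
    """Build the phylostratum index from node and taxon membership tables.

    Parameters
    ----------
    node_table
        Columns ``ps`` (integer >= 1) and ``node_name``; rows in
        root-to-tip order with consecutive indices 1..P.
    taxon_table
        Columns ``taxon_id`` and ``ps``; each taxon assigned to exactly one
        listed node.

    Raises
    ------
    PhylostratigraphyError
        On empty tables, non-consecutive ps indices, duplicate taxon
        assignment, or a taxon referencing an unlisted node.
    """
    if len(node_table) == 0:
        raise PhylostratigraphyError("node table is empty")
    if len(taxon_table) == 0:
        raise PhylostratigraphyError("taxon table is empty")

    ps = node_table["ps"].astype(int).to_numpy()
    if not np.array_equal(ps, np.arange(1, len(ps) + 1)):
        raise PhylostratigraphyError(
            "node table ps indices must be consecutive 1..P in root-to-tip order; "
            f"got {ps.tolist()}"
        )
    nodes = tuple(zip(ps.tolist(), node_table["node_name"].astype(str).tolist()))

    taxa = taxon_table["taxon_id"].astype(str)
    dup = taxa[taxa.duplicated()].unique()
    if len(dup):
        raise PhylostratigraphyError(f"taxa assigned to more than one node: {dup.tolist()}")
    tax_ps = taxon_table["ps"].astype(int)
    bad = sorted(set(tax_ps) - set(ps.tolist()))
    if bad:
        raise PhylostratigraphyError(f"taxa reference nodes absent from node table: {bad}")

    return Phylostratigraphy(nodes=nodes, taxon_map=dict(zip(taxa, tax_ps)))


def assign_gene_ages(
    hits: pd.DataFrame,
    index: Phylostratigraphy,
    evalue_threshold: float = 1e-3,
    focal_taxon: str | None = None,
    self_rule: Literal["taxon", "gene"] = "taxon",
) -> GeneAgeMap:
    """Assign each query gene its phylostratum by the oldest-internode rule.

    Hits with e-value above ``evalue_threshold`` (inclusive comparison:
    retained iff evalue <= threshold) are dropped.  A query with no retained
    self-match is discarded.  Every other query gets the oldest, i.e.
    numerically smallest, ps among the subject taxa of its retained hits.

    Parameters
    ----------
    hits
        Columns ``query``, ``subject_taxon``, ``evalue``; with
        ``self_rule="gene"`` additionally ``subject_gene``.
    focal_taxon
        Taxon id of the focal species; required for ``self_rule="taxon"``,
        where a retained hit to this taxon counts as the self-match.
    self_rule
        ``"taxon"``: self-match at taxon granularity (any retained hit whose
        subject taxon is the focal species).  ``"gene"``: the retained hit's
        ``subject_gene`` must equal the query id.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    if self_rule == "taxon" and focal_taxon is None:
        raise ValueError("focal_taxon is required with self_rule='taxon'")

    if len(hits) == 0:
        warnings.warn("empty hit table: returning an empty gene-age map", stacklevel=2)
        return GeneAgeMap(
            ages=pd.Series(dtype=int), evalue_threshold=evalue_threshold, n_discarded=0
        )

    subject = hits["subject_taxon"].astype(str)
    unknown = sorted(set(subject) - set(index.taxon_map))
    if unknown:
        raise PhylostratigraphyError(f"hits reference taxa absent from the index: {unknown}")

    if focal_taxon is not None and focal_taxon in index.taxon_map:
        if index.taxon_map[focal_taxon] != index.n_strata:
            warnings.warn(
                f"focal taxon {focal_taxon!r} maps to ps "
                f"{index.taxon_map[focal_taxon]}, not the terminal ps {index.n_strata}",
                stacklevel=2,
            )

    evalue = pd.to_numeric(hits["evalue"])
    if (evalue < 0).any():
        raise ValueError("negative e-values in hit table")
    retained = hits.loc[(evalue <= evalue_threshold).to_numpy()]

    n_queries = hits["query"].nunique()
    if len(retained) == 0:
        return GeneAgeMap(
            ages=pd.Series(dtype=int),
            evalue_threshold=evalue_threshold,
            n_discarded=n_queries,
        )

    if self_rule == "taxon":
        is_self = retained["subject_taxon"].astype(str) == focal_taxon
    else:
        if "subject_gene" not in retained.columns:
            raise ValueError("self_rule='gene' requires a subject_gene column")
        is_self = retained["subject_gene"].astype(str) == retained["query"].astype(str)

    self_queries = set(retained.loc[is_self.to_numpy(), "query"])
    kept = retained.loc[retained["query"].isin(self_queries)]
    ps_of_hit = kept["subject_taxon"].astype(str).map(index.taxon_map)
    ages = ps_of_hit.groupby(kept["query"].to_numpy()).min().astype(int)
    ages.index = pd.Index(ages.index.astype(str))
    ages = ages.rename(None).sort_index()
    ages.index.name = None

    return GeneAgeMap(
        ages=ages,
        evalue_threshold=evalue_threshold,
        n_discarded=n_queries - len(ages),
    )


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns (ps, node_name)."""
    return pd.read_csv(path, sep="\t", dtype={"node_name": str})


def read_taxon_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns (taxon_id, ps)."""
    return pd.read_csv(path, sep="\t", dtype={"taxon_id": str})


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header (query, subject_taxon, evalue[, subject_gene])."""
    return pd.read_csv(path, sep="\t", dtype={"query": str, "subject_taxon": str})


def write_node_table(index: Phylostratigraphy, path: str | Path) -> None:
    pd.DataFrame(index.nodes, columns=["ps", "node_name"]).to_csv(path, sep="\t", index=False)


def write_taxon_table(index: Phylostratigraphy, path: str | Path) -> None:
    pd.DataFrame(
        {"taxon_id": list(index.taxon_map), "ps": list(index.taxon_map.values())}
    ).to_csv(path, sep="\t", index=False)
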