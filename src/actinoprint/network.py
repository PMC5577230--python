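"""Antibacterial-activity summaries and their correlation with gene presence.

Activity screens are binary isolate x test-strain tables (agar-plug style
inhibition calls). The module tabulates per-strain and Gram-class hit rates
among active isolates, partitions active isolates by biosynthetic-gene
content (both loci / exactly one / neither), and renders the relationships
as a tripartite isolate-locus-strain network exportable as an edge-list TSV
or GraphML.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .util import ParameterError, percent


@dataclass
class CorrelationSummary:
    """Partition of active isolates by gene content, plus silent carriers."""

    n_active: int
    both: int
    either: int   # exactly one locus
    neither: int
    inactive_gene_positive: int
    categories: dict[str, str]  # isolate -> {"both", "either", "neither"}

    @property
    def both_pct(self) -> float:
        return percent(self.both, self.n_active)

    @property
    def either_pct(self) -> float:
        return percent(self.either, self.n_active)

    @property
    def neither_pct(self) -> float:
        return percent(self.neither, self.n_active)


def _check_binary(t: pd.DataFrame) -> pd.DataFrame:
    if t.columns.has_duplicates:
        raise ParameterError("duplicate column names")
    return t.astype(bool)


def activity_summary(
    t: pd.DataFrame, gram_map: dict[str, str] | None = None
) -> dict:
    """Per-strain and Gram-class activity among active isolates.

    An isolate is *active* if it inhibits at least one test strain. Counts
    and percentages are reported relative to the number of active isolates;
    Gram-class rollups count active isolates hitting >= 1 strain of that
    class and require every strain to appear in ``gram_map``.
    """
    t = _check_binary(t)
    active = t.index[t.any(axis=1)]
    out: dict = {"n_isolates": len(t), "n_active": len(active), "per_strain": {}}
    if len(active) == 0:
        return out
    sub = t.loc[active]
    for strain in t.columns:
        hits = int(sub[strain].sum())
        out["per_strain"][strain] = {"count": hits, "pct": percent(hits, len(active))}
    if gram_map is not None:
        unmapped = [s for s in t.columns if s not in gram_map]
        if unmapped:
            raise ParameterError(f"strains missing from Gram map: {unmapped}")
        out["per_gram_class"] = {}
        for cls in sorted(set(gram_map.values())):
            strains = [s for s in t.columns if gram_map[s] == cls]
            hits = int(sub[strains].any(axis=1).sum())
            out["per_gram_class"][cls] = {
                "count": hits,
                "pct": percent(hits, len(active)),
            }
    return out


def crosstab_activity_genes(
    t: pd.DataFrame, g: pd.DataFrame
) -> CorrelationSummary:
    """Cross-tabulate activity with gene presence over one isolate universe.

    Active isolates fall into exactly one of: positive for both loci,
    positive for exactly one, or negative for all; silent gene carriers
    (inactive but >= 1 locus) are counted alongside.
    """
    t = _check_binary(t)
    g = _check_binary(g)
    if set(t.index) != set(g.index):
        diff = sorted(set(t.index) ^ set(g.index))
        raise ParameterError(f"isolate universes differ; symmetric difference: {diff}")
    g = g.loc[t.index]
    n_loci = g.sum(axis=1)
    active = t.any(axis=1)
    categories = {}
    for iso in t.index:
        k = int(n_loci[iso])
        categories[iso] = "both" if k >= 2 else ("either" if k == 1 else "neither")
    both = int(sum(active[i] and categories[i] == "both" for i in t.index))
    either = int(sum(active[i] and categories[i] == "either" for i in t.index))
    neither = int(sum(active[i] and categories[i] == "neither" for i in t.index))
    silent = int(sum((not active[i]) and n_loci[i] >= 1 for i in t.index))
    return CorrelationSummary(
        n_active=int(active.sum()),
        both=both,
        either=either,
        neither=neither,
        inactive_gene_positive=silent,
        categories=categories,
    )


def build_network(
    t: pd.DataFrame,
    g: pd.DataFrame,
    genus_of: dict[str, str] | None = None,
) -> nx.Graph:
    """Tripartite isolate-locus-strain graph of gene presence and activity.

    One edge per true cell of either table (``kind`` attribute ``gene`` or
    ``activity``); isolate nodes carry genus and gene-content category.
    """
    summary = crosstab_activity_genes(t, g)
    t = _check_binary(t)
    g = _check_binary(g.loc[t.index])
    graph = nx.Graph()
    for iso in sorted(t.index):
        graph.add_node(
            iso,
            kind="isolate",
            category=summary.categories[iso],
            genus=(genus_of or {}).get(iso, ""),
        )
    for locus in sorted(g.columns):
        graph.add_node(str(locus), kind="locus")
    for strain in sorted(t.columns):
        graph.add_node(str(strain), kind="strain")
    for iso in sorted(t.index):
        for locus in sorted(g.columns):
            if g.loc[iso, locus]:
                graph.add_edge(iso, str(locus), kind="gene")
        for strain in sorted(t.columns):
            if t.loc[iso, strain]:
                graph.add_edge(iso, str(strain), kind="activity")
    return graph


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as a sorted edge-list TSV or as GraphML."""
    path = Path(path)
    if fmt == "tsv":
        rows = sorted(
            (u, v, data.get("kind", "")) if u <= v else (v, u, data.get("kind", ""))
            for u, v, data in graph.edges(data=True)
        )
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\n")
            for u, v, kind in rows:
                fh.write(f"{u}\t{v}\t{kind}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ParameterError(f"unknown export format {fmt!r}")


def read_edge_list(path: str | Path) -> set[tuple[str, str, str]]:
    """Edge set from a TSV written by :func:`export_graph`."""
    edges = set()
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget\tkind":
            raise ParameterError("not an actinoprint edge-list TSV")
        for line in fh:
            u, v, kind = line.rstrip("\n").split("\t")
            edges.add((u, v, kind))
    return edges
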