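"""Pathway analysis in the MetPA style: hypergeometric over-representation
of significantly changed metabolites plus a topology "impact" score from
relative betweenness centrality of the hit compounds.

Pathways are undirected, unweighted compound graphs. Node importance is
betweenness centrality normalized so importances sum to 1 across the
pathway (uniform fallback when every centrality is 0, e.g. complete
graphs); the impact of a hit set is the summed importance of its matched
nodes, hence in [0, 1] with 1 meaning every node was hit.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError


@dataclass
class PathwayGraph:
    name: str
    graph: nx.Graph = field(repr=False)

    def __post_init__(self):
        g = nx.Graph(self.graph)
        g.remove_edges_from(nx.selfloop_edges(g))
        self.graph = g

    @classmethod
    def from_edges(cls, name: str, edges, extra_nodes=()) -> "PathwayGraph":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        g.add_nodes_from(extra_nodes)
        return cls(name, g)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)


@dataclass
class PathwayResult:
    pathway: str
    n_hits: int
    n_pathway: int
    raw_p: float
    impact: float
    holm_p: float = np.nan
    fdr_p: float = np.nan


def hypergeom_enrichment(hits: set, pathway_nodes: set, universe: set) -> float:
    """Upper-tail hypergeometric P(X >= k) with k = |hits ∩ pathway|,
    K = |pathway|, n = |hits|, N = |universe|."""
    if not universe:
        raise InputError("empty universe")
    if not pathway_nodes <= universe:
        raise InputError("pathway nodes must be a subset of the universe")
    if not hits <= universe:
        raise InputError("hits must be a subset of the universe")
    k = len(hits & pathway_nodes)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, len(universe), len(pathway_nodes), len(hits)))


def relative_betweenness(pg: PathwayGraph) -> dict:
    """Node -> importance in [0, 1], summing to 1 across the pathway."""
    nodes = list(pg.graph.nodes)
    if not nodes:
        raise InputError(f"pathway {pg.name!r} has no nodes")
    bc = nx.betweenness_centrality(pg.graph, normalized=False)
    total = sum(bc.values())
    if total == 0:
        return {n: 1.0 / len(nodes) for n in nodes}
    return {n: bc[n] / total for n in nodes}


def pathway_impact(pg: PathwayGraph, hits: set) -> float:
    """Summed relative-betweenness importance of the hit nodes."""
    imp = relative_betweenness(pg)
    return float(sum(imp[n] for n in hits & pg.nodes))


def metpa(
    hits: set,
    library: list[PathwayGraph],
    universe: set | None = None,
) -> pd.DataFrame:
    """Per-pathway enrichment p and topology impact, sorted by raw p.

    ``universe`` defaults to the union of all library compounds (a
    reference-metabolome list, e.g. the assigned metabolites, can be passed
    instead). Hits outside the universe are dropped with a warning.
    """
    if not library:
        raise InputError("empty pathway library")
    if universe is None:
        universe = set().union(*(pg.nodes for pg in library))
    hits = set(hits)
    stray = hits - universe
    if stray:
        warnings.warn(
            f"dropping {len(stray)} hit(s) absent from the universe: "
            f"{sorted(stray)}", RuntimeWarning,
        )
        hits &= universe
    rows = []
    for pg in library:
        nodes = pg.nodes & universe
        rows.append(PathwayResult(
            pathway=pg.name,
            n_hits=len(hits & nodes),
            n_pathway=len(nodes),
            raw_p=hypergeom_enrichment(hits, nodes, universe),
            impact=pathway_impact(pg, hits),
        ))
    raw = np.array([r.raw_p for r in rows])
    holm = multipletests(raw, method="holm")[1]
    fdr = multipletests(raw, method="fdr_bh")[1]
    for r, h, f in zip(rows, holm, fdr):
        r.holm_p, r.fdr_p = float(h), float(f)
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "raw_p", kind="stable").reset_index(drop=True)
    df["neg_log10_p"] = -np.log10(df.raw_p)
    return df


# ---------------------------------------------------------------------------
# library I/O and the bundled toy library


def save_library(library: list[PathwayGraph], out_dir: str) -> str:
    """One edge-list CSV per pathway plus an index CSV; returns index path."""
    os.makedirs(out_dir, exist_ok=True)
    idx = []
    for i, pg in enumerate(library):
        fname = f"pathway_{i:02d}.csv"
        pd.DataFrame(pg.graph.edges, columns=["source", "target"]).to_csv(
            os.path.join(out_dir, fname), index=False)
        idx.append({"pathway": f"pathway_{i:02d}", "file": fname, "name": pg.name})
    index_path = os.path.join(out_dir, "index.csv")
    pd.DataFrame(idx).to_csv(index_path, index=False)
    return index_path


def load_library(index_path: str) -> list[PathwayGraph]:
    try:
        idx = pd.read_csv(index_path)
    except OSError:
        raise InputError(f"pathway index not found: {index_path}")
    for col in ("file", "name"):
        if col not in idx.columns:
            raise InputError(f"{index_path}: index lacks column {col!r}")
    base = os.path.dirname(os.path.abspath(index_path))
    out = []
    for _, row in idx.iterrows():
        edges = pd.read_csv(os.path.join(base, row["file"]))
        out.append(PathwayGraph.from_edges(
            row["name"], zip(edges["source"], edges["target"])))
    return out


def toy_library() -> list[PathwayGraph]:
    """Small literature-shaped pathways over the default metabolite names,
    bundled for tests and demo runs (a chain, a cycle, a star, a tree, a
    clique and a two-component graph)."""
    chain = PathwayGraph.from_edges(
        "branched-chain amino acid degradation",
        [("leucine", "isoleucine"), ("isoleucine", "valine"),
         ("valine", "succinate")],
    )
    cycle = PathwayGraph.from_edges(
        "TCA cycle",
        [("citrate", "succinate"), ("succinate", "fumarate"),
         ("fumarate", "malate"), ("malate", "pyruvate"),
         ("pyruvate", "citrate")],
    )
    star = PathwayGraph.from_edges(
        "choline and osmolyte metabolism",
        [("choline", "betaine"), ("choline", "glycerophosphocholine"),
         ("choline", "N,N-dimethylglycine"), ("choline", "myo-inositol")],
    )
    tree = PathwayGraph.from_edges(
        "purine metabolism",
        [("ATP", "AMP"), ("AMP", "adenosine"), ("adenosine", "inosine"),
         ("inosine", "hypoxanthine"), ("AMP", "NAD+")],
    )
    members = ["alanine", "aspartate", "glutamate", "glutamine"]
    clique = PathwayGraph.from_edges(
        "alanine, aspartate and glutamate metabolism",
        [(a, b) for i, a in enumerate(members) for b in members[i + 1:]],
    )
    split = PathwayGraph.from_edges(
        "glycolysis and gluconeogenesis",
        [("glucose", "pyruvate"), ("pyruvate", "lactate"),
         ("maltose", "glycerol")],
    )
    return [chain, cycle, star, tree, clique, split]
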