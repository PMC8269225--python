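"""Metaweb assembly, community detection and network properties.

The metaweb of one stratum (here a country) collects every significant
pairwise association inferred across that stratum's samples: a positive
edge set (co-occurrence) and a negative edge set (co-exclusion) over the
filtered OTU universe.  Modules are detected on the positive-edge
subgraph with the walktrap random-walk agglomerative algorithm, cutting
the merge dendrogram at maximal Newman-Girvan modularity.

Graph metrics follow the conventions of the igraph library: the
clustering coefficient is the average transitivity (mean local clustering
over nodes of degree >= 2), and the average path length is the mean
geodesic over connected node pairs only, which keeps the property
meaningful on disconnected local networks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .community_io import PresenceMatrix
from .cooccurrence import SIGN_NEGATIVE, SIGN_POSITIVE

Edge = tuple[str, str]


@dataclass
class ModulePartition:
    """A node partition with its Newman-Girvan modularity.

    ``merge_history`` records the agglomerative merges (pairs of community
    indices) so a partition can be reproduced and audited.
    """

    assignment: dict[str, int]
    Q: float
    merge_history: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module: int) -> set[str]:
        return {n for n, m in self.assignment.items() if m == module}


@dataclass
class Metaweb:
    """All significant pairwise associations of one stratum.

    ``nodes`` is the full filtered OTU universe, including species that
    ended up with no significant edge — they still count in the
    denominators of the local edge proportions.
    """

    stratum: str
    nodes: list[str]
    positive_edges: list[Edge]
    negative_edges: list[Edge]
    edge_pvalues: dict[Edge, float] = field(default_factory=dict)
    modules: ModulePartition | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for name, edges in (("positive", self.positive_edges), ("negative", self.negative_edges)):
            for a, b in edges:
                if a == b:
                    raise ValueError(f"self-loop on {a!r}")
                if a not in node_set or b not in node_set:
                    raise ValueError(f"{name} edge endpoint not in node set: ({a}, {b})")
        pos = {frozenset(e) for e in self.positive_edges}
        neg = {frozenset(e) for e in self.negative_edges}
        if len(pos) != len(self.positive_edges) or len(neg) != len(self.negative_edges):
            raise ValueError("duplicate edges")
        if pos & neg:
            raise ValueError("an edge cannot be both positive and negative")

    def edges(self, sign: str) -> list[Edge]:
        if sign in ("pos", SIGN_POSITIVE):
            return self.positive_edges
        if sign in ("neg", SIGN_NEGATIVE):
            return self.negative_edges
        raise ValueError(f"unknown sign {sign!r}")


def build_metaweb(assoc: pd.DataFrame, nodes: list[str], stratum: str = "") -> Metaweb:
    """Assemble a metaweb from an association table over the given OTU universe."""
    pos = assoc[assoc["sign"] == SIGN_POSITIVE]
    neg = assoc[assoc["sign"] == SIGN_NEGATIVE]
    pvals: dict[Edge, float] = {}
    pos_edges = [(str(a), str(b)) for a, b in zip(pos["otu_a"], pos["otu_b"])]
    neg_edges = [(str(a), str(b)) for a, b in zip(neg["otu_a"], neg["otu_b"])]
    for e, p in zip(pos_edges, pos["p_gt"]):
        pvals[e] = float(p)
    for e, p in zip(neg_edges, neg["p_lt"]):
        pvals[e] = float(p)
    web = Metaweb(stratum, [str(n) for n in nodes], pos_edges, neg_edges, pvals)
    if pos_edges:
        web.modules = walktrap_communities(pos_edges)
    return web


# ---------------------------------------------------------------------------
# community detection and modularity
# ---------------------------------------------------------------------------


def _igraph_from_edges(edges: list[Edge]) -> tuple[ig.Graph, list[str]]:
    """Build an igraph over the non-isolated nodes, sorted for determinism."""
    names = sorted({n for e in edges for n in e})
    index = {n: i for i, n in enumerate(names)}
    g = ig.Graph(n=len(names), edges=[(index[a], index[b]) for a, b in edges])
    return g, names


def walktrap_communities(edges: list[Edge], steps: int = 4, seed: int = 0) -> ModulePartition:
    """Random-walk agglomerative community detection (walktrap).

    Communities are merged bottom-up by similarity of ``steps``-step
    random-walk profiles and the dendrogram is cut at the level of maximal
    Newman-Girvan modularity.  The procedure is deterministic; ``seed`` is
    accepted for interface symmetry with the stochastic stages.
    """
    if not edges:
        raise ValueError("cannot partition an empty graph")
    g, names = _igraph_from_edges(edges)
    dendrogram = g.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()
    assignment = {names[v]: m for v, m in enumerate(clustering.membership)}
    q = newman_modularity(edges, assignment)
    merges = [tuple(map(int, m)) for m in dendrogram.merges]
    return ModulePartition(assignment, q, merges)


def newman_modularity(edges: list[Edge], assignment: dict[str, int]) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2]."""
    m = len(edges)
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    within: dict[int, int] = {}
    degree_sum: dict[int, int] = {}
    for a, b in edges:
        ca, cb = assignment[a], assignment[b]
        degree_sum[ca] = degree_sum.get(ca, 0) + 1
        degree_sum[cb] = degree_sum.get(cb, 0) + 1
        if ca == cb:
            within[ca] = within.get(ca, 0) + 1
    return float(
        sum(within.get(c, 0) / m - (degree_sum[c] / (2 * m)) ** 2 for c in degree_sum)
    )


# ---------------------------------------------------------------------------
# graph properties
# ---------------------------------------------------------------------------


@dataclass
class GraphProperties:
    """Community-level properties of one (signed) network."""

    n_nodes: int
    n_edges: int
    n_components: int | None
    modularity: float | None
    clustering: float | None
    avg_path_length: float | None
    edge_proportion: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def graph_properties(edges: list[Edge], total_otus: int, walktrap_steps: int = 4) -> GraphProperties:
    """Global properties of the network spanned by ``edges``.

    Components, clustering and path length are computed on the
    non-isolated node set; ``total_otus`` (the sample's filtered richness
    S) only enters the edge proportion denominator C(S, 2).  With no edges
    every property is missing and the proportion is 0.
    """
    n_pairs = math.comb(total_otus, 2)
    if not edges:
        return GraphProperties(0, 0, None, None, None, None, 0.0)
    g, names = _igraph_from_edges(edges)
    if total_otus < len(names):
        raise ValueError(f"total_otus={total_otus} < {len(names)} nodes with edges")
    clustering = g.transitivity_avglocal_undirected(mode="nan")
    if isinstance(clustering, float) and math.isnan(clustering):
        clustering = None
    apl = g.average_path_length(unconn=True)  # mean geodesic over connected pairs
    if isinstance(apl, float) and math.isnan(apl):
        apl = None
    partition = walktrap_communities(edges, steps=walktrap_steps)
    return GraphProperties(
        n_nodes=g.vcount(),
        n_edges=g.ecount(),
        n_components=len(g.connected_components()),
        modularity=partition.Q,
        clustering=clustering,
        avg_path_length=apl,
        edge_proportion=g.ecount() / n_pairs if n_pairs else 0.0,
    )


# ---------------------------------------------------------------------------
# module summaries
# ---------------------------------------------------------------------------


def module_completeness(metaweb: Metaweb, presence: PresenceMatrix) -> pd.DataFrame:
    """Fraction of each metaweb module's species present in each sample."""
    if metaweb.modules is None:
        raise ValueError("metaweb has no module partition (no positive edges?)")
    modules = sorted(set(metaweb.modules.assignment.values()))
    member_sets = {m: metaweb.modules.members(m) for m in modules}
    out = np.zeros((presence.n_samples, len(modules)))
    otu_index = {o: i for i, o in enumerate(presence.otu_ids)}
    for mi, m in enumerate(modules):
        cols = [otu_index[o] for o in member_sets[m] if o in otu_index]
        size = len(member_sets[m])
        if cols:
            out[:, mi] = presence.values[:, cols].sum(axis=1) / size
    return pd.DataFrame(out, index=presence.sample_ids, columns=[f"module_{m}" for m in modules])


def module_env_summary(
    metaweb: Metaweb,
    presence: PresenceMatrix,
    metadata: pd.DataFrame,
    variable: str = "max_temperature",
) -> tuple[pd.Series, pd.DataFrame]:
    """Environmental range of each module.

    Each OTU is summarised by the mean of ``variable`` over the samples
    where it occurs (the conditions where it thrives); the per-module
    distribution of those means (median, IQR, range) characterises the
    module's environmental band.
    """
    if metaweb.modules is None:
        raise ValueError("metaweb has no module partition")
    if variable not in metadata.columns:
        raise KeyError(f"metadata has no column {variable!r}")
    env = metadata.loc[presence.sample_ids, variable].to_numpy(float)
    values = presence.values.astype(float)
    occ = values.sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_otu = (values * env[:, None]).sum(axis=0) / occ
    per_otu = pd.Series(per_otu, index=presence.otu_ids, name=f"mean_{variable}")
    missing = per_otu.index[occ == 0]
    if len(missing):
        import warnings

        warnings.warn(f"{len(missing)} OTUs present in no sample excluded from summary")
        per_otu = per_otu.drop(missing)
    assign = pd.Series(metaweb.modules.assignment, name="module")
    joined = pd.concat([per_otu, assign], axis=1, join="inner")
    summary = joined.groupby("module")[per_otu.name].agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
        n="size",
    )
    return per_otu, summary


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def write_metaweb(web: Metaweb, edges_path, modules_path=None) -> None:
    rows = [
        (a, b, "positive", web.edge_pvalues.get((a, b), np.nan))
        for a, b in web.positive_edges
    ] + [
        (a, b, "negative", web.edge_pvalues.get((a, b), np.nan))
        for a, b in web.negative_edges
    ]
    pd.DataFrame(rows, columns=["otu_a", "otu_b", "sign", "p_value"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if modules_path is not None and web.modules is not None:
        pd.Series(web.modules.assignment, name="module").rename_axis("otu_id").to_csv(
            modules_path, sep="\t"
        )


def read_metaweb(edges_path, nodes: list[str], stratum: str = "") -> Metaweb:
    df = pd.read_csv(edges_path, sep="\t", dtype={"otu_a": str, "otu_b": str})
    pos = [(a, b) for a, b, s in zip(df["otu_a"], df["otu_b"], df["sign"]) if s == "positive"]
    neg = [(a, b) for a, b, s in zip(df["otu_a"], df["otu_b"], df["sign"]) if s == "negative"]
    pvals = {
        (a, b): float(p) for a, b, p in zip(df["otu_a"], df["otu_b"], df["p_value"])
    }
    web = Metaweb(stratum, nodes, pos, neg, pvals)
    if pos:
        web.modules = walktrap_communities(pos)
    return web


def properties_report(props: GraphProperties, path) -> None:
    with open(path, "w") as fh:
        json.dump(props.as_dict(), fh, indent=2)
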