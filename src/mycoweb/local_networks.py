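"""Projection of the metaweb into per-sample local networks.

A sample's local network is the induced subgraph of the metaweb on the
species present in that sample: an edge (of either sign) is inherited iff
both endpoints occur locally.  Community-level properties (components,
modularity, average transitivity, average path length) are then computed
per sample and per sign, together with the co-occurrence and co-exclusion
proportions — the number of inherited edges of each sign over all
C(S, 2) species pairs of the sample, S being the sample's richness within
the filtered OTU universe.

This projection step is agnostic to how the pairwise association lists
were produced; any external edge list over the same OTU universe can be
substituted for the exact-model metaweb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_io import PresenceMatrix
from .metaweb import Edge, GraphProperties, Metaweb, graph_properties

logger = logging.getLogger(__name__)

#: per-sign property columns of the wide profile table
PROPERTY_NAMES = (
    "n_nodes",
    "n_edges",
    "n_components",
    "modularity",
    "clustering",
    "avg_path_length",
)


@dataclass
class LocalNetworkProfile:
    """Community-level network properties of one sample."""

    sample_id: str
    richness_S: int
    pos: GraphProperties
    neg: GraphProperties
    cooccurrence_proportion: float
    coexclusion_proportion: float

    def as_row(self) -> dict:
        row: dict = {"sample_id": self.sample_id, "richness_S": self.richness_S}
        for sign, props in (("pos", self.pos), ("neg", self.neg)):
            for name in PROPERTY_NAMES:
                row[f"{name}_{sign}"] = getattr(props, name)
        row["cooccurrence_proportion"] = self.cooccurrence_proportion
        row["coexclusion_proportion"] = self.coexclusion_proportion
        return row


def extract_local(metaweb: Metaweb, species: set[str], sign: str) -> list[Edge]:
    """Metaweb edges of one sign with both endpoints in ``species``."""
    unknown = species - set(metaweb.nodes)
    if unknown:
        shown = sorted(unknown)[:5]
        raise ValueError(f"species not in metaweb node set: {shown}")
    return [(a, b) for a, b in metaweb.edges(sign) if a in species and b in species]


def local_profile(
    metaweb: Metaweb, species: set[str], sample_id: str = "", walktrap_steps: int = 4
) -> LocalNetworkProfile:
    """Properties of one sample's induced (+) and (-) subgraphs."""
    s = len(species)
    if s < 2:
        raise ValueError(f"sample {sample_id!r}: need >=2 species for pair proportions")
    n_pairs = math.comb(s, 2)
    pos_edges = extract_local(metaweb, species, "pos")
    neg_edges = extract_local(metaweb, species, "neg")
    return LocalNetworkProfile(
        sample_id=sample_id,
        richness_S=s,
        pos=graph_properties(pos_edges, s, walktrap_steps),
        neg=graph_properties(neg_edges, s, walktrap_steps),
        cooccurrence_proportion=len(pos_edges) / n_pairs,
        coexclusion_proportion=len(neg_edges) / n_pairs,
    )


def profile_all(
    metaweb: Metaweb, presence: PresenceMatrix, walktrap_steps: int = 4
) -> pd.DataFrame:
    """One profile row per sample of a presence matrix.

    Samples that cannot be profiled (richness < 2) are kept with missing
    values and logged.  The returned frame is indexed by sample_id and
    carries a min/mean/max summary per property in ``.attrs['ranges']``.
    """
    node_index = {o: j for j, o in enumerate(presence.otu_ids) if o in set(metaweb.nodes)}
    cols = np.array(list(node_index.values()), dtype=int)
    names = np.array(list(node_index.keys()), dtype=object)
    rows = []
    for i, sid in enumerate(presence.sample_ids):
        present = names[presence.values[i, cols] > 0]
        species = set(present)
        try:
            rows.append(local_profile(metaweb, species, sid, walktrap_steps).as_row())
        except ValueError as exc:
            logger.warning("skipping properties for %s: %s", sid, exc)
            rows.append({"sample_id": sid, "richness_S": len(species)})
    table = pd.DataFrame(rows).set_index("sample_id", drop=False)
    numeric = table.drop(columns=["sample_id"]).select_dtypes("number")
    table.attrs["ranges"] = numeric.agg(["min", "mean", "max"]).T
    return table


def write_profiles(table: pd.DataFrame, path, ranges_path=None) -> None:
    table.to_csv(path, sep="\t", index=False)
    if ranges_path is not None and "ranges" in table.attrs:
        table.attrs["ranges"].rename_axis("property").reset_index().to_json(
            ranges_path, orient="records", indent=2
        )


def read_profiles(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return table.set_index("sample_id", drop=False)
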